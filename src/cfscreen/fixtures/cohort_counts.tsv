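label	n_diagnostic_positive	n_detected	printed_pct
cma_positive_rate	452	335	74.12
cnv_of_positive	335	249	74.33
cnv_detected_any	249	159	63.86
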