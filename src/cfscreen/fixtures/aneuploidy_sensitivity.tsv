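label	n_diagnostic_positive	n_detected	printed_pct
T21	29	28	96.55
T18	7	7	100.00
T13	1	1	100.00
SCA	45	43	95.56
45,X	20	18	90.00
RAT	5	4	80.00
aneuploidy_total	86	83	96.51
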