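label	n_screen_positive	n_confirmed	printed_pct
T21	31	28	90.32
T18	8	7	87.50
T13	4	1	25.00
SCA	45	40	88.89
RAT	8	4	50.00
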