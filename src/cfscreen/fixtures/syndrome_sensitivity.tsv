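label	n_diagnostic_positive	n_detected	printed_pct
1p36 microdeletion	2	2	100.00
cri-du-chat (5p15)	2	2	100.00
Williams-Beuren (7q11.23)	3	1	33.33
9p deletion/duplication	4	4	100.00
Angelman/Prader-Willi (15q11-q13)	3	2	66.67
RCAD (17q12)	15	11	73.33
DiGeorge (22q11.2)	13	12	92.31
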