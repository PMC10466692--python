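label	stratum	n_diagnostic_positive	n_detected	n_maternal_origin	n_larger_than_cma	printed_pct
500 kb to <=1 Mb	500 kb to <=1 Mb	53	21	17	4	39.62
1 to <=2 Mb	1 to <=2 Mb	94	49	41	2	52.13
2 to <=3 Mb	2 to <=3 Mb	14	10	5	0	71.43
3 to <=5 Mb	3 to <=5 Mb	32	29	9	1	90.63
5 to <10 Mb	5 to <10 Mb	15	15	2	1	100.00
>=10 Mb	>=10 Mb	26	20	0	0	76.92
total	total	234	144	74	8	61.54
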