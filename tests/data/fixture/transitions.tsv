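class_a	class_b	n	n_neighbor	odds_ratio	p	q
XX-biased	XX-biased	1	0	0.8095238095	1	1
XX-biased	XO-biased	0	0	2.714285714	1	1
XX-biased	Non	1	0	0.8095238095	1	1
XO-biased	XX-biased	1	1	11.4	0.25	1
XO-biased	XO-biased	1	0	0.8095238095	1	1
XO-biased	Non	0	0	2.714285714	1	1
Non	XX-biased	1	1	11.4	0.25	1
Non	XO-biased	0	0	2.714285714	1	1
Non	Non	7	1	0.25	0.5227272727	1
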