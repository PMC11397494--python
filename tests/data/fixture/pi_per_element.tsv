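element_class	chrom	start	end	length	pi
CNE	chrI	300	353	53	0.01078167116
CNE	chrI	1000	1060	60	0
CNE	chrI	1200	1260	60	0.004761904762
CNE	chrI	1600	1700	100	0.006785714286
CDS	chrI	100	220	120	0.01398809524
CDS	chrI	620	780	160	0.007142857143
CDS	chrI	1410	1490	80	0.005357142857
CDS	chrI	1760	1890	130	0
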