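element_class	n	median_pi	low_count
CNE	4	0.005773809524	True
CDS	4	0.00625	True
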