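cne_id	ref_chrom	ref_start	ref_end	C_brenneri_coords	C_brenneri_status	C_briggsae_coords	C_briggsae_status	C_elegans_coords	C_elegans_status	C_inopinata_coords	C_inopinata_status	C_latens_coords	C_latens_status	C_nigoni_coords	C_nigoni_status	C_niphades_coords	C_niphades_status	C_remanei_coords	C_remanei_status	C_sinica_coords	C_sinica_status	C_tropicalis_coords	C_tropicalis_status	C_wallacei_coords	C_wallacei_status	C_niphades_nearest_gene	C_niphades_gene_distance
CNE00001	chrI	70	100	chrI:70-100	kept	chrI:70-100	kept	chrI:70-100	kept	chrI:70-100	kept	chrI:70-100	kept	chrI:70-100	kept	chrI:70-100	kept	chrI:70-100	kept	chrI:70-100	kept	chrI:70-100	kept	chrI:70-100	kept	g0001	0
CNE00002	chrI	300	353	chrI:300-353	kept	chrI:300-353	kept	chrI:300-353	kept	chrI:300-353	kept	chrI:300-353	kept	chrI:300-353	kept	chrI:300-353	kept	chrI:300-353	kept	chrI:300-353	kept	chrI:300-353	kept	chrI:300-353	kept	g0001	-60
CNE00003	chrI	500	540	chrI:500-540	kept	chrI:500-540	kept	chrI:500-540	kept	chrI:500-540	kept	chrI:500-540	kept	chrI:500-540	kept	chrI:500-540	kept	chrI:500-540	kept	chrI:500-540	kept	chrI:500-540	kept	chrI:500-540	kept	g0002	60
CNE00004	chrI	850	862	chrI:850-862	kept	chrI:850-862	kept	chrI:850-862	kept	chrI:850-862	kept	chrI:850-862	kept	chrI:850-862	kept	chrI:850-862	kept	chrI:850-862	kept	chrI:850-862	kept	chrI:850-862	kept	chrI:850-862	kept	g0002	-50
CNE00005	chrI	1000	1060	chrI:1000-1060	kept	chrI:1000-1060	kept	chrI:1000-1060	kept	chrI:1000-1060	kept	chrI:1000-1130	dropped_length_ratio	chrI:1000-1060	kept	chrI:1000-1060	kept	chrI:1000-1060	kept	chrI:1000-1060	kept	chrI:1000-1060	kept	chrI:1000-1060	kept	g0002	-200
CNE00006	chrI	1200	1260	chrB:5000-5060;chrI:1200-1260	dropped_redundant	chrI:1200-1260	kept	chrI:1200-1260	kept	chrI:1200-1260	kept	chrI:1270-1330	kept	chrI:1200-1260	kept	chrI:1200-1260	kept	chrI:1200-1260	kept	chrI:1200-1260	kept	chrI:1200-1260	kept	chrI:1200-1260	kept	g0003	140
CNE00007	chrI	1600	1700	chrI:1600-1700	kept	chrI:1600-1700	kept	chrI:1600-1700	kept	chrI:1600-1700	kept	chrI:1670-1770	kept	chrI:1600-1700	kept	chrI:1600-1700	kept	chrI:1600-1700	kept	chrI:1600-1700	kept	chrI:1600-1700	kept	chrI:1600-1700	kept	g0004	50
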