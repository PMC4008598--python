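variant_id	chrom	pos	risk_allele	other_allele	odds_ratio	raf	n_cases	n_controls
HLA_DRB1_1501	6		DRB1*15		3.08	0.2013	9772	17376
rs_fix_0001	1		A	G	1.22	0.28	14498	24091
rs_fix_0002	2		T	C	1.15	0.62	14498	24091
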