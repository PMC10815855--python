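gene	gene_id	chrom	pos_mb	mean_expression	has_coding_variant	is_cis_regulated	sig_corr_with_focal	functional_sources
Myl4	17896	11	104.550663	10.8	True	False	True	RGD_causal;KEGG
Ace	11421	11	105.967945	11.7	False	True	True	KEGG
Kpna2	16647	11	106.988629	10.3	True	True	True
Golm1	105348	13	59.640163	9.8	True	True	True
Zfp367	238673	13	64.133022	8.3	True	True	True
Zfp712	78251	13	67.038594	8.6	True	True	True
Zfp759	268670	13	67.128226	8.7	True	True	True
Zfp874a	238692	13	67.426259	8.2	True	True	True
Zfp729a	212281	13	67.617001	10.5	True	True	True
Mtrr	210009	13	68.56078	9.4	True	True	True
Sdha	66945	13	74.322254	14.6	False	False	True	RGD_causal;KEGG
Rhobtb3	73296	13	75.869537	10.0	True	True	True
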