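gene_name	gene_id	chrom_human	start_human	end_human	chrom_mouse	start_mouse	end_mouse	pubmed_id	cancer_type_mouse
DLEU2	ENSG00000231607	chr13	50048971	50049063	chr14	61631880	61631972	24316982	Liver
DLEU2	ENSG00000231607	chr13	50049117	50049206	chr14	61632026	61632110	24316982	Liver
GAS5	ENSG00000234741	chr1	173864370	173864435	chr1	161038091	161038156	25961939	Sarcoma
MONC	ENSG00000215386	chr21	16539096	16539161	chr16	77598935	77599000	23685747	Nervous System
MONC	ENSG00000215386	chr21	16561654	16561655	chr16	77616439	77616440	24316982	Liver
NEAT1	ENSG00000245532	chr11	65444511	65444512	chr19	5825497	5825498	24316982	Liver
PINT	ENSG00000231721	chr7	131049455	131049456	chr6	31179149	31179150	22699621	Pancreatic
PVT1	ENSG00000249859	chr8	128007970	128007971	chr15	62186646	62186647	22699621	Pancreatic
SLNCR1	ENSG00000227036	chr17	72507275	72507276	chr11	113137613	113137614	22699621	Pancreatic
XIST	ENSG00000229807	chrX	73841539	73841540	chrX	103473862	103473863	24316982	Liver
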