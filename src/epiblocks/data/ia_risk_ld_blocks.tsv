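# 16 intracranial-aneurysm risk SNPs and their LD blocks (GRCh37, 1-based inclusive coordinates)
rsid	chrom	start	stop	location_class	nearest_gene
rs3767137	chr1	22160723	22168310	intronic	HSPG2
rs1800255	chr2	189841613	189867882	exonic	COL3A1
rs1429412	chr2	198148191	198223121	intergenic	ANKRD44
rs700651	chr2	198541398	198631714	intronic	BOLL
rs6841581	chr4	148365339	148414651	intergenic	EDNRA
rs251124	chr5	82805424	82826254	intronic	VCAN
rs4628172	chr7	15493884	15506529	intronic	AGMO
rs1800796	chr7	22766246	22771738	intronic	IL6
rs42524	chr7	94043239	94049356	exonic	COL1A2
rs10958409	chr8	55309731	55328116	intergenic	-
rs9298506	chr8	55421614	55462324	intergenic	-
rs2891168	chr9	22072264	22125503	intronic	CDKN2B-AS1
rs10757278	chr9	22077085	22125503	intergenic	CDKN2B-AS1
rs6538595	chr12	95489131	95516843	intronic	FGD6
rs4934	chr14	95078677	95080803	exonic	SERPINA3
rs1132274	chr20	17594030	17600114	exonic	RRBP1
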