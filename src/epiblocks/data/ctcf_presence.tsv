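# Per-block presence (Y/N) of CTCF ChIP-seq binding sites by cell type.
# No CTCF track exists for neutrophils (PNL) or PBMCs: those columns are unavailable.
rsid	HUVEC:CTCF	M0:CTCF	PNL:CTCF	PBMC:CTCF
rs3767137	Y	Y	unavailable	unavailable
rs1800255	N	N	unavailable	unavailable
rs1429412	Y	Y	unavailable	unavailable
rs700651	Y	Y	unavailable	unavailable
rs6841581	N	N	unavailable	unavailable
rs251124	Y	Y	unavailable	unavailable
rs4628172	N	N	unavailable	unavailable
rs1800796	Y	Y	unavailable	unavailable
rs42524	N	N	unavailable	unavailable
rs10958409	Y	N	unavailable	unavailable
rs9298506	Y	N	unavailable	unavailable
rs2891168	N	N	unavailable	unavailable
rs10757278	Y	Y	unavailable	unavailable
rs6538595	N	N	unavailable	unavailable
rs4934	Y	N	unavailable	unavailable
rs1132274	Y	Y	unavailable	unavailable
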