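# Per-block presence (Y/N) of H3K4me1/H3K27ac ChIP-seq peaks by cell type.
# "unavailable" marks (cell type, mark) combinations with no public track.
# HUVEC = umbilical-vein endothelial cells, M0 = CD14+ monocytes,
# PNL = neutrophils, PBMC = peripheral blood mononuclear cells.
rsid	HUVEC:H3K4me1	HUVEC:H3K27ac	M0:H3K4me1	M0:H3K27ac	PNL:H3K4me1	PNL:H3K27ac	PBMC:H3K4me1	PBMC:H3K27ac
rs3767137	Y	N	N	N	N	N	N	unavailable
rs1800255	Y	Y	N	N	N	N	N	unavailable
rs1429412	Y	Y	Y	Y	Y	Y	Y	unavailable
rs700651	Y	Y	Y	Y	Y	Y	Y	unavailable
rs6841581	Y	N	N	N	N	N	N	unavailable
rs251124	Y	Y	Y	Y	N	N	Y	unavailable
rs4628172	Y	N	N	N	N	N	N	unavailable
rs1800796	Y	Y	Y	Y	Y	N	Y	unavailable
rs42524	Y	N	N	N	N	N	N	unavailable
rs10958409	Y	Y	N	N	N	N	N	unavailable
rs9298506	Y	Y	N	N	N	N	N	unavailable
rs2891168	Y	Y	Y	N	N	N	Y	unavailable
rs10757278	Y	Y	Y	N	N	N	Y	unavailable
rs6538595	Y	Y	Y	Y	Y	N	Y	unavailable
rs4934	N	N	N	N	N	N	N	unavailable
rs1132274	Y	N	Y	Y	Y	Y	Y	unavailable
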