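# TF binding sites inside histone-marked segments of the IA-risk LD blocks (HUVEC only).
# distal / promoter: comma-separated TF lists, "-" = none.
# A trailing "*" flags a TF whose site lies in a segment carrying BOTH H3K4me1 and
# H3K27ac; unflagged TFs sit in H3K4me1-only segments.
rsid	distal	promoter
rs3767137	-	POLR2A
rs1800255	FOS,GATA2,JUN	-
rs1429412	FOS,GATA2,JUN	-
rs700651	FOS	MAX*,MYC*,POLR2A*
rs6841581	-	EZH2
rs251124	JUN*	-
rs4628172	FOS	-
rs1800796	FOS*,GATA2*,JUN*,POLR2A*	POLR2A*
rs42524	FOS,JUN	-
rs10958409	FOS,GATA2,JUN	-
rs9298506	-	-
rs2891168	FOS*,GATA2*,JUN*,POLR2A*	-
rs10757278	FOS*,GATA2*,JUN*,POLR2A*	-
rs6538595	FOS*,GATA2*,JUN*,POLR2A*	-
rs4934	-	-
rs1132274	-	-
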