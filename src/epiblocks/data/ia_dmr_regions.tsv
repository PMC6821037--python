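# Differentially methylated regions (aneurysm vs superficial temporal artery tissue)
# that fall inside IA-risk LD blocks (GRCh37, 1-based inclusive coordinates).
# block_rsid records the printed LD-block assignment.
chrom	start	stop	block_rsid
chr2	198173194	198173317	rs1429412
chr4	148413287	148413410	rs6841581
chr20	17595355	17595478	rs1132274
chr20	17595448	17595571	rs1132274
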