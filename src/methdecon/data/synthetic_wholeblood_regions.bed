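chrom	start	end	region_id	Gran	CD4T	CD8T	Bcell	Mono	NK
chr1	1000	1201	dmr0000_Gran_hyper	1	0	0	0	0	0
chr1	6250	6451	dmr0001_Gran_hyper	1	0	0	0	0	0
chr1	11500	11701	dmr0002_Gran_hyper	1	0	0	0	0	0
chr1	16750	16951	dmr0003_Gran_hypo	0	1	1	1	1	1
chr1	22000	22201	dmr0004_Gran_hypo	0	1	1	1	1	1
chr1	27250	27451	dmr0005_Gran_hypo	0	1	1	1	1	1
chr1	32500	32701	dmr0006_CD4T_hyper	0	1	0	0	0	0
chr1	37750	37951	dmr0007_CD4T_hyper	0	1	0	0	0	0
chr1	43000	43201	dmr0008_CD4T_hyper	0	1	0	0	0	0
chr1	48250	48451	dmr0009_CD4T_hypo	1	0	1	1	1	1
chr1	53500	53701	dmr0010_CD4T_hypo	1	0	1	1	1	1
chr1	58750	58951	dmr0011_CD4T_hypo	1	0	1	1	1	1
chr1	64000	64201	dmr0012_CD8T_hyper	0	0	1	0	0	0
chr1	69250	69451	dmr0013_CD8T_hyper	0	0	1	0	0	0
chr1	74500	74701	dmr0014_CD8T_hyper	0	0	1	0	0	0
chr1	79750	79951	dmr0015_CD8T_hypo	1	1	0	1	1	1
chr1	85000	85201	dmr0016_CD8T_hypo	1	1	0	1	1	1
chr1	90250	90451	dmr0017_CD8T_hypo	1	1	0	1	1	1
chr1	95500	95701	dmr0018_Bcell_hyper	0	0	0	1	0	0
chr1	100750	100951	dmr0019_Bcell_hyper	0	0	0	1	0	0
chr1	106000	106201	dmr0020_Bcell_hyper	0	0	0	1	0	0
chr1	111250	111451	dmr0021_Bcell_hypo	1	1	1	0	1	1
chr1	116500	116701	dmr0022_Bcell_hypo	1	1	1	0	1	1
chr1	121750	121951	dmr0023_Bcell_hypo	1	1	1	0	1	1
chr1	127000	127201	dmr0024_Mono_hyper	0	0	0	0	1	0
chr1	132250	132451	dmr0025_Mono_hyper	0	0	0	0	1	0
chr1	137500	137701	dmr0026_Mono_hyper	0	0	0	0	1	0
chr1	142750	142951	dmr0027_Mono_hypo	1	1	1	1	0	1
chr1	148000	148201	dmr0028_Mono_hypo	1	1	1	1	0	1
chr1	153250	153451	dmr0029_Mono_hypo	1	1	1	1	0	1
chr1	158500	158701	dmr0030_NK_hyper	0	0	0	0	0	1
chr1	163750	163951	dmr0031_NK_hyper	0	0	0	0	0	1
chr1	169000	169201	dmr0032_NK_hyper	0	0	0	0	0	1
chr1	174250	174451	dmr0033_NK_hypo	1	1	1	1	1	0
chr1	179500	179701	dmr0034_NK_hypo	1	1	1	1	1	0
chr1	184750	184951	dmr0035_NK_hypo	1	1	1	1	1	0
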