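snp_id	variant_type	gene_symbol	gene_type	expression_pattern
rs1999241	Intron variant	GAD2	protein-coding	Pancreas and brain
rs7645985	Intron variant	LINC01968	ncRNA	Testis and placenta
rs6516709	Intron variant	APP	protein-coding	Brain
rs6078354	Intron variant	LINC00687	ncRNA	Testis
rs7725201	Stop gained	RASGEF1C	protein-coding	Ubiquitous
rs10859918	Intron variant	PGAM1P5	pseudogene	Ubiquitous
rs6110516	Intron variant	MACROD2	protein-coding	Ubiquitous
rs5928104	Intron variant	DMD	protein-coding	Ubiquitous
rs8084397	Intron variant	LOC105372209; LOC105372210	ncRNA	Heart, testis, placenta, and brain
Affx-2716217	Upstream variant	DOCK1	protein-coding	Ubiquitous
rs201036	Non-coding transcript; intron variant	LOC101928047; LOC101928004	ncRNA	Heart, kidney, bone marrow, and fat
rs9965164	Non-coding transcript	LOC105372208	ncRNA	Heart, testis, and placenta
rs3813579	Intron variant	LOC105371356	ncRNA	Liver, testis, kidney, and skin
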