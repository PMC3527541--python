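# VISTA enhancer loci overlapped by DGV-deposited small Indels (100 bp - 1 kb)
enhancer_id	enhancer_position	bracketing_genes	expression	indel_position	indel_id
hs205	chr2:66297527-66299214	Meis1-Spred2	Positive	chr2:66296800-66297653	Variation_115355
hs571	chr13:112793153-112794130	Sox1-1700094C09Rik	Negative	chr13:112793819-112794660	Variation_61360
hs808	chr18:73570346-73571156	Zfp516-Tshz1	Negative	chr18:73569805-73570587	Variation_61640
hs808	chr18:73570346-73571156	Zfp516-Tshz1	Negative	chr18:73569967-73570384	Variation_41944
hs809	chr1:87795192-87796737	Lmo4-Hs2st1	Positive	chr1:87796383-87797017	Variation_69038
hs855	chr11:31989173-31990022	Rcn1-Pax6os1	Positive	chr11:31989283-31989466	Variation_60040
hs1387	chr3:63672828-63674786	Sntn-Thoc7	Positive	chr3:63673334-63673795	Variation_51148
hs1592	chr20:39461549-39463625	Mafb-Top1	Negative	chr20:39462401-39462826	Variation_79198
hs1592	chr20:39461549-39463625	Mafb-Top1	Negative	chr20:39462851-39463076	Variation_90558
hs1592	chr20:39461549-39463625	Mafb-Top1	Negative	chr20:39462851-39463026	Variation_79197
hs1592	chr20:39461549-39463625	Mafb-Top1	Negative	chr20:39462951-39463626	Variation_79196
hs1675	chr17:27994702-27996874	Ssh2(intragenic)	Positive	chr17:27995436-27995598	Variation_60230
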