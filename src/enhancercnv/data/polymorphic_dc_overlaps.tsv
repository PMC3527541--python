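# VISTA enhancer loci localized in genotyped polymorphic-DC CNV regions
enhancer_id	enhancer_position	bracketing_genes	expression	cnv_position	cnv_id
hs7	chr16:79026563-79028162	WWOX (intragenic)	Negative	chr16:79026434-79039202	CNVR6795.1
hs98	chr16:22684122-22685282	CDR2-HS3ST2	Negative	chr16:22551908-22712190	CNVR6669.1
hs445	chr1:83878319-83879217	LPHN2-FLJ23033	Negative	chr1:83598248-83955219	CNVR230.1
hs628	chr9:159657-160780	APOA1	Positive	chr9:48710-209354	CNVR4135.1
hs1339	chr9:92292484-92293889	GADD45G-DIRAS2	Positive	chr9:91963403-92343382	CNVR4393.2
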