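# VISTA enhancer loci localized in validated copy-number-polymorphism (CNP) regions
enhancer_id	enhancer_position	bracketing_genes	expression	cnv_position	cnv_id
hs98	chr16:22684122-22685282	CDR2-HS3ST2	Negative	chr16:22557932-22704521	2157
hs628	chr9:159657-160780	APOA1	Positive	chr9:149481-274606	11533
hs1108	chr9:128945054-128946417	PBX3-FAM125B	Negative	chr9:128944285-128954309	1512
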