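# VISTA enhancer loci deleted in patients: sequencing-confirmed deletion breakpoints
enhancer_id	enhancer_position	sample	deletion_position	bracketing_genes	expression	expression_pattern
hs607	chr12:16,610,045-16,611,936	27	chr12:16606713-16665783	MGST1-LMO3	Positive	hindbrain (rhombencephalon), neural tube
hs676	chr6:97,544,611-97,545,759	25	chr6:97375836-97550891	KIAA1900 (intragenic)	Positive	branchial arch, ear, forebrain, hindbrain
hs775	chr18:77,010,009-77,010,795	01	chr18:77008844-77024003	CDR2-HS3ST2	Positive	forebrain
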