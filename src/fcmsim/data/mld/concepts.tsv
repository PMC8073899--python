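id	label	category
OCT4	octamer-binding transcription factor 4	gene
SOX2	SRY-box transcription factor 2	gene
KLF4	Kruppel-like factor 4	gene
CMYC	cMYC proto-oncogene	gene
B27_MEDIA	B27 neural media with zinc, ascorbate and doxycycline	media_component
ARSA	arylsulfatase A	gene
SULF_CLEARANCE	lysosomal sulfatide clearance machinery	protein
LYSO_STRESS	lysosomal stress	phenotype
SULF_LYS	sulfatides (lysosomal)	phenotype
SULF_REL	sulfatides (released)	phenotype
ASTRO_ACT	astrocyte activation	phenotype
MICRO_ACT	microglial activation	phenotype
DEMYELIN	demyelination	phenotype
NEURODEGEN	neurodegeneration	phenotype
DEMENTIA	dementia	phenotype
SEIZURES	seizures	phenotype
PERIPH_NEURO	peripheral neuropathy	phenotype
OLIGO	oligodendrocyte	cell_type
NEURON	neuron	cell_type
RADIAL_GLIA	radial glia / neural stem cell	cell_type
BBB_FUNC	blood-brain-barrier function	phenotype
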