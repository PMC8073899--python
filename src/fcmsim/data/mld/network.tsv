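# Curated MLD toy cascade: ARSA deficiency -> sulfatide accumulation and
# lysosomal stress -> glial activation -> demyelination -> neurodegeneration.
# Weights are saturating (+-0.5, +-0.8) so sign conclusions are robust.
source	target	weight
ARSA	SULF_LYS	-0.8
ARSA	LYSO_STRESS	-0.8
SULF_CLEARANCE	SULF_LYS	-0.8
SULF_CLEARANCE	SULF_REL	-0.8
SULF_LYS	SULF_REL	0.8
SULF_LYS	ASTRO_ACT	0.8
SULF_LYS	OLIGO	-0.8
LYSO_STRESS	MICRO_ACT	0.8
ASTRO_ACT	DEMYELIN	0.8
MICRO_ACT	DEMYELIN	0.5
MICRO_ACT	NEURODEGEN	0.5
DEMYELIN	NEURODEGEN	0.8
NEURODEGEN	DEMENTIA	0.8
NEURODEGEN	SEIZURES	0.8
SULF_REL	PERIPH_NEURO	0.8
DEMYELIN	BBB_FUNC	-0.5
B27_MEDIA	RADIAL_GLIA	0.5
OCT4	RADIAL_GLIA	0.5
SOX2	RADIAL_GLIA	0.5
KLF4	RADIAL_GLIA	0.5
CMYC	RADIAL_GLIA	0.5
RADIAL_GLIA	NEURON	0.8
B27_MEDIA	OLIGO	0.5
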