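# Default internal mass standards for MALDI reflector spectra.
# name <tab> theoretical MH+ (Da) <tab> kind (matrix_standard | autolysis)
#
# ACTH clip 18-39 is a corticotropin fragment spiked into the matrix.
# RfffR (f = pentafluoro-phenylalanine) is a synthetic matrix standard; its
# MH+ here is the value quoted by its supplier and is user-editable because
# the pentafluoro-Phe residue mass is not standardised.
# The autolysis entries are the usual porcine trypsin self-digestion peaks
# that are present in any in-gel tryptic digest; edit to match your enzyme lot.
ACTH_18-39	2465.199	matrix_standard
RfffR	1042.276	matrix_standard
trypsin_842	842.5099	autolysis
trypsin_1045	1045.5642	autolysis
trypsin_1469	1469.7305	autolysis
trypsin_2211	2211.1046	autolysis
trypsin_2283	2283.1807	autolysis
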