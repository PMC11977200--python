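# NOR-bearing chromosome per species.  Hymenochirus sp. carries no state
# homologous to the Xenopus labels and is listed with an empty cell; it is
# pruned before parsimony.
species,nor_chromosome
X_laevis,3L
X_gilli,3L
X_petersii,3L
X_pygmaeus,6S
X_parafraseri,6S
X_clivii,4L
X_borealis,4L
X_muelleri,5L
X_tropicalis,7
X_calcaratus,7a
X_epitropicalis,7a
X_mellotropicalis,7a
Hymenochirus_sp,
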