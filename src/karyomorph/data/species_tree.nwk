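[Schematic pipid species tree. Hymenochirus sp. is the outgroup. Subgenus Silurana: X. tropicalis (diploid) plus the tetraploids X. calcaratus, X. epitropicalis and X. mellotropicalis, the latter two sisters. Subgenus Xenopus: X. clivii is the sister lineage of the X. muelleri species group (X. muelleri, X. borealis), which together branch first; the X. laevis species group (X. laevis, X. gilli, X. petersii) and the X. amieti species group (X. pygmaeus, X. parafraseri) are sisters.]
(Hymenochirus_sp,((X_tropicalis,(X_calcaratus,(X_epitropicalis,X_mellotropicalis))),((X_clivii,(X_muelleri,X_borealis)),((X_laevis,(X_gilli,X_petersii)),(X_pygmaeus,X_parafraseri)))));
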