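# Xenopus pygmaeus karyotype template: per-type medians of chromosome length
# (l, % of total metaphase length), centromeric index (i, 0-50) and p/q arm
# ratio (r1), with the Levan-interval category.  The published 4L i cell is
# corrupted by spreadsheet date-formatting; its i here is derived from the
# printed arm ratio r1 = 0.30 via i = 100*r1/(1+r1) = 23.0769.
type_label,l_pct_median,i_median,category,subgenome,r1_median
1L,4.25,41.35,m,L,0.70
1S,3.69,40.49,m,S,0.68
2L,3.45,37.82,m,L,0.61
2S,3.09,35.85,sm,S,0.56
3L,2.94,20.00,st,L,0.25
3S,2.74,21.97,st,S,0.28
4L,2.8,23.0769,st,L,0.30
4S,2.44,20.29,st,S,0.26
5L,3.03,39.22,m,L,0.64
5S,2.77,38.08,m,S,0.62
6L,3.03,48.19,m,L,0.93
6S,2.67,42.13,m,S,0.72
7L,2.42,41.91,m,L,0.72
7S,1.93,42.77,m,S,0.75
8L,2.46,21.73,st,L,0.28
8S,1.71,44.49,m,S,0.80
9_10L,2.38,20.80,st,L,0.26
9_10S,2.21,24.24,st,S,0.32
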