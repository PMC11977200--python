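# Xenopus laevis marker map from genome-database annotation.  cept1 is
# annotated only in the S-subgenome (2S q arm, distal of the centromere at
# ~54-55 Mb) and gyg2 only in the L-subgenome (2L p arm).  fn1, ndufs1 and
# sf3b1 are annotated on both 9_10 homeologs; the 9_10L q-arm ranks follow
# the shared q-q fusion geometry (ancestral 9q genes proximal, 9p distal).
species,gene,chromosome,arm,rank,region,copy
X_laevis,cept1,2S,q,1,pericentromeric,S
X_laevis,gyg2,2L,p,1,pericentromeric,L
X_laevis,fn1,9_10L,q,1,interstitial,L
X_laevis,ndufs1,9_10L,q,2,interstitial,L
X_laevis,sf3b1,9_10L,q,3,interstitial,L
X_laevis,nomo3,9_10L,q,4,interstitial,L
X_laevis,bmp7,9_10L,p,1,interstitial,L
X_laevis,sox9,9_10L,p,2,interstitial,L
X_laevis,fn1,9_10S,q,1,interstitial,S
X_laevis,ndufs1,9_10S,q,2,interstitial,S
X_laevis,sf3b1,9_10S,q,3,interstitial,S
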