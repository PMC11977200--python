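# Xenopus pygmaeus FISH-mapped marker loci.  cept1 and gyg2 hybridize to both
# chromosomes 2L (p arm) and 2S (q arm); their homeologous copy is unresolved
# (copy = none).  fn1.L, ndufs1.L and nomo3.L sit on the 9_10L q arm with the
# ancestral-9q genes proximal and the ancestral-9p gene (nomo3) distal;
# bmp7.L and sox9.L sit on the 9_10L p arm; sf3b1.S sits on the 9_10S q arm.
# Ranks along 9_10L follow the observed q-q fusion geometry.
species,gene,chromosome,arm,rank,region,copy
X_pygmaeus,cept1,2L,p,1,pericentromeric,none
X_pygmaeus,gyg2,2L,p,2,pericentromeric,none
X_pygmaeus,cept1,2S,q,1,pericentromeric,none
X_pygmaeus,gyg2,2S,q,2,pericentromeric,none
X_pygmaeus,fn1,9_10L,q,1,interstitial,L
X_pygmaeus,ndufs1,9_10L,q,2,interstitial,L
X_pygmaeus,nomo3,9_10L,q,3,interstitial,L
X_pygmaeus,bmp7,9_10L,p,1,interstitial,L
X_pygmaeus,sox9,9_10L,p,2,interstitial,L
X_pygmaeus,sf3b1,9_10S,q,1,interstitial,S
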