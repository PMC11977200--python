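# Xenopus mellotropicalis (allotetraploid, subgenus Silurana) marker map.
# The a-subgenome copies retain the ancestral X. tropicalis arrangement; in
# the b-subgenome, sf3b1 has been translocated from chromosome 9b to the
# pericentromeric region of chromosome 2b.
species,gene,chromosome,arm,rank,region,copy
X_mellotropicalis,cept1,2a,p,1,pericentromeric,a
X_mellotropicalis,gyg2,2a,p,2,pericentromeric,a
X_mellotropicalis,nomo3,9a,p,1,interstitial,a
X_mellotropicalis,sf3b1,9a,q,1,pericentromeric,a
X_mellotropicalis,ndufs1,9a,q,2,interstitial,a
X_mellotropicalis,fn1,9a,q,3,interstitial,a
X_mellotropicalis,bmp7,10a,p,1,interstitial,a
X_mellotropicalis,sox9,10a,q,1,interstitial,a
X_mellotropicalis,cept1,2b,p,1,pericentromeric,b
X_mellotropicalis,gyg2,2b,p,2,pericentromeric,b
X_mellotropicalis,sf3b1,2b,q,1,pericentromeric,b
X_mellotropicalis,nomo3,9b,p,1,interstitial,b
X_mellotropicalis,ndufs1,9b,q,1,interstitial,b
X_mellotropicalis,fn1,9b,q,2,interstitial,b
X_mellotropicalis,bmp7,10b,p,1,interstitial,b
X_mellotropicalis,sox9,10b,q,1,interstitial,b
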