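# Xenopus tropicalis (diploid, subgenus Silurana) marker map.  Positions are
# treated as ancestral: cept1/gyg2 on the 2p pericentromeric region; sf3b1,
# ndufs1, fn1 on 9q with sf3b1 proximal (it is the pericentromeric-block gene
# moved by the Silurana 9-2 translocation); nomo3 on 9p; bmp7 on 10p; sox9 on
# 10q.  Ranks count 1-based from the centromere outward; intra-arm order is a
# fixture convention consistent with the rearrangement geometry.
species,gene,chromosome,arm,rank,region,copy
X_tropicalis,cept1,2,p,1,pericentromeric,none
X_tropicalis,gyg2,2,p,2,pericentromeric,none
X_tropicalis,nomo3,9,p,1,interstitial,none
X_tropicalis,sf3b1,9,q,1,pericentromeric,none
X_tropicalis,ndufs1,9,q,2,interstitial,none
X_tropicalis,fn1,9,q,3,interstitial,none
X_tropicalis,bmp7,10,p,1,interstitial,none
X_tropicalis,sox9,10,q,1,interstitial,none
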