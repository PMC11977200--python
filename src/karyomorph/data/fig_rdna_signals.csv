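# Xenopus pygmaeus rDNA FISH signal table.  One 28S (NOR) signal on the 6S
# long-arm telomere; 5S signals in telomeric regions of all chromosome types
# except 8S, on both arms of 2L, co-localized with 28S on 6S, and with low
# intensity on 4L and 5L.  Single-arm 5S signals are recorded on the q arm
# as a fixture convention (the observation is telomeric, not arm-resolved).
probe,chromosome,arm,region,intensity
28S,6S,q,telomeric,normal
5S,1L,q,telomeric,normal
5S,1S,q,telomeric,normal
5S,2L,both,telomeric,normal
5S,2S,q,telomeric,normal
5S,3L,q,telomeric,normal
5S,3S,q,telomeric,normal
5S,4L,q,telomeric,low
5S,4S,q,telomeric,normal
5S,5L,q,telomeric,low
5S,5S,q,telomeric,normal
5S,6L,q,telomeric,normal
5S,6S,q,telomeric,normal
5S,7L,q,telomeric,normal
5S,7S,q,telomeric,normal
5S,8L,q,telomeric,normal
5S,9_10L,q,telomeric,normal
5S,9_10S,q,telomeric,normal
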