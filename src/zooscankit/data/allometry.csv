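taxon,a,b,area_min_mm2,area_max_mm2
Actinopterygii (eggs and larvae),43.38,1.54,0.079,1.198
Appendicularia,43.38,1.54,0.056,6.071
Ascidiacea (larvae),43.38,1.54,0.072,1.652
Amphipoda,43.38,1.54,0.103,59.854
Brachiopoda (larvae),43.38,1.54,0.193,0.366
Bivalvia (larvae),43.38,1.54,0.071,2.040
Bryozoa (larvae),43.38,1.54,0.067,0.240
Chaetognatha,23.45,1.19,0.068,15.935
Cirripedia (larvae and cypris),43.38,1.54,0.071,0.286
Cladocera,43.38,1.54,0.072,0.455
Cnidaria,4.03,1.24,0.051,95.743
Copepoda,43.97,1.52,0.068,9.177
Decapoda (zoea),43.38,1.54,0.072,6.733
Echinodermata,43.38,1.54,0.070,0.757
Euphausiacea,43.38,1.54,0.145,461.813
Eggs,43.38,1.54,0.070,1.952
Gastropoda (larvae),43.38,1.54,0.071,2.266
Isopoda,43.38,1.54,0.073,0.930
Mysidacea,43.38,1.54,0.126,43.504
Nemertea (pilidium),43.38,1.54,0.082,0.777
Ostracoda,43.38,1.54,0.066,1.270
Platyhelminthes (larvae),43.38,1.54,0.075,0.162
Polychaeta (larvae),43.38,1.54,0.068,7.535
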