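pathway	reaction
alanine_biosynthesis	rxn00260
alanine_degradation	rxn00261
arginine_biosynthesis	rxn00433
arginine_biosynthesis	rxn00435
arginine_degradation	rxn00553
aspartate_biosynthesis	rxn00337
aspartate_degradation	rxn00340
glutamate_biosynthesis	rxn00182
glutamate_biosynthesis	rxn00187
glutamate_degradation	rxn00189
glycine_biosynthesis	rxn00692
glycine_degradation	rxn00693
histidine_biosynthesis	rxn02160
histidine_degradation	rxn02465
methionine_biosynthesis	rxn01304
methionine_degradation	rxn01739
proline_biosynthesis	rxn01434
proline_degradation	rxn01438
tryptophan_biosynthesis	rxn00726
tryptophan_degradation	rxn00727
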