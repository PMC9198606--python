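Ligand gene symbol,Receptor gene symbol
COL1A1,ITGA2
COL1A2,ITGA2
COL8A1,ITGA2
FN1,ITGA2
HSPG2,ITGA2
LAMA1,ITGA2
LAMA1,ITGA6
LAMB1,ITGA6
FN1,ITGB1
COL1A1,ITGB1
LAMA1,ITGA3
LAMB1,ITGB4
FN1,ITGB6
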