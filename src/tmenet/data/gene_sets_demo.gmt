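CELL_JUNCTION_ORGANIZATION	synthetic demo set: junction/adhesion molecules	ITGA2	ITGA3	ITGA6	ITGB1	ITGB4	ITGB6	COL1A1	COL1A2	COL8A1	FN1	HSPG2	LAMA1	LAMB1	CDH5	EPCAM
CELL_COMMUNICATION	synthetic demo set: communication mediators	ITGA2	ITGA6	ITGB1	COL1A1	COL8A1	FN1	HSPG2	LAMA1	MS4A1	CD3E	ITGAM
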