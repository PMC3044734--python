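gene	cnv_seed	huge_seed
ABCA1	N	N
ABCB1	Y	Y
ABCB4	Y	Y
AGL	Y	N
ANK3	N	N
AP4M1	Y	N
ATXN1	N	Y
BDNF	N	Y
CANX	N	N
CHRNA7	Y	Y
GABRA1	Y	Y
GABRG2	Y	Y
HAX1	N	N
MAPK1	N	N
MDFI	N	N
NPY	N	Y
PRKACA	N	N
RXRA	N	N
UBB	N	N
UBQLN4	N	N
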