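# Small curated ligand-receptor pair table for BCP-ALL crosstalk analysis.
# Directed pairs (ligand -> receptor) drawn from public L-R interaction
# resources; includes the B-cell / myeloid pairs highlighted in the BCP-ALL
# bone-marrow literature plus a few canonical signaling axes.
ligand,receptor,source
CTHRC1,FZD6,curated
S100A9,TLR4,curated
APP,TNFRSF21,curated
MDK,SDC1,curated
MDK,GPC2,curated
UBC,LDLR,curated
LAMB1,ITGB4,curated
B2M,LILRB1,curated
B2M,KLRD1,curated
B2M,HFE,curated
JAG1,NOTCH3,curated
SLIT2,ROBO1,curated
ANGPT1,TIE1,curated
INHBA,ACVR2B,curated
CEACAM1,CEACAM1,curated
HMGB1,TLR6,curated
NRTN,GFRA2,curated
VEGFB,FLT1,curated
DLL1,NOTCH3,curated
JAG1,NOTCH1,curated
MDK,LRP1,curated
APOE,LDLR,curated
PTN,SDC1,curated
LAMB1,ITGB1,curated
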