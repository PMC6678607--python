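gene,category,weight
HLA-A,MHC,1.0
HLA-B,MHC,1.0
HLA-C,MHC,1.0
HLA-E,MHC,1.0
HLA-F,MHC,1.0
HLA-DPA1,MHC,1.0
HLA-DPB1,MHC,1.0
TAP1,MHC,1.0
TAP2,MHC,1.0
B2M,MHC,1.0
CD27,immunomodulator,1.0
ICOS,immunomodulator,1.0
CD40,immunomodulator,1.0
CD274,immunomodulator,-1.0
CTLA4,immunomodulator,-1.0
PDCD1,immunomodulator,-1.0
LAG3,immunomodulator,-1.0
TIGIT,immunomodulator,-1.0
IDO1,immunomodulator,-1.0
CD8A,effector,1.0
GZMA,effector,1.0
GZMB,effector,1.0
PRF1,effector,1.0
IFNG,effector,1.0
TBX21,effector,1.0
NKG7,effector,1.0
FOXP3,suppressor,-1.0
IL10,suppressor,-1.0
TGFB1,suppressor,-1.0
CCR8,suppressor,-1.0
ENTPD1,suppressor,-1.0
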