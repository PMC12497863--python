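ligand,receptor,role,ge2,ge10
TNFSF10,TNFRSF10A,Activation,YES,YES
TNF,TNFRSF1A,Activation,YES,YES
SEMA7A,PLXNC1,Memory generation,YES,
SEMA4D,CD72,Effector function,YES,YES
SELPLG,SELP,Migration/Infiltration,YES,
SELPLG,SELL,Migration/Infiltration,YES,YES
CD274,PDCD1,Regulatory function,YES,
GZMA,F2R,Regulatory function,YES,
DLL1,NOTCH1,Effector function,YES,YES
TNFSF14,TNFRSF14,Activation,YES,YES
ITGAL/ITGB2,CD226,Activation/Effector function,YES,YES
FASLG,FAS,Regulatory function,YES,YES
EFNA1,EPHA4,Regulatory function,YES,
CD99,PILRA,Activation,YES,
CD6,ALCAM,Effector function,YES,YES
BAG6,NCR3,Effector function,YES,
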