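marker,case,comparison,sensitivity,specificity,quality_factor
Bim,P15,Expert 2,0.7090,0.9459,0.8275
Bim,P15,IP_OHTA,0.5444,0.9048,0.7246
Bim,P18,Expert 2,0.8579,0.6622,0.7601
Bim,P18,IP_OHTA,0.8262,0.6228,0.7245
Bim,P26,Expert 2,0.9294,0.4940,0.7117
Bim,P26,IP_OHTA,0.8982,0.5577,0.7280
Mcl-1,P25,Expert 2,0.7090,0.9459,0.8275
Mcl-1,P25,IP_OHTA,0.5444,0.9048,0.7246
Mcl-1,P29,Expert 2,0.8579,0.6622,0.7601
Mcl-1,P29,IP_OHTA,0.8262,0.6228,0.7245
Mcl-1,P37,Expert 2,0.9294,0.4940,0.7117
Mcl-1,P37,IP_OHTA,0.8982,0.5577,0.7280
P-ERK,P19,Expert 2,0.9785,0.9205,0.9495
P-ERK,P19,IP_OHTA,0.8943,0.7586,0.8265
P-ERK,P26,Expert 2,0.9939,0.7705,0.8822
P-ERK,P26,IP_OHTA,0.9864,0.4571,0.7218
P-ERK,P36,Expert 2,0.9667,0.8264,0.8966
P-ERK,P36,IP_OHTA,0.9152,0.8085,0.8619
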