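marker,case,i_moy,i_sig,i_skw,cp1
Bim,P10,0.37,0.035,0.178,-1.208
Bim,P12,0.312,0.025,0.679,-2.795
Bim,P13,0.335,0.04,0.208,-1.187
Bim,P14,0.476,0.044,0.129,0.263
Bim,P15,0.531,0.039,0.097,0.479
Bim,P17,0.435,0.058,0.642,0.296
Bim,P18,0.414,0.033,0.488,-1.237
Bim,P19,0.561,0.055,-0.447,2.22
Bim,P21,0.42,0.037,0.666,-1.148
Bim,P22,0.515,0.04,0.103,0.384
Bim,P24,0.525,0.048,0.501,0.54
Bim,P25,0.508,0.054,-0.155,1.433
Bim,P26,0.425,0.036,0.594,-1.065
Bim,P27,0.449,0.053,-0.204,0.924
Bim,P28,0.556,0.039,-1.087,1.844
Bim,P29,0.425,0.042,1.374,-1.483
Bim,P30,0.588,0.064,0.18,2.375
Bim,P31,0.452,0.042,-0.461,0.535
Bim,P32,0.344,0.036,0.988,-2.157
Bim,P33,0.494,0.045,0.391,0.249
Bim,P34,0.464,0.056,-0.157,1.167
Bim,P35,0.379,0.029,0.41,-1.68
Bim,P36,0.588,0.046,0.236,1.191
Bim,P37,0.426,0.036,0.303,-0.78
Bim,P38,0.445,0.05,-0.319,0.841
Mcl-1,P10,0.316,0.026,1.307,-2.74
Mcl-1,P12,0.36,0.035,1.193,-1.47
Mcl-1,P13,0.402,0.037,0.738,-0.25
Mcl-1,P14,0.449,0.041,0.483,0.928
Mcl-1,P15,0.411,0.034,1.235,-0.989
Mcl-1,P17,0.404,0.064,0.434,1.92
Mcl-1,P18,0.47,0.04,1.467,-0.216
Mcl-1,P19,0.471,0.048,0.481,1.648
Mcl-1,P21,0.406,0.034,0.81,-0.498
Mcl-1,P22,0.465,0.04,0.923,0.449
Mcl-1,P24,0.384,0.039,0.626,-0.217
Mcl-1,P25,0.494,0.047,-0.13,2.683
Mcl-1,P26,0.45,0.036,0.616,0.456
Mcl-1,P27,0.436,0.03,0.97,-0.553
Mcl-1,P28,0.512,0.038,0.425,1.559
Mcl-1,P29,0.363,0.036,1.405,-1.653
Mcl-1,P30,0.425,0.035,-0.033,0.927
Mcl-1,P31,0.397,0.033,1.297,-1.271
Mcl-1,P32,0.361,0.033,0.865,-1.18
Mcl-1,P33,0.405,0.051,1.153,0.128
Mcl-1,P34,0.41,0.058,0.185,1.948
Mcl-1,P35,0.426,0.032,1.251,-0.936
Mcl-1,P36,0.452,0.042,1.242,0.049
Mcl-1,P37,0.427,0.034,1.364,-0.96
Mcl-1,P38,0.422,0.031,0.294,0.238
P-ERK,P10,0.009,0.055,6.372,-4.08
P-ERK,P12,0.185,0.188,0.083,-0.951
P-ERK,P13,0.356,0.227,-0.711,0.228
P-ERK,P14,0.269,0.172,-0.798,-0.23
P-ERK,P15,0.423,0.146,-2.325,1.064
P-ERK,P17,0.449,0.069,-3.731,1.623
P-ERK,P18,0.344,0.205,-1.021,0.255
P-ERK,P19,0.477,0.168,-2.162,1.301
P-ERK,P21,0.033,0.121,3.374,-2.894
P-ERK,P22,0.39,0.03,-0.278,0.123
P-ERK,P24,0.267,0.25,-0.083,-0.429
P-ERK,P25,0.188,0.234,0.505,-1.051
P-ERK,P26,0.131,0.172,0.606,-1.419
P-ERK,P27,0.235,0.21,-0.184,-0.588
P-ERK,P28,0.46,0.169,-2.072,1.184
P-ERK,P29,0.268,0.178,-0.763,-0.241
P-ERK,P30,0.432,0.176,-1.596,0.886
P-ERK,P31,0.398,0.169,-1.781,0.769
P-ERK,P32,0.298,0.161,-1.217,0.052
P-ERK,P33,0.39,0.205,-1.225,0.56
P-ERK,P34,0.407,0.219,-1.106,0.617
P-ERK,P35,0.531,0.093,-3.931,2.13
P-ERK,P36,0.296,0.231,-0.444,-0.173
P-ERK,P37,0.469,0.133,-2.982,1.513
P-ERK,P38,0.269,0.184,-0.729,-0.248
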