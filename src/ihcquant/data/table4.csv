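marker,case,n0,n1,n2,r50_pct,ip_label,expert_label
Bim,P10,198,770,0,,high,high
Bim,P12,1204,162,0,,low,low
Bim,P13,512,415,0,,low,low
Bim,P14,0,366,143,,high,high
Bim,P15,0,92,338,,high,high
Bim,P17,0,8,2,,high,high
Bim,P18,5,649,9,,high,high
Bim,P19,0,42,297,,high,high
Bim,P21,10,1410,38,,high,high
Bim,P22,0,49,77,,high,high
Bim,P24,0,795,1367,,high,high
Bim,P25,2,707,942,,high,high
Bim,P26,0,1791,58,,high,low
Bim,P27,27,849,175,,high,high
Bim,P28,0,60,768,,high,high
Bim,P29,4,2129,114,,high,low
Bim,P30,0,30,315,,high,high
Bim,P31,22,2107,240,,high,high
Bim,P32,711,636,4,,low,high
Bim,P33,0,976,703,,high,high
Bim,P34,13,563,206,,high,high
Bim,P35,36,369,1,,high,low
Bim,P36,0,38,1603,,high,high
Bim,P37,7,2086,64,,high,high
Bim,P38,20,492,75,,high,high
Mcl-1,P10,919,36,2,,low,low
Mcl-1,P12,653,246,37,,low,high
Mcl-1,P13,111,466,94,,high,high
Mcl-1,P14,9,193,227,,high,high
Mcl-1,P15,36,374,77,,high,high
Mcl-1,P17,71,53,54,,low,high
Mcl-1,P18,3,137,715,,high,high
Mcl-1,P19,2,92,261,,high,high
Mcl-1,P21,157,1005,209,,high,low
Mcl-1,P22,0,61,146,,high,high
Mcl-1,P24,784,807,181,,high,low
Mcl-1,P25,8,253,1664,,high,high
Mcl-1,P26,3,1007,1202,,high,low
Mcl-1,P27,10,513,391,,high,high
Mcl-1,P28,0,9,801,,high,high
Mcl-1,P29,1231,634,62,,low,low
Mcl-1,P30,21,291,136,,high,high
Mcl-1,P31,410,1735,199,,high,low
Mcl-1,P32,654,301,22,,low,low
Mcl-1,P33,295,595,239,,high,low
Mcl-1,P34,177,279,207,,high,high
Mcl-1,P35,3,338,92,,high,low
Mcl-1,P36,1,948,1221,,high,high
Mcl-1,P37,32,1579,578,,high,high
Mcl-1,P38,27,416,162,,high,high
P-ERK,P10,949,20,1,0.10,low,low
P-ERK,P12,589,514,20,1.78,low,low
P-ERK,P13,278,322,438,42.20,low,low
P-ERK,P14,210,420,23,3.52,low,low
P-ERK,P15,52,178,298,56.44,high,low
P-ERK,P17,2,74,65,46.10,low,high
P-ERK,P18,207,264,332,41.34,low,high
P-ERK,P19,44,52,343,78.13,high,high
P-ERK,P21,1284,40,59,4.27,low,low
P-ERK,P22,0,30,0,0.00,low,high
P-ERK,P24,896,302,745,38.34,low,low
P-ERK,P25,1225,389,420,20.65,low,low
P-ERK,P26,1112,529,10,0.61,low,low
P-ERK,P27,593,664,88,6.54,low,low
P-ERK,P28,103,107,729,77.64,high,low
P-ERK,P29,577,1250,60,3.18,low,low
P-ERK,P30,57,138,253,56.47,high,low
P-ERK,P31,275,716,889,47.29,low,low
P-ERK,P32,263,910,28,2.33,low,low
P-ERK,P33,348,380,961,56.90,high,low
P-ERK,P34,196,199,545,57.98,high,high
P-ERK,P35,9,19,380,93.14,high,high
P-ERK,P36,942,654,924,36.67,low,low
P-ERK,P37,201,228,2417,84.93,high,high
P-ERK,P38,488,1019,27,1.76,low,low
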