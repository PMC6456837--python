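age,n,d_cm,h_m,f,tv_ref,mai_ref,pai_ref
3,2500,5.0,2.0,0.85,8.34,2.78,
7,1750,7.2,4.0,0.82,23.36,3.34,3.75
10,1700,8.4,5.0,0.8,37.66,3.77,4.77
13,1650,9.2,6.3,0.77,53.18,4.09,5.17
15,1600,9.9,7.0,0.75,64.63,4.31,5.72
18,1550,11.3,7.5,0.72,83.90,4.66,6.42
20,1390,12.0,9.0,0.7,98.99,4.95,7.55
23,1210,14.2,9.5,0.68,123.73,5.38,8.25
25,1100,15.0,10.5,0.66,134.64,5.39,5.46
30,950,17.5,11.0,0.63,158.27,5.28,4.73
35,940,18.5,11.5,0.60,174.26,4.98,3.20
40,870,19.4,12.0,0.60,185.07,4.63,2.16
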