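age,n,d_cm,h_m,f,tv_ref,mai_ref,pai_ref
18,1460,12.0,8.3,0.72,98.63,5.48,
20,1250,13.0,10.0,0.70,116.08,5.80,8.73
23,950,17.0,10.5,0.68,153.88,6.69,12.60
25,780,19.0,11.5,0.66,167.77,6.71,6.94
30,740,21.0,12.0,0.63,193.67,6.46,5.18
35,630,24.0,12.5,0.60,213.65,6.10,4.00
40,530,26.0,13.0,0.60,229.50,5.74,3.17
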