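net_income_midr,cost_midr,household_size
14.5,7,3
14.5,7,3
14.5,7,3
18.5,8,3
18.5,8,3
18.5,8,3
18.5,8,3
22.5,9,4
22.5,9,4
22.5,9,4
22.5,9,4
22.5,9,4
26.5,10,5
26.5,10,5
26.5,10,5
26.5,10,5
26.5,10,5
26.5,10,5
26.5,10,5
26.5,10,5
30.5,12,5
30.5,12,5
30.5,12,5
30.5,12,5
30.5,12,5
30.5,12,5
34.5,14,3
34.5,14,3
34.5,14,3
34.5,14,3
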