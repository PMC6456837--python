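net_midr,cost_midr,nrr_ref
14.5,7,9.8
18.5,8,10.5
22.5,9,11.0
26.5,10,11.4
30.5,12,11.1
34.5,14,10.9
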