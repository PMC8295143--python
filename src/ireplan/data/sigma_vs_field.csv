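field_V_per_m,value
10000.0,0.065
25000.0,0.078015625
40000.0,0.10665
55000.0,0.13528437499999998
70000.0,0.1483
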