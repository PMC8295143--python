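temperature_C,value
37.0,50000.0
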