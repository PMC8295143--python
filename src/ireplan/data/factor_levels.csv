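level,active_length_mm,distance_mm,voltage_V,pulse_number,pulse_width_us
1,10.0,10,1000,30,40
2,15.0,15,2000,60,70
3,,20,3000,90,100
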