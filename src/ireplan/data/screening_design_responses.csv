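run_id,active_length_mm,distance_mm,voltage_V,pulse_number,pulse_width_us,ablation_area_mm2,max_temperature_C,thermal_damage
1,10,10,1000,30,40,68.79,37.58,False
2,10,10,2000,60,70,135.56,43.67,False
3,10,10,3000,90,100,216.57,62.9,True
4,10,15,1000,30,70,9.46,37.0,False
5,10,15,2000,60,100,192.34,42.29,False
6,10,15,3000,90,40,297.33,43.34,False
7,10,20,1000,60,40,1.35,37.0,False
8,10,20,2000,90,70,208.79,39.82,False
9,10,20,3000,30,100,330.24,42.21,False
10,15,10,1000,90,100,95.03,39.66,False
11,15,10,2000,30,40,157.81,39.53,False
12,15,10,3000,60,70,237.69,52.61,True
13,15,15,1000,60,100,10.5,37.3,False
14,15,15,2000,90,40,216.62,39.88,False
15,15,15,3000,30,70,313.66,43.27,False
16,15,20,1000,90,70,4.74,37.35,False
17,15,20,2000,30,100,215.8,39.34,False
18,15,20,3000,60,40,375.46,40.61,False
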