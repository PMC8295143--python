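response,rsm_predicted,simulated,relative_error_pct
ablation_area_mm2,268.07,250.82,6.43
max_temperature_C,49.98,45.36,9.24
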