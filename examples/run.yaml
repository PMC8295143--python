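# Example study configuration for ire-plan (clinician units: mm, µs, V).
# Any omitted key keeps its default.
domain:
  width_mm: 60.0
  height_mm: 60.0
  spacing_mm: 0.25
  margin_mm: 15.0
electrode_diameter_mm: 1.0
insertion_depth_mm: 20.0
frequency_hz: 1.0
dt_s: 0.1
screening_spacing_mm: 0.5
verification_spacing_mm: 0.25
ablation_threshold: 80000.0    # V/m (800 V/cm)
damage_limit: 50.0             # C
perfusion: true
area_importance: 0.25
seed: 0
output_dir: ireplan_out
# tissue:
#   sigma_vs_field_csv: my_sigma.csv     # recalibrate the conductivity curve
#   k_vs_temperature_csv: my_k.csv
# blood:
#   perfusion_rate: 0.0                  # ex vivo: no perfusion
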