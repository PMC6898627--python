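label: ethionamide_table1
drug:
  name: ethionamide
  solubility_mg_per_mL: 0.46
  intrinsic_dissolution_rate_mg_per_cm2_min: 0.06
  particle_diameter_um: 3.6
  density_g_per_cm3: 1.0
  permeability_exp_cm_per_min: 5.3e-4
  membrane_thickness_exp_um: 62.5
apparatus:
  membrane_area_cm2: 4.91
  membrane_thickness_um: 62.5
  mucus_volume_uL: 25.0
  receiver_volume_uL: 500.0
  perfusate_flow_mL_per_min: 0.4
run:
  dose_ug: 50.0
  dose_form: particles
  stirring: well_stirred
  t_end_min: 120.0
  dt_min: 0.01
  integrator: rk4
  output_stride_min: 1.0
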