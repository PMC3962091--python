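# memflux_version = 0.1.0
# F_C_per_mol = 96485.0
# R_J_per_molK = 8.314
# T_K = 310.15
# sign_convention = positive flux = blood to dialysate
# lambda_convention = lam = (d_max/2)/b (solute radius)
# eta_exponent = 1.4
# double_hindrance = True
# d0_source = reference
# diffusivity_units = cm^2/s
# seed = 0
# membrane_a = highflux_fiber
# membrane_b = nanofab_1um
toxin	d_max_nm	k_diff_a	k_diff_b	d0	d_eff_a	d_eff_b	ratio_b_over_a
Endothelin	2.60	7.847486e-04	7.209947e-01	1.911440e-06	1.500000e-09	1.378138e-06	9.187589e+02
Cystatin C	4.08	7.847486e-04	5.807265e-01	9.812060e-07	7.700000e-10	5.698124e-07	7.400161e+02
Interleukin-6	5.18	7.847486e-04	4.856032e-01	6.881185e-07	5.400000e-10	3.341526e-07	6.188011e+02
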