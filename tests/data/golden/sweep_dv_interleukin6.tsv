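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
# toxin = Interleukin-6
# membrane = nanofab_1um
# d_eff_cm2_s = 3.341526e-07
# electromigration = per unit valence
delta_V_mV	J_diffusion	J_electromigration	J_pH	J_convection	J_ultrafiltration	J_total
10	-0.000000e+00	7.956612e-15	8.095104e-13	0.000000e+00	0.000000e+00	8.174670e-13
20	-0.000000e+00	1.591322e-14	8.095104e-13	0.000000e+00	0.000000e+00	8.254236e-13
30	-0.000000e+00	2.386983e-14	8.095104e-13	0.000000e+00	0.000000e+00	8.333802e-13
40	-0.000000e+00	3.182645e-14	8.095104e-13	0.000000e+00	0.000000e+00	8.413368e-13
50	-0.000000e+00	3.978306e-14	8.095104e-13	0.000000e+00	0.000000e+00	8.492934e-13
60	-0.000000e+00	4.773967e-14	8.095104e-13	0.000000e+00	0.000000e+00	8.572500e-13
70	-0.000000e+00	5.569628e-14	8.095104e-13	0.000000e+00	0.000000e+00	8.652066e-13
80	-0.000000e+00	6.365289e-14	8.095104e-13	0.000000e+00	0.000000e+00	8.731633e-13
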