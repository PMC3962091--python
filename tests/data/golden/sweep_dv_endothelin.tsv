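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
# toxin = Endothelin
# membrane = nanofab_1um
# d_eff_cm2_s = 1.378138e-06
# electromigration = per unit valence
delta_V_mV	J_diffusion	J_electromigration	J_pH	J_convection	J_ultrafiltration	J_total
10	-0.000000e+00	5.959575e-13	6.063306e-11	0.000000e+00	0.000000e+00	6.122902e-11
20	-0.000000e+00	1.191915e-12	6.063306e-11	0.000000e+00	0.000000e+00	6.182498e-11
30	-0.000000e+00	1.787872e-12	6.063306e-11	0.000000e+00	0.000000e+00	6.242094e-11
40	-0.000000e+00	2.383830e-12	6.063306e-11	0.000000e+00	0.000000e+00	6.301689e-11
50	-0.000000e+00	2.979787e-12	6.063306e-11	0.000000e+00	0.000000e+00	6.361285e-11
60	-0.000000e+00	3.575745e-12	6.063306e-11	0.000000e+00	0.000000e+00	6.420881e-11
70	-0.000000e+00	4.171702e-12	6.063306e-11	0.000000e+00	0.000000e+00	6.480477e-11
80	-0.000000e+00	4.767660e-12	6.063306e-11	0.000000e+00	0.000000e+00	6.540072e-11
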