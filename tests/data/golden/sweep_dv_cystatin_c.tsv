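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
# toxin = Cystatin C
# membrane = nanofab_1um
# d_eff_cm2_s = 5.698124e-07
# electromigration = per unit valence
delta_V_mV	J_diffusion	J_electromigration	J_pH	J_convection	J_ultrafiltration	J_total
10	-0.000000e+00	2.556680e-09	2.601181e-07	0.000000e+00	0.000000e+00	2.626748e-07
20	-0.000000e+00	5.113360e-09	2.601181e-07	0.000000e+00	0.000000e+00	2.652315e-07
30	-0.000000e+00	7.670040e-09	2.601181e-07	0.000000e+00	0.000000e+00	2.677882e-07
40	-0.000000e+00	1.022672e-08	2.601181e-07	0.000000e+00	0.000000e+00	2.703448e-07
50	-0.000000e+00	1.278340e-08	2.601181e-07	0.000000e+00	0.000000e+00	2.729015e-07
60	-0.000000e+00	1.534008e-08	2.601181e-07	0.000000e+00	0.000000e+00	2.754582e-07
70	-0.000000e+00	1.789676e-08	2.601181e-07	0.000000e+00	0.000000e+00	2.780149e-07
80	-0.000000e+00	2.045344e-08	2.601181e-07	0.000000e+00	0.000000e+00	2.805716e-07
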