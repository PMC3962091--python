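name	pdb_id	d_max_nm	molar_mass_g_mol	molar_mass_source	c_normal_value	c_normal_unit	z
Endothelin	1EDN	2.6	2492	UniProt P05305 mature endothelin-1 (21 aa)	28.8	ng/L
Cystatin C	3GAX	4.08	13343	mature human cystatin C chain (120 aa)	1.6	mg/L
Retinol-binding protein	1BRP	4.9	21066	mature plasma RBP4 chain
Complement Factor D	1DSU	5.12	24405	mature adipsin/factor D chain
Interleukin-6	1ALU	5.18	20900	mature secreted IL-6 chain	13.3	ng/L
Tumor necrosis factor - alpha	3GIO	5.79	17353	mature soluble TNF-alpha monomer
Interleukin - 1 beta	3LTQ	6.04	17377	mature IL-1beta chain
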