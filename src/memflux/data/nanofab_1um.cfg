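# Nanofabricated sheet membrane: straight cylindrical nanopores.
# Pore radius 10 nm, thickness 1 um, area 1 m^2, sieving coefficient 1.
label = nanofab_1um
geometry = cylindrical-nanopore
pore_radius_nm = 10
thickness_m = 1e-6
area_m2 = 1.0
sieving_coefficient = 1.0
k_conv = 1.0
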