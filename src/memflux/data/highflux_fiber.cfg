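# High-flux hollow-fiber capillary wall: hindrance from the open-area
# fraction of the inner (blood-side) surface. 50 um wall thickness.
label = highflux_fiber
geometry = open-area-wall
open_area_fraction = 0.0545
thickness_m = 50e-6
area_m2 = 1.0
sieving_coefficient = 1.0
k_conv = 1.0
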