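# Example run: compare the hollow-fiber wall with the 1-um nanopore sheet
# and sweep the applied potential for the three middle molecules.
membranes = highflux_fiber, nanofab_1um
toxins = Endothelin, Cystatin C, Interleukin-6
d0_source = reference
ph_blood = 7.4
ph_dialysate = 7.33
dv_grid_mV = 10, 20, 30, 40, 50, 60, 70, 80
seed = 0
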