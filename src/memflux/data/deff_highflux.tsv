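name	deff_highflux_cm2_s
Endothelin	15e-10
Cystatin C	7.7e-10
Interleukin-6	5.4e-10
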