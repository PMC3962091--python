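"""Electromigration flux vs applied potential and membrane thickness.

Sweeps the applied potential 10-80 mV for cystatin C across the 1-um
nanopore membrane (flux per unit valence, since the net charge is a user
input), then shows the 1/x thickness leverage: thinning 25 um -> 1 um
multiplies the electromigration flux by exactly 25.
"""

from memflux import (DrivingForces, get_toxin, load_membrane, sweep)

toxin = get_toxin("Cystatin C")
membrane = load_membrane("nanofab_1um")

grid_mV = [10, 20, 30, 40, 50, 60, 70, 80]
tab = sweep(toxin, membrane, DrivingForces(), "delta_V",
            [v * 1e-3 for v in grid_mV])
print("dV (mV)   J_electromigr/z (mol/s)")
for mv, b in zip(grid_mV, tab.breakdowns):
    print(f"{mv:7g}   {b.j_electromigration:.4e}")

thick = sweep(toxin, membrane, DrivingForces(delta_V=0.01), "x",
              [25e-6, 1e-6])
j25, j1 = (b.j_electromigration for b in thick.breakdowns)
print(f"\nthickness 25 um -> 1 um at 10 mV: flux x{j1 / j25:.0f}")
# The flux is linear in the applied potential and scales as 1/thickness.
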