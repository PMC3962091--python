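"""Synthetic fixtures with exactly known ground truth.

Two generators back the test suite so that no structure download or lab
measurement is needed:

* :func:`make_structure` emits a PDB-format molecule whose point-set
  diameter is known analytically: two anchor atoms sit exactly
  ``diameter`` apart and every other atom is sampled strictly inside the
  ball spanned by them, with enough margin that the guarantee survives
  PDB's 3-decimal coordinate rounding.
* :func:`make_scenario` builds a transport scenario (toxin, membrane,
  driving forces, a known free diffusivity) and computes the expected flux
  breakdown with a straight-line arithmetic oracle written independently of
  the flux module — simple enough to audit by eye — so the pipeline can be
  checked against it and parameter recovery (inferring D0 back) is exact.

These structures emulate nothing about real protein shapes, charge or
chemistry; they pin down geometry and arithmetic only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .catalog import ToxinSpecies
from .errors import ConfigError
from .flux import DrivingForces, FluxBreakdown
from .structure import StructureModel
from .transport import MembraneSpec


@dataclass
class SyntheticStructureSpec:
    """Recipe for a structure of exactly known diameter (Angstrom)."""

    diameter: float
    n_atoms: int
    seed: int = 0
    element: str = "C"

    def __post_init__(self) -> None:
        if self.n_atoms < 2:
            raise ValueError(f"need at least 2 atoms, got {self.n_atoms}")
        if not self.diameter > 0:
            raise ValueError(f"diameter must be positive, got {self.diameter}")


def make_structure(spec: SyntheticStructureSpec) -> tuple[StructureModel, str]:
    """Generate a structure with point-set diameter exactly ``spec.diameter``.

    Returns the in-memory model (unrounded coordinates; diameter exact to
    floating point) and its PDB text (3-decimal coordinates; diameter
    preserved within 1e-3 Angstrom). Deterministic: the same spec yields
    byte-identical text.
    """
    d = spec.diameter
    rng = np.random.default_rng(spec.seed)
    coords = np.zeros((spec.n_atoms, 3))
    coords[0] = (-d / 2.0, 0.0, 0.0)
    coords[1] = (d / 2.0, 0.0, 0.0)
    n_interior = spec.n_atoms - 2
    if n_interior > 0:
        # strict interior with margin so 3-decimal rounding cannot create
        # a pair longer than the anchors
        r_max = max(0.49 * d - 0.01, 0.0)
        dirs = rng.normal(size=(n_interior, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        radii = r_max * rng.uniform(size=n_interior) ** (1.0 / 3.0)
        coords[2:] = dirs * radii[:, None]

    lines = []
    for i, (x, y, z) in enumerate(coords, start=1):
        lines.append(
            f"ATOM  {i:5d}  CA  GLY A{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
            f"{spec.element:>2s}"
        )
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"

    model = StructureModel(
        elements=[spec.element] * spec.n_atoms,
        coords=coords,
        chain_ids=["A"] * spec.n_atoms,
        occupancies=np.ones(spec.n_atoms),
        model_index=0,
        selection={"synthetic": True, "spec": spec},
    )
    return model, pdb_text


# ---------------------------------------------------------------------------
# transport scenarios with an independent flux oracle

_ORACLE_UNIT_TO_G_PER_L = {"ng/L": 1e-9, "ug/L": 1e-6, "µg/L": 1e-6,
                           "mg/L": 1e-3, "g/L": 1.0}


def _oracle_breakdown(true_d0_cm2s: float, membrane: MembraneSpec,
                      toxin: ToxinSpecies, forces: DrivingForces,
                      ) -> tuple[FluxBreakdown, float]:
    """Straight-line arithmetic for the expected fluxes; every formula is
    written out inline and independently of the flux module."""
    # hindrance
    if membrane.geometry == "cylindrical-nanopore":
        lam = (toxin.d_max / 2.0) / membrane.b
        kdiff = 1.0 - 2.3 * lam + 1.154 * lam * lam + 0.224 * lam ** 3
    else:
        eps = membrane.epsilon
        kdiff = (eps / (2.0 - eps)) ** 2
    deff_cm2s = kdiff * true_d0_cm2s
    deff = deff_cm2s * 1e-4                       # m^2/s
    # molar concentration, mol/m^3
    if toxin.c_normal is None:
        cm = 0.0
    else:
        g_per_L = toxin.c_normal * _ORACLE_UNIT_TO_G_PER_L[toxin.c_normal_unit]
        cm = g_per_L / toxin.molar_mass * 1000.0
    A, x = membrane.A, membrane.x
    j_dif = -deff * A * kdiff * forces.delta_c / x
    j_el = deff * A * cm * 96485.0 / (8.314 * forces.T) * forces.delta_V / x
    if toxin.z is not None:
        j_el = -toxin.z * j_el
    if forces.pH_blood is not None and forces.pH_dialysate is not None:
        bracket = (-4.606 * forces.pH_blood
                   - 2.303 * math.log10(forces.pH_dialysate ** 2))
        j_ph = -deff * A * cm / x * bracket
    else:
        j_ph = 0.0
    j_conv = membrane.K_conv * A * cm * forces.J_v
    if forces.delta_P != 0 or forces.delta_pi != 0:
        j_uf = membrane.Omega * membrane.L_p * A * (forces.delta_P
                                                    + forces.delta_pi)
    else:
        j_uf = 0.0
    expected = FluxBreakdown(
        j_diffusion=j_dif, j_electromigration=j_el, j_ph=j_ph,
        j_convection=j_conv, j_ultrafiltration=j_uf,
        j_total=j_dif + j_el + j_ph + j_conv + j_uf,
        per_valence=toxin.z is None,
        inputs={"oracle": True},
    )
    return expected, deff_cm2s


@dataclass
class SyntheticScenario:
    """A transport scenario with oracle-computed expected outputs."""

    true_d0: float               # cm^2/s
    membrane: MembraneSpec
    toxin: ToxinSpecies
    forces: DrivingForces
    expected: FluxBreakdown
    expected_d_eff: float        # cm^2/s
    seed: int = 0


def make_scenario(true_d0: float, membrane: MembraneSpec,
                  toxin: ToxinSpecies, forces: DrivingForces | None = None,
                  seed: int = 0) -> SyntheticScenario:
    """Build a scenario; with ``forces=None`` modest random driving forces
    are drawn from ``seed`` (potentials of tens of mV, physiological pH)."""
    if not true_d0 > 0:
        raise ConfigError("true_d0", f"must be positive, got {true_d0}")
    if forces is None:
        rng = np.random.default_rng(seed)
        forces = DrivingForces(
            delta_c=float(toxin.c_molar or 0.0),
            delta_V=float(rng.uniform(0.01, 0.08)),
            pH_blood=float(rng.uniform(7.2, 7.6)),
            pH_dialysate=float(rng.uniform(7.2, 7.6)),
        )
    expected, deff = _oracle_breakdown(true_d0, membrane, toxin, forces)
    return SyntheticScenario(true_d0=true_d0, membrane=membrane, toxin=toxin,
                             forces=forces, expected=expected,
                             expected_d_eff=deff, seed=seed)
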