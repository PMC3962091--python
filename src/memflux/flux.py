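"""Term-wise Nernst–Planck flux decomposition for membrane transport.

The solute flux across a thin membrane is written as the sum of five
uncoupled contributions — diffusion, electromigration, a pH (proton-motive)
term, convection, and ultrafiltration:

    J = -Deff*A*Kdiff*(dc/dx)
        - (Deff*A*Cm*z*F/(R*T))*(dV/dx)
        - (Deff*A*Cm/x)*(-4.606*pH1 - 2.303*log10(pH2^2))
        + Kconv*A*Cm*Jv
        + Omega*Lp*A*(dP + dpi)

Gradients are uniform across the wall: dV/dx = dV/x, dc/dx = dc/x, with x
the membrane thickness. All inputs and outputs are SI (mol, m, s, V, K, Pa);
fluxes are mol/s.

Conventions, all recorded in report headers:

* Sign: positive flux = blood to dialysate. The leading minus signs of the
  diffusion/electromigration/pH terms are kept literally, so driving-force
  differences should be passed as (dialysate side minus blood side) for a
  clearing flux to come out positive.
* The diffusion term multiplies Deff by Kdiff as written above, although
  Deff already contains Kdiff; this literal double-hindrance form is the
  default and ``double_hindrance=False`` drops the extra factor.
* When a toxin's valence ``z`` is unset, the electromigration term is the
  per-unit-valence magnitude coefficient times dV/x (no sign), i.e. the
  flux per unit of net charge.
* The pH bracket is evaluated literally as ``-4.606*pH1 - 2.303*log10(pH2**2)``
  with pH1 the blood side and pH2 the dialysate side by default; the
  pairing is configurable via ``ph_pairing`` and logged. The algebraic
  origin of this bracket is opaque (see the methods note); it is exposed
  as-is rather than reinterpreted.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from .catalog import ToxinSpecies
from .errors import ConfigError
from .transport import (BODY_TEMPERATURE_K, DiffusivityResult, MembraneSpec,
                        diffusivity, hindrance, infer_d0)

FARADAY = 96485.0        # C/mol
GAS_CONSTANT = 8.314     # J/(mol K)


@dataclass
class DrivingForces:
    """Driving forces applied across one membrane.

    ``delta_c`` (mol/m^3) and ``delta_V`` (V) are differences across the
    wall; divided by the thickness they form the uniform gradients. ``J_v``
    is the volumetric convective flow in m^3/s, ``delta_P``/``delta_pi``
    hydraulic and osmotic pressure differences in Pa.
    """

    delta_c: float = 0.0
    delta_V: float = 0.0
    pH_blood: float | None = None
    pH_dialysate: float | None = None
    J_v: float = 0.0
    delta_P: float = 0.0
    delta_pi: float = 0.0
    T: float = BODY_TEMPERATURE_K

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise ValueError(f"T must be positive, got {self.T}")
        for name in ("pH_blood", "pH_dialysate"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 14:
                raise ValueError(f"{name} = {v} outside [0, 14]")

    @property
    def delta_pH(self) -> float | None:
        if self.pH_blood is None or self.pH_dialysate is None:
            return None
        return self.pH_blood - self.pH_dialysate


@dataclass
class FluxBreakdown:
    """The five flux terms (mol/s) and their sum for one toxin/membrane/
    conditions triple, with full provenance."""

    j_diffusion: float
    j_electromigration: float
    j_ph: float
    j_convection: float
    j_ultrafiltration: float
    j_total: float
    per_valence: bool            # electromigration reported per unit z
    inputs: dict = field(default_factory=dict)
    F: float = FARADAY
    R: float = GAS_CONSTANT

    @property
    def terms(self) -> dict[str, float]:
        return {
            "diffusion": self.j_diffusion,
            "electromigration": self.j_electromigration,
            "pH": self.j_ph,
            "convection": self.j_convection,
            "ultrafiltration": self.j_ultrafiltration,
        }


def diffusion_flux(d_eff: float, A: float, k_diff: float,
                   delta_c: float, x: float, *,
                   double_hindrance: bool = True) -> float:
    """Diffusive term -Deff*A*Kdiff*(dc/x), SI (d_eff in m^2/s).

    The extra Kdiff factor is the literal composed form; pass
    ``double_hindrance=False`` to use -Deff*A*(dc/x).
    """
    if not x > 0:
        raise ValueError(f"thickness must be positive, got {x}")
    k = k_diff if double_hindrance else 1.0
    return -d_eff * A * k * (delta_c / x)


def electromigration_flux(d_eff: float, A: float, c_m: float,
                          z: float | None, T: float,
                          delta_V: float, x: float) -> float:
    """Electromigration term -Deff*A*Cm*z*F/(R*T)*(dV/x), SI.

    With ``z=None`` the per-unit-valence magnitude coefficient times dV/x
    is returned (no leading sign), linear in ``delta_V``.
    """
    if not x > 0:
        raise ValueError(f"thickness must be positive, got {x}")
    if not T > 0:
        raise ValueError(f"T must be positive, got {T}")
    coeff = d_eff * A * c_m * FARADAY / (GAS_CONSTANT * T) * (delta_V / x)
    if z is None:
        return coeff
    return -z * coeff


def ph_flux(d_eff: float, A: float, c_m: float, x: float,
            pH_1: float, pH_2: float) -> float:
    """Proton-motive term -(Deff*A*Cm/x)*(-4.606*pH1 - 2.303*log10(pH2^2)), SI."""
    if not x > 0:
        raise ValueError(f"thickness must be positive, got {x}")
    if not (0 <= pH_1 <= 14 and 0 < pH_2 <= 14):
        raise ValueError(f"pH values out of range: {pH_1}, {pH_2}")
    bracket = -4.606 * pH_1 - 2.303 * math.log10(pH_2 ** 2)
    return -(d_eff * A * c_m / x) * bracket


def convection_flux(k_conv: float, A: float, c_m: float, J_v: float) -> float:
    """Convective term Kconv*A*Cm*Jv, SI."""
    return k_conv * A * c_m * J_v


def ultrafiltration_flux(omega: float, L_p: float, A: float,
                         delta_P: float, delta_pi: float) -> float:
    """Ultrafiltration term Omega*Lp*A*(dP + dpi), SI."""
    return omega * L_p * A * (delta_P + delta_pi)


def total_flux(toxin: ToxinSpecies, membrane: MembraneSpec,
               forces: DrivingForces, *,
               diff: DiffusivityResult | None = None,
               c_m: float | None = None,
               double_hindrance: bool = True,
               eta_exponent: float = 1.4,
               lam_literal: bool = False,
               partial_specific_volume: float = 0.73,
               ph_pairing: tuple[str, str] = ("blood", "dialysate"),
               ) -> FluxBreakdown:
    """All five flux terms from one coherent input set.

    ``diff`` carries the effective diffusivity (cm^2/s, as produced by
    :func:`memflux.transport.diffusivity`); when omitted it is computed from
    the toxin's molar volume at ``forces.T``. ``c_m`` (mol/m^3) overrides
    the toxin's normal plasma concentration.
    """
    if diff is None:
        diff = diffusivity(toxin, membrane, T=forces.T,
                           partial_specific_volume=partial_specific_volume,
                           eta_exponent=eta_exponent, lam_literal=lam_literal)
    d_eff = diff.d_eff_si
    k_diff = diff.hindrance.k_diff
    A, x = membrane.A, membrane.x

    if c_m is None:
        c_m = toxin.c_molar
    needs_cm = (forces.delta_V != 0 or forces.J_v != 0
                or (forces.pH_blood is not None
                    and forces.pH_dialysate is not None))
    if c_m is None:
        if needs_cm:
            raise ConfigError(
                "c_m", f"no concentration available for {toxin.name}; set "
                       "c_normal in the catalog or pass c_m explicitly")
        c_m = 0.0

    j_dif = diffusion_flux(d_eff, A, k_diff, forces.delta_c, x,
                           double_hindrance=double_hindrance)
    j_el = electromigration_flux(d_eff, A, c_m, toxin.z, forces.T,
                                 forces.delta_V, x)
    if forces.pH_blood is not None and forces.pH_dialysate is not None:
        side = {"blood": forces.pH_blood, "dialysate": forces.pH_dialysate}
        j_ph = ph_flux(d_eff, A, c_m, x, side[ph_pairing[0]], side[ph_pairing[1]])
    else:
        j_ph = 0.0
    j_conv = convection_flux(membrane.K_conv, A, c_m, forces.J_v)
    if forces.delta_P != 0 or forces.delta_pi != 0:
        if membrane.L_p is None or membrane.Omega is None:
            raise ConfigError(
                "L_p/Omega", f"membrane {membrane.label!r} has no hydraulic "
                             "permeability/coupling coefficient but a pressure "
                             "difference was requested")
        j_uf = ultrafiltration_flux(membrane.Omega, membrane.L_p, A,
                                    forces.delta_P, forces.delta_pi)
    else:
        j_uf = 0.0

    return FluxBreakdown(
        j_diffusion=j_dif, j_electromigration=j_el, j_ph=j_ph,
        j_convection=j_conv, j_ultrafiltration=j_uf,
        j_total=j_dif + j_el + j_ph + j_conv + j_uf,
        per_valence=toxin.z is None,
        inputs={
            "toxin": toxin.name, "membrane": membrane.label,
            "c_m_mol_m3": c_m, "d_eff_cm2_s": diff.d_eff,
            "k_diff": k_diff, "forces": dataclasses.asdict(forces),
            "double_hindrance": double_hindrance,
            "ph_pairing": ph_pairing,
            "sign_convention": "positive = blood to dialysate",
        },
    )


@dataclass
class SweepTable:
    """One flux breakdown per grid point of a swept variable."""

    variable: str
    values: list[float]
    breakdowns: list[FluxBreakdown]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v, b in zip(self.values, self.breakdowns):
            rows.append({self.variable: v, "J_diffusion": b.j_diffusion,
                         "J_electromigration": b.j_electromigration,
                         "J_pH": b.j_ph, "J_convection": b.j_convection,
                         "J_ultrafiltration": b.j_ultrafiltration,
                         "J_total": b.j_total})
        return pd.DataFrame(rows)


_SWEEPABLE = ("delta_V", "pH", "x")


def sweep(toxin: ToxinSpecies, membrane: MembraneSpec, forces: DrivingForces,
          variable: str, grid: Sequence[float], **kwargs) -> SweepTable:
    """Evaluate the flux breakdown over a grid of one driving variable.

    ``variable`` is one of ``delta_V`` (applied potential, V), ``pH``
    (both sides set to the grid value), or ``x`` (membrane thickness, m;
    the diffusion/electromigration/pH terms scale as 1/x).
    """
    if variable not in _SWEEPABLE:
        raise ConfigError("variable", f"{variable!r} not in {_SWEEPABLE}")
    grid = list(grid)
    if not grid:
        raise ConfigError("grid", "sweep grid is empty")
    breakdowns = []
    for v in grid:
        if variable == "delta_V":
            f = replace(forces, delta_V=v)
            breakdowns.append(total_flux(toxin, membrane, f, **kwargs))
        elif variable == "pH":
            f = replace(forces, pH_blood=v, pH_dialysate=v)
            breakdowns.append(total_flux(toxin, membrane, f, **kwargs))
        else:
            if not v > 0:
                raise ConfigError("grid", f"thickness must be positive, got {v}")
            m = replace(membrane, x=v)
            breakdowns.append(total_flux(toxin, m, forces, **kwargs))
    return SweepTable(variable=variable, values=grid, breakdowns=breakdowns)


def compare_membranes(toxins: Iterable[ToxinSpecies],
                      membrane_a: MembraneSpec, membrane_b: MembraneSpec, *,
                      d_eff_a: dict[str, float] | None = None,
                      lam_literal: bool = False,
                      eta_exponent: float = 1.4,
                      partial_specific_volume: float = 0.73) -> pd.DataFrame:
    """Per-toxin effective diffusivity under two membranes plus the ratio.

    When ``d_eff_a`` maps toxin names to measured effective diffusivities
    (cm^2/s) through membrane A, the free diffusivity is inferred from those
    measurements (D0 = Deff/Kdiff_A) and carried to membrane B — the
    cross-membrane route, independent of any molar-volume prediction.
    Otherwise D0 is predicted from each toxin's molar volume.
    """
    rows = []
    for toxin in toxins:
        if d_eff_a is not None:
            if toxin.name not in d_eff_a:
                continue
            ha = hindrance(toxin.d_max, membrane_a, lam_literal=lam_literal)
            d0 = infer_d0(d_eff_a[toxin.name], ha.k_diff)
            res_a = diffusivity(toxin, membrane_a, d0=d0,
                                lam_literal=lam_literal)
            res_b = diffusivity(toxin, membrane_b, d0=d0,
                                lam_literal=lam_literal)
        else:
            res_a = diffusivity(toxin, membrane_a, lam_literal=lam_literal,
                                eta_exponent=eta_exponent,
                                partial_specific_volume=partial_specific_volume)
            res_b = diffusivity(toxin, membrane_b, lam_literal=lam_literal,
                                eta_exponent=eta_exponent,
                                partial_specific_volume=partial_specific_volume)
        rows.append({
            "toxin": toxin.name,
            "d_max_nm": toxin.d_max,
            "k_diff_a": res_a.hindrance.k_diff,
            "k_diff_b": res_b.hindrance.k_diff,
            "d0_cm2_s": res_a.d0,
            "d_eff_a_cm2_s": res_a.d_eff,
            "d_eff_b_cm2_s": res_b.d_eff,
            "ratio_b_over_a": res_b.d_eff / res_a.d_eff,
        })
    return pd.DataFrame(rows)
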