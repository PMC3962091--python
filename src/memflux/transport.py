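"""Hindrance factors and hindered effective diffusivity.

Two membrane idealizations are supported:

* ``cylindrical-nanopore`` — straight cylindrical pores of radius ``b``.
  Steric/hydrodynamic hindrance follows the Renkin polynomial
  ``Kdiff = 1 - 2.3*lam + 1.154*lam**2 + 0.224*lam**3`` in the size ratio
  ``lam = r/b`` with ``r`` the solute radius. By default ``r`` is taken as
  half the maximal molecular dimension (a molecule of maximal dimension
  d_max presents a radius d_max/2 to the pore); a literal mode using
  ``r = d_max`` is available behind ``lam_literal`` for sensitivity checks.
* ``open-area-wall`` — a wall characterized only by its open-area fraction
  ``eps``, with ``Kdiff = (eps/(2-eps))**2``.

Free-solution diffusivity uses the molar-volume correlation
``D0 = 13.26e-5 / (eta**p * V_M**0.589)`` (D0 in cm^2/s, eta in cP, V_M in
cm^3/mol). The viscosity exponent ``p`` defaults to 1.4; the classical
Hayduk–Laudie exponent 1.14 is selectable — back-calculated diffusivities
for the bundled toxin panel are consistent with either at the 10–20% level,
so the choice is exposed rather than hidden. Effective diffusivity is
``Deff = Kdiff * D0``.

Internally SI; diffusivities are carried in cm^2/s because every published
comparison value for these membranes is printed in cm^2/s.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .catalog import ToxinSpecies
from .errors import ConfigError, MoleculeExcludedError
from .structure import estimate_molar_volume

BODY_TEMPERATURE_K = 310.15

_GEOMETRIES = ("cylindrical-nanopore", "open-area-wall")


@dataclass
class MembraneSpec:
    """Geometry and transport coefficients of one membrane.

    Exactly one of ``b`` (pore radius, nm; nanopore geometry) or ``epsilon``
    (open-area fraction; open-area geometry) is required, matching
    ``geometry``. ``x`` is thickness in m, ``A`` total area in m^2, ``S``
    the sieving coefficient, ``K_conv`` the convective hindrance
    coefficient, ``L_p`` hydraulic permeability in m/(s*Pa) and ``Omega``
    the dimensionless solute-coupling coefficient. ``L_p`` and ``Omega``
    stay unset unless ultrafiltration is modelled.
    """

    label: str
    geometry: str
    x: float                      # thickness, m
    A: float = 1.0                # area, m^2
    b: float | None = None        # pore radius, nm
    epsilon: float | None = None  # open-area fraction
    S: float = 1.0
    K_conv: float = 1.0
    L_p: float | None = None
    Omega: float | None = None

    def __post_init__(self) -> None:
        if self.geometry not in _GEOMETRIES:
            raise ConfigError("geometry",
                              f"{self.geometry!r} not in {_GEOMETRIES}")
        if self.geometry == "cylindrical-nanopore":
            if self.b is None or self.epsilon is not None:
                raise ConfigError("b", "cylindrical-nanopore needs a pore "
                                       "radius b (and no epsilon)")
            if not self.b > 0:
                raise ConfigError("b", f"pore radius must be positive, got {self.b}")
        else:
            if self.epsilon is None or self.b is not None:
                raise ConfigError("epsilon", "open-area-wall needs an open-area "
                                             "fraction epsilon (and no b)")
            if not 0 < self.epsilon <= 1:
                raise ConfigError("epsilon",
                                  f"must be in (0, 1], got {self.epsilon}")
        if not self.x > 0:
            raise ConfigError("x", f"thickness must be positive, got {self.x}")
        if not self.A > 0:
            raise ConfigError("A", f"area must be positive, got {self.A}")
        if not 0 < self.S <= 1:
            raise ConfigError("S", f"sieving coefficient must be in (0, 1], "
                                   f"got {self.S}")


@dataclass
class HindranceResult:
    """Diffusion hindrance and how it was obtained."""

    k_diff: float
    formula: str                 # "renkin" or "open-area"
    lam: float | None = None     # size ratio, nanopore geometry only

    def __post_init__(self) -> None:
        if not 0 < self.k_diff <= 1:
            raise ValueError(f"k_diff must be in (0, 1], got {self.k_diff}")


@dataclass
class DiffusivityResult:
    """Free and effective diffusivity with the provenance of each factor."""

    d0: float                    # cm^2/s
    d_eff: float                 # cm^2/s
    hindrance: HindranceResult
    v_m: float | None = None     # cm^3/mol
    eta: float | None = None     # cP
    T: float | None = None       # K

    @property
    def d_eff_si(self) -> float:
        """Effective diffusivity in m^2/s."""
        return self.d_eff * 1e-4


def lambda_ratio(d_max: float, b: float, *, literal: bool = False) -> float:
    """Size ratio lam governing pore hindrance.

    ``d_max`` is the solute's maximal dimension and ``b`` the pore radius,
    both in nm. The solute radius d_max/2 is compared with the pore radius
    (set ``literal=True`` to use d_max itself, for sensitivity analysis).
    A solute whose radius reaches the pore radius is sterically excluded.
    """
    if not d_max > 0:
        raise ValueError(f"d_max must be positive, got {d_max}")
    if not b > 0:
        raise ValueError(f"pore radius must be positive, got {b}")
    r = d_max if literal else d_max / 2.0
    if r >= b:
        raise MoleculeExcludedError(
            f"solute radius {r} nm >= pore radius {b} nm: molecule excluded")
    return r / b


def renkin_hindrance(lam: float) -> float:
    """Diffusion hindrance in a cylindrical pore: cubic in the size ratio.

    Valid for ``0 <= lam < 1``; the polynomial was fitted for small ratios,
    so a warning is issued above 0.6.
    """
    if not 0 <= lam < 1:
        raise ValueError(f"lam must be in [0, 1), got {lam}")
    if lam > 0.6:
        warnings.warn(f"Renkin hindrance polynomial used outside its "
                      f"fitted range (lam = {lam:.3f} > 0.6)", stacklevel=2)
    return 1.0 - 2.3 * lam + 1.154 * lam ** 2 + 0.224 * lam ** 3


def open_area_hindrance(epsilon: float) -> float:
    """Diffusion hindrance of an open-area wall: ``(eps/(2-eps))**2``."""
    if not 0 < epsilon <= 1:
        raise ValueError(f"epsilon must be in (0, 1], got {epsilon}")
    return (epsilon / (2.0 - epsilon)) ** 2


def hindrance(d_max_nm: float, membrane: MembraneSpec,
              *, lam_literal: bool = False) -> HindranceResult:
    """Dispatch to the geometry-appropriate hindrance formula."""
    if membrane.geometry == "cylindrical-nanopore":
        lam = lambda_ratio(d_max_nm, membrane.b, literal=lam_literal)
        return HindranceResult(k_diff=renkin_hindrance(lam),
                               formula="renkin", lam=lam)
    return HindranceResult(k_diff=open_area_hindrance(membrane.epsilon),
                           formula="open-area")


def water_viscosity(T: float) -> float:
    """Liquid-water dynamic viscosity in cP at temperature T (K).

    Vogel-type fit eta = exp(-3.7188 + 578.919/(T - 137.546)), accurate to
    a few tenths of a percent over 0-100 degC (1.002 cP at 20 degC,
    0.694 cP at 37 degC).
    """
    if not 273.15 <= T <= 373.15:
        raise ValueError(f"T = {T} K outside liquid-water range "
                         "[273.15, 373.15]")
    return math.exp(-3.7188 + 578.919 / (T - 137.546))


def free_diffusivity(v_m: float, eta: float,
                     eta_exponent: float = 1.4) -> float:
    """Free-solution diffusivity D0 in cm^2/s from molar volume and viscosity.

    ``D0 = 13.26e-5 / (eta**eta_exponent * v_m**0.589)`` with ``v_m`` in
    cm^3/mol and ``eta`` in cP. ``eta_exponent`` defaults to 1.4; pass 1.14
    for the classical Hayduk–Laudie form.
    """
    if not v_m > 0:
        raise ValueError(f"v_m must be positive, got {v_m}")
    if not eta > 0:
        raise ValueError(f"eta must be positive, got {eta}")
    return 13.26e-5 / (eta ** eta_exponent * v_m ** 0.589)


def effective_diffusivity(d0: float, k_diff: float) -> float:
    """Hindered diffusivity Deff = Kdiff * D0 (cm^2/s in, cm^2/s out)."""
    if not d0 > 0:
        raise ValueError(f"d0 must be positive, got {d0}")
    if not 0 < k_diff <= 1:
        raise ValueError(f"k_diff must be in (0, 1], got {k_diff}")
    return k_diff * d0


def infer_d0(d_eff: float, k_diff: float) -> float:
    """Invert Deff = Kdiff * D0, e.g. to carry a measured Deff from one
    membrane geometry to another."""
    if not k_diff > 0:
        raise ValueError(f"k_diff must be positive, got {k_diff}")
    return d_eff / k_diff


def diffusivity(toxin: ToxinSpecies, membrane: MembraneSpec, *,
                T: float = BODY_TEMPERATURE_K,
                partial_specific_volume: float = 0.73,
                eta_exponent: float = 1.4,
                lam_literal: bool = False,
                d0: float | None = None) -> DiffusivityResult:
    """Full chain d_max/molar mass -> hindrance, D0, Deff for one membrane.

    ``d0`` (cm^2/s) may be supplied directly — e.g. inferred from a measured
    effective diffusivity via :func:`infer_d0` — otherwise it is predicted
    from the toxin's molar volume and the water viscosity at ``T``.
    """
    h = hindrance(toxin.d_max, membrane, lam_literal=lam_literal)
    if d0 is None:
        if toxin.molar_mass is None:
            raise ConfigError("molar_mass",
                              f"needed to predict D0 for {toxin.name}")
        v_m = estimate_molar_volume(toxin.molar_mass, partial_specific_volume)
        eta = water_viscosity(T)
        d0 = free_diffusivity(v_m, eta, eta_exponent)
        return DiffusivityResult(d0=d0, d_eff=effective_diffusivity(d0, h.k_diff),
                                 hindrance=h, v_m=v_m, eta=eta, T=T)
    return DiffusivityResult(d0=d0, d_eff=effective_diffusivity(d0, h.k_diff),
                             hindrance=h, T=T)


# ---------------------------------------------------------------------------
# membrane configuration files

def _parse_kv(text: str, origin: str) -> dict[str, str]:
    out = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(origin, f"expected 'key = value', got {raw!r}")
        key, val = line.split("=", 1)
        out[key.strip()] = val.strip()
    return out


_MEMBRANE_KEYS = {
    "label": ("label", str),
    "geometry": ("geometry", str),
    "pore_radius_nm": ("b", float),
    "open_area_fraction": ("epsilon", float),
    "thickness_m": ("x", float),
    "area_m2": ("A", float),
    "sieving_coefficient": ("S", float),
    "k_conv": ("K_conv", float),
    "l_p": ("L_p", float),
    "omega": ("Omega", float),
}


def membrane_from_text(text: str, origin: str = "<text>") -> MembraneSpec:
    """Build a MembraneSpec from plain-text ``key = value`` configuration."""
    kv = _parse_kv(text, origin)
    kwargs = {}
    for key, val in kv.items():
        if key not in _MEMBRANE_KEYS:
            raise ConfigError(key, f"unknown membrane key in {origin}")
        attr, conv = _MEMBRANE_KEYS[key]
        kwargs[attr] = conv(val)
    for required in ("label", "geometry", "x"):
        if required not in kwargs:
            raise ConfigError(required, f"missing in membrane file {origin}")
    return MembraneSpec(**kwargs)


def load_membrane(name_or_path: str | Path) -> MembraneSpec:
    """Load a membrane spec: a bundled name (``nanofab_1um``,
    ``highflux_fiber``) or a path to a configuration file."""
    name = str(name_or_path)
    if name in ("nanofab_1um", "highflux_fiber"):
        text = resources.files("memflux.data").joinpath(f"{name}.cfg").read_text()
        return membrane_from_text(text, origin=f"builtin {name}")
    return membrane_from_text(Path(name_or_path).read_text(),
                              origin=str(name_or_path))


def reference_highflux_deff() -> dict[str, float]:
    """Measured effective diffusivities (cm^2/s) of the three middle
    molecules through a high-flux hollow-fiber wall, bundled as reference
    input for cross-membrane comparisons."""
    text = resources.files("memflux.data").joinpath("deff_highflux.tsv").read_text()
    rows = csv.DictReader(text.splitlines(), delimiter="\t")
    return {r["name"]: float(r["deff_highflux_cm2_s"]) for r in rows}
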