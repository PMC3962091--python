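"""Uremic-toxin catalog with unit-safe concentration handling.

The built-in panel holds seven middle-molecule uremic toxins (endothelin,
cystatin C, retinol-binding protein, complement factor D, interleukin-6,
TNF-alpha and interleukin-1beta), each with its Protein Data Bank accession,
maximal linear dimension and — where a normal plasma level is established —
a mass concentration. Transport calculations need the membrane-side molar
concentration ``Cm`` in mol/m^3, so every species carries a molar mass
(literature values; the source is recorded per entry and can be overridden)
and converts on demand.

Custom panels are accepted as TSV files in the same dialect as the bundled
``data/toxins.tsv``.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import ConfigError, UnitError

# accepted mass-concentration units -> factor to g/L
_UNIT_TO_G_PER_L = {
    "ng/L": 1e-9,
    "ug/L": 1e-6,
    "µg/L": 1e-6,
    "mg/L": 1e-3,
    "g/L": 1.0,
}

_PDB_ID_RE = re.compile(r"^[0-9][A-Za-z0-9]{3}$")


def to_molar(c_mass: float, unit: str, molar_mass: float) -> float:
    """Convert a mass concentration to mol/m^3.

    Parameters
    ----------
    c_mass : float
        Concentration value in ``unit``.
    unit : str
        One of ``ng/L``, ``ug/L`` (``µg/L``), ``mg/L``, ``g/L``.
    molar_mass : float
        Molar mass in g/mol; must be positive.

    Returns
    -------
    float
        Molar concentration in mol/m^3 (1 mol/L = 1000 mol/m^3).
    """
    if unit not in _UNIT_TO_G_PER_L:
        raise UnitError(f"unknown concentration unit {unit!r}; "
                        f"expected one of {sorted(set(_UNIT_TO_G_PER_L))}")
    if not molar_mass > 0:
        raise ValueError(f"molar mass must be positive, got {molar_mass}")
    grams_per_litre = c_mass * _UNIT_TO_G_PER_L[unit]
    return grams_per_litre / molar_mass * 1000.0


def from_molar(c_molar: float, unit: str, molar_mass: float) -> float:
    """Inverse of :func:`to_molar`: mol/m^3 back to a mass concentration."""
    if unit not in _UNIT_TO_G_PER_L:
        raise UnitError(f"unknown concentration unit {unit!r}")
    if not molar_mass > 0:
        raise ValueError(f"molar mass must be positive, got {molar_mass}")
    grams_per_litre = c_molar / 1000.0 * molar_mass
    return grams_per_litre / _UNIT_TO_G_PER_L[unit]


@dataclass
class ToxinSpecies:
    """One uremic toxin and everything the transport pipeline needs of it.

    ``d_max`` is the maximal linear dimension (point-set diameter) in nm;
    ``z`` is the signed valence and is left unset by default because net
    protein charge is pH- and site-dependent — fluxes that require ``z``
    are then reported per unit valence.
    """

    name: str
    pdb_id: str
    d_max: float                      # nm
    molar_mass: float | None = None   # g/mol
    molar_mass_source: str = ""
    c_normal: float | None = None     # value in c_normal_unit
    c_normal_unit: str = "ng/L"
    z: float | None = None

    def __post_init__(self) -> None:
        if not _PDB_ID_RE.match(self.pdb_id):
            raise ValueError(f"{self.pdb_id!r} is not a valid PDB accession")
        if not self.d_max > 0:
            raise ValueError(f"d_max must be positive, got {self.d_max}")
        if self.molar_mass is not None and not self.molar_mass > 0:
            raise ValueError(f"molar_mass must be positive, got {self.molar_mass}")

    @property
    def c_molar(self) -> float | None:
        """Membrane-side molar concentration Cm in mol/m^3, or None."""
        if self.c_normal is None:
            return None
        if self.molar_mass is None:
            raise ConfigError("molar_mass",
                              f"needed to convert {self.name} concentration to molar")
        return to_molar(self.c_normal, self.c_normal_unit, self.molar_mass)

    @property
    def d_max_m(self) -> float:
        return self.d_max * 1e-9


def _parse_rows(rows: list[dict[str, str]], origin: str) -> list[ToxinSpecies]:
    out = []
    for row in rows:
        try:
            out.append(ToxinSpecies(
                name=row["name"].strip(),
                pdb_id=row["pdb_id"].strip(),
                d_max=float(row["d_max_nm"]),
                molar_mass=float(row["molar_mass_g_mol"])
                if row.get("molar_mass_g_mol") else None,
                molar_mass_source=(row.get("molar_mass_source") or "").strip(),
                c_normal=float(row["c_normal_value"])
                if row.get("c_normal_value") else None,
                c_normal_unit=(row.get("c_normal_unit") or "ng/L").strip() or "ng/L",
                z=float(row["z"]) if row.get("z") else None,
            ))
        except (KeyError, ValueError) as exc:
            raise ConfigError("catalog", f"bad row in {origin}: {row!r} ({exc})")
    return out


def load_catalog(path: str | Path) -> list[ToxinSpecies]:
    """Read a toxin panel from a TSV file (same columns as the bundled one)."""
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    return _parse_rows(rows, str(path))


def builtin_catalog() -> list[ToxinSpecies]:
    """The bundled seven-toxin panel, in order of increasing size."""
    text = resources.files("memflux.data").joinpath("toxins.tsv").read_text()
    rows = list(csv.DictReader(text.splitlines(), delimiter="\t"))
    return _parse_rows(rows, "builtin toxins.tsv")


def get_toxin(name: str, catalog: list[ToxinSpecies] | None = None) -> ToxinSpecies:
    """Case-insensitive lookup by name in a catalog (builtin by default)."""
    catalog = builtin_catalog() if catalog is None else catalog
    for t in catalog:
        if t.name.lower() == name.lower():
            return t
    raise KeyError(f"no toxin named {name!r} in catalog "
                   f"({', '.join(t.name for t in catalog)})")
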