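"""Structure parsing and maximal molecular dimension.

The size that matters for steric hindrance in a pore is the molecule's
maximal linear dimension — the diameter of its atom point set, i.e. the
largest pairwise Euclidean distance. This module parses PDB (optionally
mmCIF) coordinates through gemmi, applies a documented default atom
selection, and computes the exact diameter.

Default selection convention (recorded in every result): first model,
all chains, all non-hydrogen amino-acid atoms; waters always excluded;
alternate locations resolved to the highest-occupancy conformer. The
selection is a convention of this package, configurable per call.

The diameter is exact: brute force over all pairs for small atom counts,
and a convex-hull fast path (the diameter endpoints are necessarily hull
vertices) above ``_HULL_THRESHOLD`` atoms. Both paths agree by construction
and are cross-tested.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import SelectionError, StructureParseError

_HULL_THRESHOLD = 3000


@dataclass
class StructureModel:
    """Selected atoms of one model of a structure file.

    Coordinates are in Angstrom (PDB convention); ``selection`` records
    exactly which filters produced this atom set.
    """

    elements: list[str]
    coords: np.ndarray          # (n, 3) float64, Angstrom
    chain_ids: list[str]
    occupancies: np.ndarray
    model_index: int
    selection: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if len(self.coords) == 0:
            raise SelectionError("selection left no atoms")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)


@dataclass
class DimensionResult:
    """Maximal linear dimension of an atom set and the atoms realizing it."""

    d_max_A: float
    endpoints: tuple[int, int]
    n_atoms: int

    @property
    def d_max_nm(self) -> float:
        return self.d_max_A / 10.0


def _pick_altloc(atoms):
    """Resolve alternate conformers: per atom name keep highest occupancy."""
    best = {}
    for a in atoms:
        key = a.name
        if key not in best or a.occ > best[key].occ:
            best[key] = a
    return best.values()


def read_structure(
    source: str | Path,
    *,
    chains: list[str] | None = None,
    include_hydrogens: bool = False,
    include_hetero: bool = False,
    model_index: int = 0,
) -> StructureModel:
    """Parse a PDB (or mmCIF) file or a PDB-format string into a StructureModel.

    Parameters
    ----------
    source
        Path to a ``.pdb``/``.ent``/``.cif`` file, or PDB-format text.
    chains
        Chain identifiers to keep; ``None`` keeps all.
    include_hydrogens
        Keep hydrogen/deuterium atoms (default: exclude).
    include_hetero
        Keep non-water heteroatom residues such as ligands (default:
        amino-acid residues only). Waters are always excluded.
    model_index
        Which model of a multi-model (e.g. NMR) file; default the first.
    """
    import gemmi

    is_path = isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists())
    if is_path and Path(source).suffix.lower() in (".cif", ".mmcif"):
        try:
            st = gemmi.read_structure(str(source))
        except (RuntimeError, ValueError) as exc:
            raise StructureParseError(str(exc), _line_from_message(str(exc)))
    else:
        text = Path(source).read_text() if is_path else str(source)
        _validate_pdb_records(text)
        try:
            st = gemmi.read_pdb_string(text)
        except (RuntimeError, ValueError) as exc:
            raise StructureParseError(str(exc), _line_from_message(str(exc)))

    if len(st) == 0:
        raise StructureParseError("file contains no models")
    if model_index >= len(st):
        raise SelectionError(
            f"model_index {model_index} out of range ({len(st)} models)")
    model = st[model_index]

    keep_chains = set(chains) if chains else None
    elements, xyz, chain_ids, occs = [], [], [], []
    for chain in model:
        if keep_chains is not None and chain.name not in keep_chains:
            continue
        for res in chain:
            if res.is_water():
                continue
            info = gemmi.find_tabulated_residue(res.name)
            is_aa = info is not None and info.is_amino_acid()
            if not is_aa and not include_hetero:
                continue
            for atom in _pick_altloc(res):
                if not include_hydrogens and atom.element.is_hydrogen:
                    continue
                elements.append(atom.element.name)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                chain_ids.append(chain.name)
                occs.append(atom.occ)

    if not xyz:
        raise SelectionError(
            "selection left no atoms "
            f"(chains={chains}, include_hydrogens={include_hydrogens}, "
            f"include_hetero={include_hetero}, model_index={model_index})")

    return StructureModel(
        elements=elements,
        coords=np.array(xyz, dtype=float),
        chain_ids=chain_ids,
        occupancies=np.array(occs, dtype=float),
        model_index=model_index,
        selection={
            "chains": chains,
            "include_hydrogens": include_hydrogens,
            "include_hetero": include_hetero,
            "model_index": model_index,
            "waters_excluded": True,
            "altloc": "highest-occupancy",
        },
    )


def _validate_pdb_records(text: str) -> None:
    """Reject malformed coordinate records (gemmi is lenient about them)."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise StructureParseError("truncated coordinate record", lineno)
        for lo, hi in ((30, 38), (38, 46), (46, 54)):
            try:
                float(line[lo:hi])
            except ValueError:
                raise StructureParseError(
                    f"bad coordinate field {line[lo:hi]!r}", lineno)


def _line_from_message(msg: str) -> int | None:
    m = re.search(r"line\s+(\d+)", msg)
    return int(m.group(1)) if m else None


def _diameter_bruteforce(coords: np.ndarray) -> tuple[float, tuple[int, int]]:
    """All-pairs maximum distance; chunked to bound memory."""
    n = len(coords)
    best_d2, best_pair = -1.0, (0, 0)
    chunk = 512
    for start in range(0, n, chunk):
        block = coords[start:start + chunk]
        d2 = np.sum((block[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
        i_loc, j = np.unravel_index(np.argmax(d2), d2.shape)
        if d2[i_loc, j] > best_d2:
            best_d2 = d2[i_loc, j]
            best_pair = (start + int(i_loc), int(j))
    i, j = sorted(best_pair)
    return float(np.sqrt(best_d2)), (i, j)


def _diameter_hull(coords: np.ndarray) -> tuple[float, tuple[int, int]]:
    """Diameter via convex hull vertices (falls back on degenerate sets)."""
    try:
        hull = ConvexHull(coords)
    except QhullError:
        return _diameter_bruteforce(coords)
    verts = hull.vertices
    d, (a, b) = _diameter_bruteforce(coords[verts])
    i, j = sorted((int(verts[a]), int(verts[b])))
    return d, (i, j)


def max_dimension(structure: StructureModel | np.ndarray) -> DimensionResult:
    """Exact maximal linear dimension of an atom set.

    Accepts a :class:`StructureModel` or a bare ``(n, 3)`` coordinate array
    in Angstrom. Requires at least two atoms. The hull fast path is used for
    large atom counts; the result always equals the all-pairs definition.
    """
    coords = structure.coords if isinstance(structure, StructureModel) else \
        np.asarray(structure, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("expected an (n, 3) coordinate array")
    n = len(coords)
    if n < 2:
        raise ValueError(f"need at least 2 atoms to measure a dimension, got {n}")
    if n < _HULL_THRESHOLD:
        d, pair = _diameter_bruteforce(coords)
    else:
        d, pair = _diameter_hull(coords)
    return DimensionResult(d_max_A=d, endpoints=pair, n_atoms=n)


def estimate_molar_volume(molar_mass: float,
                          partial_specific_volume: float = 0.73) -> float:
    """Molar volume V_M in cm^3/mol from molar mass and partial specific volume.

    V_M = M * v_bar. The default v_bar of 0.73 cm^3/g is the canonical value
    for globular proteins; this simple product is this package's documented
    stand-in for a crystallographic volume calculation.
    """
    if not molar_mass > 0:
        raise ValueError(f"molar_mass must be positive, got {molar_mass}")
    if not partial_specific_volume > 0:
        raise ValueError("partial_specific_volume must be positive, "
                         f"got {partial_specific_volume}")
    return molar_mass * partial_specific_volume


def fetch_pdb(pdb_id: str, dest_dir: str | Path = ".") -> Path:
    """Convenience download of a PDB entry from RCSB (requires network).

    No part of the package or its tests depends on this; it exists so users
    with connectivity can pull deposited entries for measurement.
    """
    import urllib.request

    pdb_id = pdb_id.lower()
    dest = Path(dest_dir) / f"{pdb_id}.pdb"
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    with urllib.request.urlopen(url, timeout=30) as resp:
        dest.write_bytes(resp.read())
    return dest
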