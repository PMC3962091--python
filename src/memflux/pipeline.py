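"""End-to-end runs: structure -> dimension -> Deff -> flux sweeps -> reports.

A :class:`RunConfig` (built in code or parsed from a plain-text
``key = value`` file) fully determines a run; the same config and inputs
produce byte-identical outputs. Reports are TSV files with a commented
metadata header recording every constant, convention and flag in effect,
so each table is self-describing and diffable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .catalog import ToxinSpecies, builtin_catalog, get_toxin, load_catalog
from .errors import ConfigError
from .flux import (FARADAY, GAS_CONSTANT, DrivingForces, compare_membranes,
                   sweep)
from .structure import max_dimension, read_structure
from .transport import (BODY_TEMPERATURE_K, MembraneSpec, load_membrane,
                        reference_highflux_deff)


def _fmt(x: float) -> str:
    return f"{x:.6e}"


@dataclass
class RunConfig:
    """Everything that determines one pipeline run."""

    catalog: str | None = None                  # path; None = builtin panel
    membranes: list[str] = field(
        default_factory=lambda: ["highflux_fiber", "nanofab_1um"])
    toxins: list[str] | None = None             # names; None = whole catalog
    structures: list[str] = field(default_factory=list)   # PDB paths
    T: float = BODY_TEMPERATURE_K
    ph_blood: float | None = None
    ph_dialysate: float | None = None
    dv_grid_mV: list[float] = field(
        default_factory=lambda: [10, 20, 30, 40, 50, 60, 70, 80])
    thickness_override_m: float | None = None
    d0_source: str = "reference"                # or "predicted"
    eta_exponent: float = 1.4
    lam_literal: bool = False
    double_hindrance: bool = True
    units: str = "paper"                        # diffusivities in cm^2/s
    seed: int = 0
    outdir: str = "memflux_out"

    def validate(self) -> None:
        if self.toxins is not None and len(self.toxins) == 0:
            raise ConfigError("toxins", "toxin list is empty")
        if self.d0_source not in ("reference", "predicted"):
            raise ConfigError("d0_source",
                              f"must be 'reference' or 'predicted', "
                              f"got {self.d0_source!r}")
        if len(self.membranes) != 2:
            raise ConfigError("membranes",
                              "exactly two membranes are compared per run")
        if not self.dv_grid_mV:
            raise ConfigError("dv_grid_mV", "potential grid is empty")


_BOOL = {"true": True, "false": False, "1": True, "0": False,
         "yes": True, "no": False}


def config_from_file(path: str | Path) -> RunConfig:
    """Parse a ``key = value`` run configuration file.

    List-valued keys (membranes, toxins, structures, dv_grid_mV) take
    comma-separated values.
    """
    cfg = RunConfig()
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(str(path), f"expected 'key = value', got {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if not hasattr(cfg, key):
            raise ConfigError(key, f"unknown configuration key in {path}")
        current = getattr(cfg, key)
        if key in ("membranes", "toxins", "structures"):
            setattr(cfg, key, [v.strip() for v in val.split(",") if v.strip()])
        elif key == "dv_grid_mV":
            setattr(cfg, key, [float(v) for v in val.split(",") if v.strip()])
        elif key in ("lam_literal", "double_hindrance"):
            setattr(cfg, key, _BOOL[val.lower()])
        elif key == "seed":
            setattr(cfg, key, int(val))
        elif isinstance(current, float) or key in ("ph_blood", "ph_dialysate",
                                                   "thickness_override_m",
                                                   "T", "eta_exponent"):
            setattr(cfg, key, float(val))
        else:
            setattr(cfg, key, val)
    return cfg


def _header(config: RunConfig, extra: dict | None = None) -> list[str]:
    meta = {
        "memflux_version": __version__,
        "F_C_per_mol": FARADAY,
        "R_J_per_molK": GAS_CONSTANT,
        "T_K": config.T,
        "sign_convention": "positive flux = blood to dialysate",
        "lambda_convention": ("lam = d_max/b (literal)" if config.lam_literal
                              else "lam = (d_max/2)/b (solute radius)"),
        "eta_exponent": config.eta_exponent,
        "double_hindrance": config.double_hindrance,
        "d0_source": config.d0_source,
        "diffusivity_units": "cm^2/s" if config.units == "paper" else "m^2/s",
        "seed": config.seed,
    }
    if extra:
        meta.update(extra)
    return [f"# {k} = {v}" for k, v in meta.items()]


def _resolve_toxins(config: RunConfig) -> list[ToxinSpecies]:
    catalog = (load_catalog(config.catalog) if config.catalog
               else builtin_catalog())
    if config.toxins is None:
        return catalog
    return [get_toxin(name, catalog) for name in config.toxins]


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute a full run and write its report bundle; returns the paths.

    Emits a dimensions report when structure files are configured, an
    effective-diffusivity comparison across the two configured membranes,
    and per-toxin applied-potential (and, when pH values are set, pH)
    sweep tables.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    toxins = _resolve_toxins(config)
    membranes = [load_membrane(m) for m in config.membranes]
    if config.thickness_override_m is not None:
        membranes = [dataclasses.replace(m, x=config.thickness_override_m)
                     for m in membranes]
    mem_a, mem_b = membranes

    # 1. dimensions report
    if config.structures:
        lines = _header(config) + [
            "accession\tn_atoms\td_max_A\td_max_nm\tendpoint_i\tendpoint_j"]
        for spath in config.structures:
            model = read_structure(spath)
            dim = max_dimension(model)
            lines.append("\t".join([
                Path(spath).stem, str(dim.n_atoms),
                f"{dim.d_max_A:.4f}", f"{dim.d_max_nm:.4f}",
                str(dim.endpoints[0]), str(dim.endpoints[1])]))
        path = outdir / "dimensions.tsv"
        path.write_text("\n".join(lines) + "\n")
        outputs["dimensions"] = path

    # 2. effective-diffusivity comparison across the two membranes
    d_eff_a = reference_highflux_deff() if config.d0_source == "reference" \
        else None
    table = compare_membranes(toxins, mem_a, mem_b, d_eff_a=d_eff_a,
                              lam_literal=config.lam_literal,
                              eta_exponent=config.eta_exponent)
    if table.empty:
        raise ConfigError(
            "toxins", "no toxin in the selection has a reference effective "
                      "diffusivity; use d0_source = predicted")
    lines = _header(config, {"membrane_a": mem_a.label,
                             "membrane_b": mem_b.label}) + [
        "toxin\td_max_nm\tk_diff_a\tk_diff_b\td0\td_eff_a\td_eff_b\tratio_b_over_a"]
    for _, row in table.iterrows():
        scale = 1.0 if config.units == "paper" else 1e-4
        lines.append("\t".join([
            row["toxin"], f"{row['d_max_nm']:.2f}",
            _fmt(row["k_diff_a"]), _fmt(row["k_diff_b"]),
            _fmt(row["d0_cm2_s"] * scale),
            _fmt(row["d_eff_a_cm2_s"] * scale),
            _fmt(row["d_eff_b_cm2_s"] * scale),
            _fmt(row["ratio_b_over_a"])]))
    path = outdir / "deff_comparison.tsv"
    path.write_text("\n".join(lines) + "\n")
    outputs["deff_comparison"] = path

    # 3. sweep tables (toxins with a known plasma concentration only)
    from .transport import diffusivity, hindrance, infer_d0

    forces = DrivingForces(T=config.T, pH_blood=config.ph_blood,
                           pH_dialysate=config.ph_dialysate)
    for toxin in toxins:
        if toxin.c_normal is None:
            continue
        if d_eff_a is not None and toxin.name in d_eff_a:
            h = hindrance(toxin.d_max, mem_a, lam_literal=config.lam_literal)
            d0 = infer_d0(d_eff_a[toxin.name], h.k_diff)
            diff_b = diffusivity(toxin, mem_b, d0=d0,
                                 lam_literal=config.lam_literal)
        else:
            diff_b = diffusivity(toxin, mem_b, T=config.T,
                                 eta_exponent=config.eta_exponent,
                                 lam_literal=config.lam_literal)
        grid_V = [v * 1e-3 for v in config.dv_grid_mV]
        tab = sweep(toxin, mem_b, forces, "delta_V", grid_V, diff=diff_b,
                    double_hindrance=config.double_hindrance)
        lines = _header(config, {"toxin": toxin.name,
                                 "membrane": mem_b.label,
                                 "d_eff_cm2_s": _fmt(diff_b.d_eff),
                                 "electromigration": "per unit valence"
                                 if toxin.z is None else f"z = {toxin.z}"}) + [
            "delta_V_mV\tJ_diffusion\tJ_electromigration\tJ_pH\t"
            "J_convection\tJ_ultrafiltration\tJ_total"]
        for mv, b in zip(config.dv_grid_mV, tab.breakdowns):
            lines.append("\t".join(
                [f"{mv:g}"] + [_fmt(v) for v in (
                    b.j_diffusion, b.j_electromigration, b.j_ph,
                    b.j_convection, b.j_ultrafiltration, b.j_total)]))
        slug = toxin.name.lower().replace(" ", "_").replace("-", "")
        path = outdir / f"sweep_dv_{slug}.tsv"
        path.write_text("\n".join(lines) + "\n")
        outputs[f"sweep_dv_{slug}"] = path

    return outputs
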