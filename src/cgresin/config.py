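"""Run configuration: a validated YAML schema driving the full pipeline.

Internal units are kJ/mol, nm, ps, amu, K, bar.  The bonding cutoff may be
given in Angstrom (``bonding_cutoff_angstrom: 5.5``); it is converted to nm
at load time and the original value is recorded in the manifest.
Unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .engine import EnsembleSpec
from .molecules import Formulation, make_formulation
from .polymerize import PolymerizationSchedule

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_config"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    formulation: Formulation
    mass_basis: int = 1000
    n_active: int = 10
    density_guess: float = 0.9  # g/cm^3 initial packing density
    min_dist: float = 0.25  # nm packing hard core
    box_scale: float = 1.0
    ensemble: EnsembleSpec = field(default_factory=EnsembleSpec)
    schedule: PolymerizationSchedule = field(default_factory=PolymerizationSchedule)
    equilibrate_steps: int = 80_000
    sweep_t_start: float = 150.0
    sweep_t_end: float = 500.0
    sweep_steps: int = 1_000_000
    sweep_segments: int = 50
    forcefield_path: str | None = None  # None -> bundled default table
    prefactor: str = "half"
    seed: int = 0
    outdir: str = "run"
    raw: dict = field(default_factory=dict, repr=False)


_TOP_KEYS = {
    "formulation", "pack", "ensemble", "schedule", "equilibrate", "sweep",
    "forcefield", "seed", "outdir",
}
_SECTION_KEYS = {
    "formulation": {"w_bisgma", "mass_basis"},
    "pack": {"n_active", "density_guess", "min_dist", "box_scale"},
    "ensemble": {"temperature", "pressure", "tau_t", "tau_p", "timestep_fs",
                 "constraint_tol", "compressibility"},
    "schedule": {"bonding_cutoff_nm", "bonding_cutoff_angstrom", "bonds_per_relaxation",
                 "relax_steps", "retry_steps", "max_failed_attempts", "max_attempts"},
    "equilibrate": {"steps"},
    "sweep": {"t_start", "t_end", "steps", "segments"},
    "forcefield": {"path", "prefactor"},
}


def _check_keys(section: str, d: dict):
    unknown = set(d) - _SECTION_KEYS[section]
    if unknown:
        raise ConfigError(f"unknown keys in [{section}]: {sorted(unknown)}")


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    f = raw.get("formulation", {})
    _check_keys("formulation", f)
    formulation = make_formulation(float(f.get("w_bisgma", 0.5)), int(f.get("mass_basis", 1000)))
    p = raw.get("pack", {})
    _check_keys("pack", p)
    e = raw.get("ensemble", {})
    _check_keys("ensemble", e)
    ensemble = EnsembleSpec(**e)
    s = dict(raw.get("schedule", {}))
    _check_keys("schedule", s)
    if "bonding_cutoff_angstrom" in s:
        if "bonding_cutoff_nm" in s:
            raise ConfigError("give the bonding cutoff in nm or Angstrom, not both")
        s["bonding_cutoff_nm"] = float(s.pop("bonding_cutoff_angstrom")) / 10.0
    sched_kwargs = {("bonding_cutoff" if k == "bonding_cutoff_nm" else k): v for k, v in s.items()}
    schedule = PolymerizationSchedule(**sched_kwargs)
    eq = raw.get("equilibrate", {})
    _check_keys("equilibrate", eq)
    sw = raw.get("sweep", {})
    _check_keys("sweep", sw)
    ffsec = raw.get("forcefield", {})
    _check_keys("forcefield", ffsec)
    return RunConfig(
        formulation=formulation,
        mass_basis=int(f.get("mass_basis", 1000)),
        n_active=int(p.get("n_active", 10)),
        density_guess=float(p.get("density_guess", 0.9)),
        min_dist=float(p.get("min_dist", 0.25)),
        box_scale=float(p.get("box_scale", 1.0)),
        ensemble=ensemble,
        schedule=schedule,
        equilibrate_steps=int(eq.get("steps", 80_000)),
        sweep_t_start=float(sw.get("t_start", 150.0)),
        sweep_t_end=float(sw.get("t_end", 500.0)),
        sweep_steps=int(sw.get("steps", 1_000_000)),
        sweep_segments=int(sw.get("segments", 50)),
        forcefield_path=ffsec.get("path"),
        prefactor=str(ffsec.get("prefactor", "half")),
        seed=int(raw.get("seed", 0)),
        outdir=str(raw.get("outdir", "run")),
        raw=raw,
    )


def dump_config(cfg: RunConfig) -> str:
    """Serialize back to the YAML schema (round-trips through load_config)."""
    doc = {
        "formulation": {"w_bisgma": cfg.formulation.w_bisgma, "mass_basis": cfg.mass_basis},
        "pack": {"n_active": cfg.n_active, "density_guess": cfg.density_guess,
                 "min_dist": cfg.min_dist, "box_scale": cfg.box_scale},
        "ensemble": {k: v for k, v in asdict(cfg.ensemble).items()},
        "schedule": {
            "bonding_cutoff_nm": cfg.schedule.bonding_cutoff,
            "bonds_per_relaxation": cfg.schedule.bonds_per_relaxation,
            "relax_steps": cfg.schedule.relax_steps,
            "retry_steps": cfg.schedule.retry_steps,
            "max_failed_attempts": cfg.schedule.max_failed_attempts,
            "max_attempts": cfg.schedule.max_attempts,
        },
        "equilibrate": {"steps": cfg.equilibrate_steps},
        "sweep": {"t_start": cfg.sweep_t_start, "t_end": cfg.sweep_t_end,
                  "steps": cfg.sweep_steps, "segments": cfg.sweep_segments},
        "forcefield": {"path": cfg.forcefield_path, "prefactor": cfg.prefactor},
        "seed": cfg.seed,
        "outdir": cfg.outdir,
    }
    return yaml.safe_dump(doc, sort_keys=False)
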