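"""Deterministic miniature systems for tests and demonstrations.

Available fixtures:

* ``tegdma1`` — a single TEGDMA molecule (6 beads) in a roomy box.
* ``bisgma1`` — a single Bis-GMA molecule (15 beads).
* ``mixed14`` — 10 TEGDMA + 4 Bis-GMA (120 beads) with 2 initiators, packed
  loosely so short MD runs are stable out of the box.
* ``chain5`` — 10 TEGDMA with one initiator that has been pre-propagated
  through 5 backbone bonds (a 6-unit linear chain), for conversion and
  network bookkeeping tests.
"""

from __future__ import annotations

import numpy as np

from .molecules import Formulation
from .polymerize import apply_bonding, find_candidates
from .system import SystemState, Topology, pack_box, write_gro

__all__ = ["FIXTURE_NAMES", "make_fixture"]

FIXTURE_NAMES = ("tegdma1", "bisgma1", "mixed14", "chain5")


def _single(species_counts: tuple[int, int], n_active=0, seed=0, density=0.3):
    formulation = Formulation(w_bisgma=0.0, n_tegdma=species_counts[0], n_bisgma=species_counts[1])
    return pack_box(formulation, n_active=n_active, target_density_guess=density, seed=seed)


def make_fixture(name: str, seed: int = 0, outdir=None) -> tuple[Topology, SystemState]:
    """Build a named fixture; optionally write a GRO file into ``outdir``."""
    if name == "tegdma1":
        topo, state = _single((1, 0), seed=seed, density=0.05)
    elif name == "bisgma1":
        topo, state = _single((0, 1), seed=seed, density=0.05)
    elif name == "mixed14":
        formulation = Formulation(w_bisgma=0.0, n_tegdma=10, n_bisgma=4)
        topo, state = pack_box(formulation, n_active=2, target_density_guess=0.45, seed=seed)
    elif name == "chain5":
        formulation = Formulation(w_bisgma=0.0, n_tegdma=10, n_bisgma=0)
        topo, state = pack_box(formulation, n_active=1, target_density_guess=0.45, seed=seed)
        # propagate the single radical 5 times with an unbounded cutoff;
        # each attempt forms exactly one bond and transfers the label
        for _ in range(5):
            cands = find_candidates(state, topo, cutoff=float(np.max(state.box)) * 0.87)
            formed = apply_bonding(state, topo, cands[:1])
            if not formed:
                raise RuntimeError("chain5 fixture could not propagate")
    else:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    if outdir is not None:
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_gro(out / f"{name}.gro", topo, state, title=f"cgresin fixture {name} seed={seed}")
    return topo, state
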