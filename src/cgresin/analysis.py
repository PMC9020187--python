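"""Curing observables: density, shrinkage, double-bond conversion, Tg.

Density is reported with the *real* molar masses of the monomers (the
coarse-grain Martini masses are used only for the dynamics, so converting a
box volume to a physical density requires the true molecular weights).
Double-bond conversion is the fraction of methacrylate beads whose C=C has
been consumed — beads incorporated into polymer bonds, plus (by default)
the initiator radicals whose double bond opened at initiation.  The glass
transition is estimated from a heating sweep as the intersection of two
straight lines fitted piecewise to density versus temperature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .system import SystemState, Topology, minimum_image

__all__ = [
    "SweepSeries",
    "TgFit",
    "DegenerateFitWarning",
    "density",
    "conversion",
    "shrinkage",
    "fit_tg",
    "bonded_distributions",
    "cg_map",
]

AMU_TO_G = 1.66053906660e-24
NM3_TO_CM3 = 1.0e-21


class DegenerateFitWarning(UserWarning):
    """Two-segment fit does not beat a single line: data look collinear."""


@dataclass
class SweepSeries:
    """Density-versus-temperature observations from an annealing run."""

    temperatures: np.ndarray  # K, strictly monotone
    densities: np.ndarray  # g/cm^3
    counts: np.ndarray | None = None  # samples per point

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        dt = np.diff(self.temperatures)
        if len(dt) and not (np.all(dt > 0) or np.all(dt < 0)):
            raise ValueError("sweep temperatures must be strictly monotone")
        if np.any(self.densities <= 0):
            raise ValueError("densities must be positive")
        if self.counts is None:
            self.counts = np.ones_like(self.temperatures)

    def __len__(self):
        return len(self.temperatures)


def density(state: SystemState, topology: Topology, mass_mode: str = "real_mw") -> float:
    """Mass density in g/cm^3.

    ``mass_mode="real_mw"`` distributes each species' true molar mass over
    its beads; ``"martini"`` uses the coarse-grain simulation masses.
    """
    vol = state.volume
    if vol <= 0:
        raise ValueError("box volume must be positive")
    if topology.n_beads == 0:
        return 0.0
    if mass_mode == "real_mw":
        mass_amu = float(np.sum(topology.real_masses()))
    elif mass_mode == "martini":
        from .forcefield import DEFAULT_MASSES, SIZE_CLASS
        mass_amu = float(sum(DEFAULT_MASSES[SIZE_CLASS[t]] for t in topology.type_codes))
    else:
        raise ValueError(f"unknown mass mode {mass_mode!r}")
    return mass_amu * AMU_TO_G / (vol * NM3_TO_CM3)


def conversion(topology: Topology, count_initiators_as_reacted: bool = True) -> float:
    """Double-bond conversion: fraction of methacrylate (label-1) beads consumed.

    A bead counts as reacted when it participates in at least one polymer
    bond; with ``count_initiators_as_reacted`` the initiator radicals (whose
    double bond opened at initiation) count too, mirroring the radical
    mechanism.
    """
    label1 = topology.mapping_labels == 1
    total = int(np.sum(label1))
    if total == 0:
        return 0.0
    deg = topology.polymer_degree()
    reacted = (deg > 0) & label1
    if count_initiators_as_reacted:
        # an initiator that never propagated still carries the active flag
        # and its double bond opened at initiation
        reacted |= topology.active & label1
    return float(np.sum(reacted)) / total


def shrinkage(volume_before: float, volume_after: float) -> float:
    """Volumetric curing shrinkage in percent; negative values mean expansion."""
    if volume_before <= 0:
        raise ValueError("reference volume must be positive")
    return 100.0 * (volume_before - volume_after) / volume_before


@dataclass
class TgFit:
    """Two-line piecewise fit of a density-temperature sweep."""

    t_intersection: float  # K
    slope_low: float  # g/cm^3/K
    slope_high: float
    intercept_low: float
    intercept_high: float
    split_index: int
    ssr: float
    ssr_single_line: float
    degenerate: bool


def fit_tg(series: SweepSeries, min_points_per_side: int = 3, rel_improvement: float = 1e-3) -> TgFit:
    """Glass-transition estimate: intersection of two piecewise linear fits.

    Every interior split with at least ``min_points_per_side`` points per
    side is scanned; the split minimizing the total squared residual wins.
    If no split improves on a single straight line by ``rel_improvement``
    (relative), a :class:`DegenerateFitWarning` is raised and the single-line
    result is returned with ``degenerate=True``.
    """
    t = np.asarray(series.temperatures, dtype=float)
    d = np.asarray(series.densities, dtype=float)
    n = len(t)
    if n < 2 * min_points_per_side:
        raise ValueError(f"need at least {2*min_points_per_side} sweep points")

    def ols(x, y):
        coef = np.polyfit(x, y, 1)
        resid = y - np.polyval(coef, x)
        return coef, float(resid @ resid)

    single_coef, ssr1 = ols(t, d)
    best = None
    for split in range(min_points_per_side, n - min_points_per_side + 1):
        c_lo, s_lo = ols(t[:split], d[:split])
        c_hi, s_hi = ols(t[split:], d[split:])
        ssr = s_lo + s_hi
        if best is None or ssr < best[0]:
            best = (ssr, split, c_lo, c_hi)
    ssr, split, c_lo, c_hi = best
    degenerate = ssr1 > 0 and (ssr1 - ssr) < rel_improvement * ssr1 or abs(c_lo[0] - c_hi[0]) < 1e-15
    if ssr1 == 0:
        degenerate = abs(c_lo[0] - c_hi[0]) < 1e-15
    if degenerate:
        warnings.warn(
            "piecewise fit does not improve on a single line; sweep looks collinear",
            DegenerateFitWarning,
        )
        return TgFit(
            t_intersection=float("nan"), slope_low=single_coef[0], slope_high=single_coef[0],
            intercept_low=single_coef[1], intercept_high=single_coef[1],
            split_index=split, ssr=ssr1, ssr_single_line=ssr1, degenerate=True,
        )
    t_int = (c_hi[1] - c_lo[1]) / (c_lo[0] - c_hi[0])
    return TgFit(
        t_intersection=float(t_int), slope_low=float(c_lo[0]), slope_high=float(c_hi[0]),
        intercept_low=float(c_lo[1]), intercept_high=float(c_hi[1]),
        split_index=split, ssr=ssr, ssr_single_line=ssr1, degenerate=False,
    )


# ---------------------------------------------------------------------------
# bonded distributions and mapping
# ---------------------------------------------------------------------------

def _dihedral_angles(pos, idx, box):
    b1 = minimum_image(pos[idx[:, 1]], pos[idx[:, 0]], box)
    b2 = minimum_image(pos[idx[:, 2]], pos[idx[:, 1]], box)
    b3 = minimum_image(pos[idx[:, 3]], pos[idx[:, 2]], box)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    l2 = np.linalg.norm(b2, axis=1)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2) / np.maximum(l2, 1e-12)
    return np.degrees(np.arctan2(y, x))


def bonded_distributions(
    trajectory: list[np.ndarray],
    topology: Topology,
    box: np.ndarray,
    terms: str = "bonds",
    bins: int = 60,
    prominence: float = 0.05,
) -> dict:
    """Normalized histograms of bond lengths / angles / dihedral angles.

    ``trajectory`` is a list of position frames.  For dihedrals the result
    includes a mode count above the given prominence (fraction of peak
    height), useful for checking the bimodal ring-rotation statistics.
    """
    if not trajectory:
        raise ValueError("need at least one frame")
    if terms == "bonds":
        idx = topology.bond_idx
        if len(idx) == 0:
            raise ValueError("no bonds selected")
        vals = np.concatenate([
            np.linalg.norm(minimum_image(p[idx[:, 0]], p[idx[:, 1]], box), axis=1)
            for p in trajectory
        ])
        rng = (vals.min() * 0.9, vals.max() * 1.1)
    elif terms == "angles":
        idx = topology.angle_idx
        if len(idx) == 0:
            raise ValueError("no angles selected")
        vals = []
        for p in trajectory:
            rij = minimum_image(p[idx[:, 0]], p[idx[:, 1]], box)
            rkj = minimum_image(p[idx[:, 2]], p[idx[:, 1]], box)
            cosb = np.clip(
                np.einsum("ij,ij->i", rij, rkj)
                / (np.linalg.norm(rij, axis=1) * np.linalg.norm(rkj, axis=1)),
                -1, 1,
            )
            vals.append(np.degrees(np.arccos(cosb)))
        vals = np.concatenate(vals)
        rng = (0.0, 180.0)
    elif terms in ("dihedrals", "impropers"):
        mask = topology.dihedral_improper if terms == "impropers" else ~topology.dihedral_improper
        idx = topology.dihedral_idx[mask]
        if len(idx) == 0:
            raise ValueError("no dihedrals selected")
        vals = np.concatenate([_dihedral_angles(p, idx, box) for p in trajectory])
        rng = (-180.0, 180.0)
    else:
        raise ValueError(f"unknown term selection {terms!r}")
    hist, edges = np.histogram(vals, bins=bins, range=rng, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    result = {"values": vals, "hist": hist, "bin_centers": centers, "mean": float(np.mean(vals))}
    if terms in ("dihedrals", "impropers"):
        # periodic padding so modes at the +-180 seam are counted once
        ext = np.concatenate([hist[-3:], hist, hist[:3]])
        peaks, _ = find_peaks(ext, prominence=prominence * max(hist.max(), 1e-12))
        peaks = [p - 3 for p in peaks if 0 <= p - 3 < len(hist)]
        result["n_modes"] = len(peaks)
        result["mode_positions"] = centers[peaks] if peaks else np.array([])
    return result


def cg_map(aa_trajectory: list[np.ndarray], mapping: dict[int, list[int]]) -> list[np.ndarray]:
    """Map all-atom frames to coarse-grain beads by centre of geometry.

    ``mapping`` assigns each bead an atom-index list; every mapped atom must
    belong to exactly one bead.  Bead positions are the unweighted mean of
    their atoms, per frame (Martini 3 centre-of-geometry convention).
    """
    seen: set[int] = set()
    for bead, atoms in mapping.items():
        if not atoms:
            raise ValueError(f"bead {bead} has no atoms assigned")
        dup = seen.intersection(atoms)
        if dup:
            raise ValueError(f"atoms assigned to more than one bead: {sorted(dup)}")
        seen.update(atoms)
    beads = sorted(mapping)
    out = []
    for frame in aa_trajectory:
        frame = np.asarray(frame, dtype=float)
        out.append(np.array([frame[mapping[b]].mean(axis=0) for b in beads]))
    return out
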