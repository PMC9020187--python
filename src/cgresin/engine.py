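"""Molecular-dynamics engine: forces, minimization, NVT/NPT propagation.

Integration is velocity Verlet at a 20 fs default timestep.  Temperature is
controlled by Bussi-style stochastic velocity rescaling (canonical sampling,
seed-reproducible) and pressure by an isotropic Berendsen weak-coupling
barostat.  Holonomic constraints (the rigid aromatic-ring triangles: two
bonds plus one angle expressed as a third distance) are enforced with SHAKE
on positions and a RATTLE-style velocity projection.

Internal units: nm, ps, amu, K, bar, kJ/mol.  With these units
1 amu nm^2 ps^-2 = 1 kJ/mol, so kinetic and potential energies add directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forcefield import ForceField
from .system import GeometryError, SystemState, Topology, neighbor_pairs

__all__ = [
    "KB",
    "PRESSURE_UNIT",
    "EnsembleSpec",
    "ConstraintError",
    "MinimizationError",
    "compute_forces",
    "minimize",
    "run_md",
    "shake_project",
    "initialize_velocities",
    "temperature_sweep",
]

KB = 0.00831446261815324  # kJ mol^-1 K^-1
PRESSURE_UNIT = 16.6054  # 1 kJ mol^-1 nm^-3 in bar

#: cap on the per-bead force from a single torsion term (kJ/mol/nm); guards
#: the collinear-geometry singularity of the dihedral gradient
DIHEDRAL_FORCE_CAP = 2000.0


class ConstraintError(RuntimeError):
    pass


class MinimizationError(RuntimeError):
    pass


@dataclass
class EnsembleSpec:
    """Thermostat/barostat targets and integration parameters.

    ``temperature=None`` gives NVE; ``pressure=None`` disables the barostat.
    """

    temperature: float | None = 298.0  # K
    pressure: float | None = 1.0  # bar
    tau_t: float = 1.0  # ps
    tau_p: float = 12.0  # ps
    timestep_fs: float = 20.0
    constraint_tol: float = 1.0e-4  # relative
    compressibility: float = 3.0e-4  # bar^-1, typical for a CG organic liquid

    def __post_init__(self):
        if self.temperature is not None and self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.timestep_fs <= 0:
            raise ValueError("timestep must be positive")

    @property
    def dt(self) -> float:
        return self.timestep_fs * 1.0e-3  # ps


# ---------------------------------------------------------------------------
# compiled term arrays (cached per topology version)
# ---------------------------------------------------------------------------

class _Compiled:
    def __init__(self, topology: Topology, ff: ForceField):
        self.version = getattr(topology, "_compiled_version", None)
        nb = len(topology.bond_idx)
        npoly = len(topology.polymer_bond_idx)
        if npoly:
            self.bond_idx = np.vstack([topology.bond_idx, np.array(topology.polymer_bond_idx, dtype=int)])
            self.bond_r0 = np.concatenate([topology.bond_r0, topology.polymer_bond_r0])
            self.bond_k = np.concatenate([topology.bond_k, topology.polymer_bond_k])
        else:
            self.bond_idx = topology.bond_idx
            self.bond_r0 = topology.bond_r0
            self.bond_k = topology.bond_k
        if topology.polymer_angle_idx:
            self.angle_idx = np.vstack([topology.angle_idx, np.array(topology.polymer_angle_idx, dtype=int)])
            self.angle_theta0 = np.radians(np.concatenate([topology.angle_theta0, topology.polymer_angle_theta0]))
            self.angle_k = np.concatenate([topology.angle_k, topology.polymer_angle_k])
        else:
            self.angle_idx = topology.angle_idx
            self.angle_theta0 = np.radians(topology.angle_theta0)
            self.angle_k = np.asarray(topology.angle_k)
        self.dihedral_idx = topology.dihedral_idx
        self.dihedral_phi0 = np.radians(topology.dihedral_phi0)
        self.dihedral_k = np.asarray(topology.dihedral_k)
        self.dihedral_n = np.asarray(topology.dihedral_n, dtype=float)
        self.dihedral_improper = topology.dihedral_improper
        self.constraint_idx = topology.constraint_idx
        self.constraint_d0 = topology.constraint_d0
        types = sorted(set(topology.type_codes)) or ["SC4"]
        t_index = {t: i for i, t in enumerate(types)}
        self.type_index = np.array([t_index[t] for t in topology.type_codes], dtype=int)
        nt = len(types)
        self.sigma = np.zeros((nt, nt))
        self.epsilon = np.zeros((nt, nt))
        for i, a in enumerate(types):
            for j, b in enumerate(types):
                self.sigma[i, j], self.epsilon[i, j] = ff.nonbonded.lookup(a, b)
        self.masses = topology.masses(ff)
        self.pref = ff._pref
        self.cutoff = ff.nonbonded.cutoff
        self.shift = ff.nonbonded.shift_mode == "potential-shift"
        self.n_constraints = len(self.constraint_idx)


def _get_compiled(topology: Topology, ff: ForceField) -> _Compiled:
    version = (len(topology.polymer_bond_idx), len(topology.polymer_angle_idx), id(ff))
    cached = getattr(topology, "_compiled", None)
    if cached is None or getattr(topology, "_compiled_key", None) != version:
        cached = _Compiled(topology, ff)
        topology._compiled = cached
        topology._compiled_key = version
    return cached


def _min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


def effective_cutoff(box: np.ndarray, cutoff: float, skin: float) -> float:
    """Largest usable cutoff under the minimum-image convention.

    Small demonstration boxes may be narrower than twice the nominal Martini
    cutoff; the interaction range is then truncated to fit the box.
    """
    return min(cutoff, float(np.min(box)) / 2.0 - skin - 1.0e-9)


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------

def compute_forces(
    state: SystemState,
    topology: Topology,
    ff: ForceField,
    pairs: np.ndarray | None = None,
    skin: float = 0.2,
    rc: float | None = None,
) -> tuple[np.ndarray, dict[str, float], float]:
    """Per-bead forces, energy breakdown and scalar virial.

    Returns ``(forces (N,3) kJ/mol/nm, energies by term class, virial kJ/mol)``
    where the virial is ``sum r_ij . f_ij`` over all interactions (used for
    the pressure).  Raises on overlapping beads (r < 1e-6 nm).
    """
    c = _get_compiled(topology, ff)
    pos = state.positions
    box = state.box
    n = len(pos)
    forces = np.zeros((n, 3))
    energies = {"bond": 0.0, "angle": 0.0, "dihedral": 0.0, "improper": 0.0, "lj": 0.0}
    virial = 0.0
    pref = c.pref

    if len(c.bond_idx):
        i, j = c.bond_idx[:, 0], c.bond_idx[:, 1]
        d = _min_image(pos[i] - pos[j], box)
        r = np.linalg.norm(d, axis=1)
        if np.any(r < 1.0e-6):
            raise FloatingPointError("overlapping bonded beads")
        dr = r - c.bond_r0
        energies["bond"] = float(np.sum(pref * c.bond_k * dr * dr))
        fmag = -2.0 * pref * c.bond_k * dr  # dE/dr with sign: force along +d on i
        fvec = (fmag / r)[:, None] * d
        np.add.at(forces, i, fvec)
        np.add.at(forces, j, -fvec)
        virial += float(np.sum(np.einsum("ij,ij->i", fvec, d)))

    if len(c.angle_idx):
        ii, jj, kk = c.angle_idx[:, 0], c.angle_idx[:, 1], c.angle_idx[:, 2]
        rij = _min_image(pos[ii] - pos[jj], box)
        rkj = _min_image(pos[kk] - pos[jj], box)
        lij = np.linalg.norm(rij, axis=1)
        lkj = np.linalg.norm(rkj, axis=1)
        cosb = np.clip(np.einsum("ij,ij->i", rij, rkj) / (lij * lkj), -1.0, 1.0)
        theta = np.arccos(cosb)
        sinb = np.maximum(np.sqrt(1.0 - cosb * cosb), 1.0e-8)
        dth = theta - c.angle_theta0
        energies["angle"] = float(np.sum(pref * c.angle_k * dth * dth))
        dedth = 2.0 * pref * c.angle_k * dth
        u = rij / lij[:, None]
        v = rkj / lkj[:, None]
        fi = (-dedth / (lij * sinb))[:, None] * (cosb[:, None] * u - v)
        fk = (-dedth / (lkj * sinb))[:, None] * (cosb[:, None] * v - u)
        np.add.at(forces, ii, fi)
        np.add.at(forces, kk, fk)
        np.add.at(forces, jj, -(fi + fk))
        virial += float(np.sum(np.einsum("ij,ij->i", fi, rij) + np.einsum("ij,ij->i", fk, rkj)))

    if len(c.dihedral_idx):
        ii, jj, kk, ll = (c.dihedral_idx[:, m] for m in range(4))
        b1 = _min_image(pos[jj] - pos[ii], box)
        b2 = _min_image(pos[kk] - pos[jj], box)
        b3 = _min_image(pos[ll] - pos[kk], box)
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        l2 = np.linalg.norm(b2, axis=1)
        x = np.einsum("ij,ij->i", n1, n2)
        y = np.einsum("ij,ij->i", np.cross(n1, n2), b2) / np.maximum(l2, 1e-12)
        phi = np.arctan2(y, x)
        arg = c.dihedral_n * phi - c.dihedral_phi0
        e_terms = c.dihedral_k * (1.0 + np.cos(arg))
        energies["improper"] = float(np.sum(e_terms[c.dihedral_improper]))
        energies["dihedral"] = float(np.sum(e_terms[~c.dihedral_improper]))
        dedphi = -c.dihedral_k * c.dihedral_n * np.sin(arg)
        n1sq = np.maximum(np.einsum("ij,ij->i", n1, n1), 1e-12)
        n2sq = np.maximum(np.einsum("ij,ij->i", n2, n2), 1e-12)
        dphi_dri = (-(l2 / n1sq))[:, None] * n1
        dphi_drl = (l2 / n2sq)[:, None] * n2
        a1 = (np.einsum("ij,ij->i", b1, b2) / np.maximum(l2 * l2, 1e-12))[:, None]
        a3 = (np.einsum("ij,ij->i", b3, b2) / np.maximum(l2 * l2, 1e-12))[:, None]
        dphi_drj = -dphi_dri - a1 * dphi_dri + a3 * dphi_drl
        dphi_drk = -dphi_drl + a1 * dphi_dri - a3 * dphi_drl
        g = -dedphi[:, None]
        fi, fj, fk, fl = g * dphi_dri, g * dphi_drj, g * dphi_drk, g * dphi_drl
        # the torsion gradient diverges when three beads approach collinearity
        # (soft adjacent angles make this reachable); cap the per-term force,
        # scaling all four contributions together so the term stays a valid
        # zero-net-force, zero-net-torque interaction
        fmax2 = np.max([np.einsum("ij,ij->i", f, f) for f in (fi, fj, fk, fl)], axis=0)
        over = fmax2 > DIHEDRAL_FORCE_CAP**2
        if np.any(over):
            scale = np.where(over, DIHEDRAL_FORCE_CAP / np.sqrt(np.maximum(fmax2, 1e-300)), 1.0)[:, None]
            fi, fj, fk, fl = fi * scale, fj * scale, fk * scale, fl * scale
        np.add.at(forces, ii, fi)
        np.add.at(forces, jj, fj)
        np.add.at(forces, kk, fk)
        np.add.at(forces, ll, fl)
        # virial in molecule-local coordinates (relative to bead j)
        virial += float(np.sum(
            np.einsum("ij,ij->i", fi, -b1)
            + np.einsum("ij,ij->i", fk, b2)
            + np.einsum("ij,ij->i", fl, b2 + b3)
        ))

    if rc is None:
        rc = effective_cutoff(box, c.cutoff, skin if pairs is None else 0.0)
    if pairs is None:
        try:
            pairs = neighbor_pairs(state, topology, rc, skin=skin)
        except GeometryError:
            pairs = np.zeros((0, 2), dtype=int)
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        d = _min_image(pos[i] - pos[j], box)
        r2 = np.einsum("ij,ij->i", d, d)
        if np.any(r2 < 1.0e-12):
            raise FloatingPointError("overlapping nonbonded beads")
        within = r2 <= rc * rc
        if np.any(within):
            i, j, d, r2 = i[within], j[within], d[within], r2[within]
            sig = c.sigma[c.type_index[i], c.type_index[j]]
            eps = c.epsilon[c.type_index[i], c.type_index[j]]
            sr6 = (sig * sig / r2) ** 3
            sr12 = sr6 * sr6
            e = 4.0 * eps * (sr12 - sr6)
            if c.shift:
                src6 = (sig / rc) ** 6
                e -= 4.0 * eps * (src6 * src6 - src6)
            energies["lj"] = float(np.sum(e))
            fmag_over_r2 = 24.0 * eps * (2.0 * sr12 - sr6) / r2
            fvec = fmag_over_r2[:, None] * d
            np.add.at(forces, i, fvec)
            np.add.at(forces, j, -fvec)
            virial += float(np.sum(fmag_over_r2 * r2))

    energies["potential"] = sum(energies.values())
    return forces, energies, virial


# ---------------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------------

def _color_constraints(constraint_idx: np.ndarray) -> list[np.ndarray]:
    """Greedy grouping so no bead repeats within a group.

    Within a group all corrections are independent and can be applied
    simultaneously; sweeping the groups in order is a Gauss-Seidel SHAKE
    pass (each ring triangle spreads over three groups).
    """
    groups: list[list[int]] = []
    group_beads: list[set[int]] = []
    for c, (i, j) in enumerate(constraint_idx):
        for g, beads in enumerate(group_beads):
            if i not in beads and j not in beads:
                groups[g].append(c)
                beads.update((int(i), int(j)))
                break
        else:
            groups.append([c])
            group_beads.append({int(i), int(j)})
    return [np.array(g, dtype=int) for g in groups]


def shake_project(
    positions: np.ndarray,
    constraint_idx: np.ndarray,
    d0: np.ndarray,
    masses: np.ndarray,
    box: np.ndarray,
    tol: float = 1.0e-4,
    max_iter: int = 500,
    ref_positions: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Project positions onto the constraint manifold (iterative SHAKE).

    Corrections are applied along the reference constraint directions (the
    pre-step geometry when ``ref_positions`` is given, the current geometry
    otherwise), swept in Gauss-Seidel order: constraints are grouped so a
    pass never touches the same bead twice, which makes each ring triangle
    converge like classic sequential SHAKE.  All constrained distances end
    within relative ``tol`` of their targets.  Returns the corrected
    positions and the iteration count.
    """
    if len(constraint_idx) == 0:
        return positions, 0
    pos = positions.copy()
    d0 = np.asarray(d0)
    groups = _color_constraints(constraint_idx)
    ii, jj = constraint_idx[:, 0], constraint_idx[:, 1]
    ref = positions if ref_positions is None else ref_positions
    s_ref_all = _min_image(ref[ii] - ref[jj], box)
    for it in range(1, max_iter + 1):
        s = _min_image(pos[ii] - pos[jj], box)
        r = np.linalg.norm(s, axis=1)
        if np.max(np.abs(r - d0) / d0) < tol:
            return pos, it - 1
        for g in groups:
            i, j = ii[g], jj[g]
            inv_mi = 1.0 / masses[i]
            inv_mj = 1.0 / masses[j]
            s = _min_image(pos[i] - pos[j], box)
            r2 = np.einsum("ij,ij->i", s, s)
            s_ref = s_ref_all[g]
            dot = np.einsum("ij,ij->i", s, s_ref)
            # fall back to the current direction if the reference has rotated away
            bad = dot < 0.1 * np.sqrt(r2) * np.linalg.norm(s_ref, axis=1)
            s_dir = np.where(bad[:, None], s, s_ref)
            dot = np.where(bad, r2, dot)
            gfac = (r2 - d0[g] * d0[g]) / (2.0 * (inv_mi + inv_mj) * dot)
            corr = gfac[:, None] * s_dir
            pos[i] -= corr * inv_mi[:, None]
            pos[j] += corr * inv_mj[:, None]
    raise ConstraintError(f"SHAKE failed to converge within {max_iter} iterations")


def _rattle_velocities(vel, positions, constraint_idx, d0, masses, box, tol, max_iter=100):
    """Zero the relative velocity along every constraint (RATTLE stage 2)."""
    if len(constraint_idx) == 0:
        return vel
    v = vel.copy()
    groups = _color_constraints(constraint_idx)
    ii, jj = constraint_idx[:, 0], constraint_idx[:, 1]
    s_all = _min_image(positions[ii] - positions[jj], box)
    r2_all = np.einsum("ij,ij->i", s_all, s_all)
    vscale = max(float(np.max(np.abs(v))), 1e-6)
    thresh = tol * vscale
    for _ in range(max_iter):
        rv = np.einsum("ij,ij->i", v[ii] - v[jj], s_all) / np.sqrt(r2_all)
        if np.max(np.abs(rv)) < thresh:
            break
        for g in groups:
            i, j = ii[g], jj[g]
            inv_mi = 1.0 / masses[i]
            inv_mj = 1.0 / masses[j]
            s = s_all[g]
            gfac = np.einsum("ij,ij->i", v[i] - v[j], s) / ((inv_mi + inv_mj) * r2_all[g])
            corr = gfac[:, None] * s
            v[i] -= corr * inv_mi[:, None]
            v[j] += corr * inv_mj[:, None]
    return v


# ---------------------------------------------------------------------------
# minimization
# ---------------------------------------------------------------------------

def minimize(
    state: SystemState,
    topology: Topology,
    ff: ForceField,
    force_tol: float = 50.0,
    max_steps: int = 500,
    max_displacement: float = 0.02,
) -> SystemState:
    """Steepest-descent energy minimization with adaptive step control.

    Accepted steps never increase the energy; constrained distances are
    re-projected with SHAKE after every accepted move.  Stops when the
    maximum per-bead force drops below ``force_tol`` (kJ/mol/nm) or after
    ``max_steps``.
    """
    st = state.copy()
    c = _get_compiled(topology, ff)
    forces, energies, _ = compute_forces(st, topology, ff)
    e = energies["potential"]
    if math.isnan(e):
        raise MinimizationError("initial energy is NaN")
    alpha = 1.0e-4
    for _ in range(max_steps):
        fmax = float(np.max(np.linalg.norm(forces, axis=1))) if len(forces) else 0.0
        if fmax <= force_tol:
            break
        step = forces * alpha
        maxd = np.max(np.linalg.norm(step, axis=1))
        if maxd > max_displacement:
            step *= max_displacement / maxd
        trial = st.positions + step
        if c.n_constraints:
            trial, _ = shake_project(trial, c.constraint_idx, c.constraint_d0,
                                     c.masses, st.box, tol=1e-6)
        trial_state = SystemState(trial, st.velocities, st.box, st.seed)
        new_forces, new_en, _ = compute_forces(trial_state, topology, ff)
        e_new = new_en["potential"]
        if math.isnan(e_new):
            raise MinimizationError("energy diverged to NaN during minimization")
        if e_new <= e:
            st = trial_state
            forces, e = new_forces, e_new
            alpha *= 1.2
        else:
            alpha *= 0.5
            if alpha < 1.0e-12:
                break
    return st


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def initialize_velocities(
    state: SystemState, topology: Topology, ff: ForceField, temperature: float, seed: int
) -> None:
    """Maxwell-Boltzmann velocities at ``temperature``, COM motion removed."""
    c = _get_compiled(topology, ff)
    rng = np.random.default_rng(seed)
    sig = np.sqrt(KB * temperature / c.masses)[:, None]
    v = rng.normal(size=(state.n_beads, 3)) * sig
    v -= np.average(v, axis=0, weights=c.masses)
    state.velocities = v


def _kinetic(vel, masses):
    return 0.5 * float(np.sum(masses * np.einsum("ij,ij->i", vel, vel)))


def _bussi_factor(kin, ndf, target_kin, c, rng):
    """Stochastic velocity-rescaling factor (canonical sampling through rescaling)."""
    r1 = rng.normal()
    ssum = 2.0 * rng.gamma(0.5 * (ndf - 1)) if ndf > 1 else 0.0
    ratio = target_kin / (ndf * kin)
    a2 = c + (1.0 - c) * ratio * (r1 * r1 + ssum) + 2.0 * r1 * math.sqrt(c * (1.0 - c) * ratio)
    return math.sqrt(max(a2, 1.0e-12))


def run_md(
    state: SystemState,
    topology: Topology,
    ff: ForceField,
    ensemble: EnsembleSpec,
    n_steps: int,
    seed: int = 0,
    sample_stride: int = 100,
    skin: float = 0.2,
) -> tuple[SystemState, pd.DataFrame]:
    """Velocity-Verlet propagation with thermostat/barostat and constraints.

    Returns the final state and a table of sampled observables (step, time,
    temperature, pressure, volume, density with Martini masses, energy
    breakdown, max constraint residual).  Deterministic for a fixed seed.
    """
    st = state.copy()
    c = _get_compiled(topology, ff)
    rng = np.random.default_rng(seed)
    dt = ensemble.dt
    masses = c.masses
    inv_m = (1.0 / masses)[:, None]
    n = st.n_beads
    ndf = max(3 * n - c.n_constraints - 3, 1)
    records = []

    rc_nominal = c.cutoff

    def build_pairs(s):
        rc = effective_cutoff(s.box, rc_nominal, skin)
        try:
            return neighbor_pairs(s, topology, rc, skin=skin), s.positions.copy(), rc
        except GeometryError:
            return np.zeros((0, 2), dtype=int), s.positions.copy(), rc

    pairs, ref_pos, rc_cur = build_pairs(st)
    forces, energies, virial = compute_forces(st, topology, ff, pairs=pairs, rc=rc_cur)
    shake_res = 0.0

    for step in range(1, n_steps + 1):
        st.velocities = st.velocities + 0.5 * dt * forces * inv_m
        unconstrained = st.positions + dt * st.velocities
        if c.n_constraints:
            new_pos, _ = shake_project(unconstrained, c.constraint_idx, c.constraint_d0,
                                       masses, st.box, tol=ensemble.constraint_tol,
                                       ref_positions=st.positions)
            st.velocities = st.velocities + (new_pos - unconstrained) / dt
            st.positions = new_pos
        else:
            st.positions = unconstrained
        # neighbor refresh when displacement exceeds half the skin
        disp = np.max(np.linalg.norm(st.positions - ref_pos, axis=1)) if n else 0.0
        if disp > 0.45 * skin or len(ref_pos) != n:
            pairs, ref_pos, rc_cur = build_pairs(st)
        forces, energies, virial = compute_forces(st, topology, ff, pairs=pairs, rc=rc_cur)
        st.velocities = st.velocities + 0.5 * dt * forces * inv_m
        if c.n_constraints:
            st.velocities = _rattle_velocities(st.velocities, st.positions, c.constraint_idx,
                                               c.constraint_d0, masses, st.box,
                                               ensemble.constraint_tol)
        kin = _kinetic(st.velocities, masses)
        if ensemble.temperature is not None and kin > 0:
            cfac = math.exp(-dt / ensemble.tau_t)
            target_kin = 0.5 * ndf * KB * ensemble.temperature
            st.velocities = st.velocities * _bussi_factor(kin, ndf, target_kin, cfac, rng)
            kin = _kinetic(st.velocities, masses)
        temp = 2.0 * kin / (ndf * KB)
        # pressure: ideal + virial term (constraint virial approximated by
        # projecting the unconstrained forces onto the constraint directions)
        w = virial
        if c.n_constraints:
            i, j = c.constraint_idx[:, 0], c.constraint_idx[:, 1]
            s = _min_image(st.positions[i] - st.positions[j], st.box)
            r = np.linalg.norm(s, axis=1)
            u = s / r[:, None]
            rel_acc = np.einsum("ij,ij->i", forces[i] / masses[i][:, None] - forces[j] / masses[j][:, None], u)
            lam = rel_acc / (1.0 / masses[i] + 1.0 / masses[j])
            w += float(np.sum(-lam * r))
        vol = st.volume
        pressure = (2.0 * kin + w) / (3.0 * vol) * PRESSURE_UNIT
        if ensemble.pressure is not None:
            mu = (1.0 - ensemble.compressibility * dt / ensemble.tau_p
                  * (ensemble.pressure - pressure)) ** (1.0 / 3.0)
            mu = min(max(mu, 0.98), 1.02)
            st.box = st.box * mu
            st.positions = st.positions * mu
            ref_pos = ref_pos * mu
            if c.n_constraints and abs(mu - 1.0) > 0.1 * ensemble.constraint_tol:
                # isotropic scaling stretches the rigid rings; re-project
                st.positions, _ = shake_project(st.positions, c.constraint_idx,
                                                c.constraint_d0, masses, st.box,
                                                tol=ensemble.constraint_tol)
        if step % sample_stride == 0 or step == n_steps:
            if c.n_constraints:
                i, j = c.constraint_idx[:, 0], c.constraint_idx[:, 1]
                s = _min_image(st.positions[i] - st.positions[j], st.box)
                shake_res = float(np.max(np.abs(np.linalg.norm(s, axis=1) - c.constraint_d0) / c.constraint_d0))
            total_mass_g = float(np.sum(masses)) * 1.66053906660e-24
            records.append({
                "step": step,
                "time_ps": step * dt,
                "T_K": temp,
                "P_bar": pressure,
                "V_nm3": st.volume,
                "density_gcm3": total_mass_g / (st.volume * 1.0e-21),
                "E_kin": kin,
                "E_pot": energies["potential"],
                "E_bond": energies["bond"],
                "E_angle": energies["angle"],
                "E_dihedral": energies["dihedral"],
                "E_improper": energies["improper"],
                "E_lj": energies["lj"],
                "constraint_residual": shake_res,
            })
    return st, pd.DataFrame(records)


def equilibrate_system(
    state: SystemState,
    topology: Topology,
    ff: ForceField,
    ensemble: EnsembleSpec,
    n_steps: int,
    seed: int = 0,
    warmup_steps: int = 2000,
    warmup_dt_fs: float = 2.0,
) -> tuple[SystemState, pd.DataFrame]:
    """Minimize, warm up gently at a short timestep, then run the main NPT.

    Freshly packed boxes sit far from equilibrium (hard-core packing leaves
    steep repulsive contacts); integrating those directly at the production
    20 fs timestep destabilizes the constrained rings.  The warm-up relaxes
    the worst contacts at ``warmup_dt_fs`` before switching to the
    production timestep.
    """
    st = minimize(state, topology, ff)
    if ensemble.temperature:
        initialize_velocities(st, topology, ff, ensemble.temperature, seed)
    warm = EnsembleSpec(
        temperature=ensemble.temperature, pressure=None, tau_t=0.2,
        timestep_fs=warmup_dt_fs, constraint_tol=ensemble.constraint_tol,
    )
    st, _ = run_md(st, topology, ff, warm, warmup_steps, seed=seed + 1)
    st = minimize(st, topology, ff)
    return run_md(st, topology, ff, ensemble, n_steps, seed=seed + 2)


def temperature_sweep(
    state: SystemState,
    topology: Topology,
    ff: ForceField,
    t_start: float = 150.0,
    t_end: float = 500.0,
    n_steps: int = 1_000_000,
    pressure: float = 1.0,
    seed: int = 0,
    n_segments: int = 50,
    ensemble: EnsembleSpec | None = None,
    mass_mode: str = "real_mw",
):
    """Linear heating ramp under NPT; density recorded versus set point.

    The ramp is split into ``n_segments`` equal NPT segments; each segment's
    density is averaged over its second half and attributed to the segment's
    mean set-point temperature.  Returns an :class:`~cgresin.analysis.SweepSeries`.
    """
    from .analysis import SweepSeries, density

    ens = ensemble or EnsembleSpec(pressure=pressure)
    st = state.copy()
    steps_per = max(n_steps // n_segments, 2)
    temps, dens, counts = [], [], []
    for seg in range(n_segments):
        frac_mid = (seg + 0.5) / n_segments
        t_set = t_start + (t_end - t_start) * frac_mid
        seg_ens = EnsembleSpec(
            temperature=t_set, pressure=pressure, tau_t=ens.tau_t, tau_p=ens.tau_p,
            timestep_fs=ens.timestep_fs, constraint_tol=ens.constraint_tol,
            compressibility=ens.compressibility,
        )
        st, obs = run_md(st, topology, ff, seg_ens, steps_per, seed=seed + seg,
                         sample_stride=max(steps_per // 20, 1))
        tail = obs.iloc[len(obs) // 2:]
        vol = float(tail["V_nm3"].mean())
        st_avg = SystemState(st.positions, st.velocities,
                             st.box * (vol / st.volume) ** (1 / 3), st.seed)
        temps.append(t_set)
        dens.append(density(st_avg, topology, mass_mode=mass_mode))
        counts.append(len(tail))
    return SweepSeries(
        temperatures=np.array(temps), densities=np.array(dens), counts=np.array(counts)
    )
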