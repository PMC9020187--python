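"""Simulated chain-growth polymerization (cutoff bonding with label transfer).

Radical photopolymerization is emulated geometrically, with no explicit
kinetics and no termination reactions — only propagation.  Methacrylate
beads carry labels: *reactive* beads hold an unreacted C=C, *active* beads
hold the radical.  At each bonding attempt every active/reactive pair within
the cutoff (default 0.55 nm) is a candidate; candidates are matched greedily
nearest-first, a backbone bond and the associated backbone and
backbone-sidechain angles are added to the topology, and the active label
passes to the reaction partner so the chain can keep growing.

The schedule alternates bonding attempts with relaxation: after enough
successful bonds the system is minimized and relaxed by MD; after an empty
attempt a shorter retry MD is run, and the simulation terminates once a set
number of consecutive attempts form no bond.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import EnsembleSpec, minimize, run_md
from .forcefield import ForceField
from .system import SystemState, Topology, minimum_image

__all__ = [
    "PolymerizationSchedule",
    "PolymerBondParams",
    "BondEvent",
    "AttemptRecord",
    "find_candidates",
    "apply_bonding",
    "polymerization_run",
    "write_event_log",
]


@dataclass
class PolymerizationSchedule:
    """Bond/relax/terminate schedule of the simulated polymerization."""

    bonding_cutoff: float = 0.55  # nm (5.5 Angstrom)
    bonds_per_relaxation: int = 10
    relax_steps: int = 40_000
    retry_steps: int = 20_000
    max_failed_attempts: int = 40
    max_attempts: int | None = None  # safety cap; None = unlimited
    seed: int = 0

    def __post_init__(self):
        if self.bonding_cutoff <= 0:
            raise ValueError("bonding cutoff must be positive")
        for name in ("bonds_per_relaxation", "relax_steps", "retry_steps", "max_failed_attempts"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class PolymerBondParams:
    """Backbone potentials added after each reaction (no backbone dihedrals)."""

    bond_r0: float = 0.31  # nm
    bond_k: float = 35_000.0  # kJ/mol/nm^2
    backbone_angle_theta0: float = 125.0  # deg
    backbone_angle_k: float = 350.0  # kJ/mol/rad^2
    sidechain_angle_theta0: float = 80.0  # deg
    sidechain_angle_k: float = 50.0  # kJ/mol/rad^2


@dataclass(frozen=True)
class BondEvent:
    attempt: int
    bead_i: int  # the active bead that initiated
    bead_j: int  # the reactive partner (receives the active label)
    distance: float  # nm at formation time
    conversion_after: float
    volume_nm3: float


@dataclass
class AttemptRecord:
    attempt: int
    bonds_formed: int
    conversion: float
    volume_nm3: float


def find_candidates(
    state: SystemState,
    topology: Topology,
    cutoff: float,
    short_loop_exclusion: bool = True,
    short_loop_bonds: int = 5,
) -> list[tuple[int, int, float]]:
    """Active/reactive pairs within ``cutoff`` (inclusive), nearest first.

    Pairs already bonded are excluded, as are (optionally) pairs of
    methacrylate beads of the same molecule whose static-bond path is at
    most ``short_loop_bonds`` bonds — bonding those would close a tight,
    numerically degenerate ring through the monomer itself.  Ties are broken
    by lowest bead indices for reproducibility.
    """
    active = np.flatnonzero(topology.active)
    reactive = np.flatnonzero(topology.reactive_available & ~topology.consumed)
    if len(active) == 0 or len(reactive) == 0:
        return []
    existing = {tuple(sorted(map(int, p))) for p in topology.all_bond_pairs()}
    out = []
    d = minimum_image(state.positions[active][:, None, :], state.positions[reactive][None, :, :], state.box)
    dist = np.linalg.norm(d, axis=2)
    for ai, a in enumerate(active):
        for rj, r in enumerate(reactive):
            if a == r:
                continue
            dd = float(dist[ai, rj])
            if dd > cutoff:
                continue
            if tuple(sorted((int(a), int(r)))) in existing:
                continue
            if short_loop_exclusion and topology.mol_id[a] == topology.mol_id[r]:
                if _static_path_length(topology, int(a), int(r)) <= short_loop_bonds:
                    continue
            out.append((int(a), int(r), dd))
    out.sort(key=lambda t: (t[2], t[0], t[1]))
    return out


def _static_path_length(topology: Topology, a: int, b: int, cap: int = 12) -> int:
    """Shortest bond-graph path between two beads (BFS, capped)."""
    adj = topology.bonded_adjacency()
    frontier = {a}
    seen = {a}
    for depth in range(1, cap + 1):
        nxt = set()
        for u in frontier:
            for v in adj[u]:
                if v == b:
                    return depth
                if v not in seen:
                    seen.add(v)
                    nxt.add(v)
        frontier = nxt
        if not frontier:
            break
    return cap + 1


def _ester_neighbor(topology: Topology, bead: int) -> int | None:
    """The statically bonded ester-side (label 2) neighbor of a methacrylate bead."""
    for i, j in topology.bond_idx:
        if i == bead:
            return int(j)
        if j == bead:
            return int(i)
    return None


def apply_bonding(
    state: SystemState,
    topology: Topology,
    candidates: list[tuple[int, int, float]],
    params: PolymerBondParams = PolymerBondParams(),
) -> list[tuple[int, int, float]]:
    """Greedy nearest-first matching; returns the bonds formed as
    ``(active bead, partner bead, formation distance)`` triples (the
    topology is updated in place).

    Per call each active bead forms at most one bond and each reactive bead
    is consumed at most once.  For every bond formed the backbone bond is
    added, backbone angles appear across any bead that now has two polymer
    bonds, backbone-sidechain angles connect the new bond to each partner's
    ester bead, and the active label transfers to the partner.
    """
    used_active: set[int] = set()
    used_reactive: set[int] = set()
    formed: list[tuple[int, int, float]] = []
    for a, r, dist in candidates:
        if a in used_active or r in used_reactive or r in used_active or a in used_reactive:
            continue
        if topology.consumed[r] or not topology.reactive_available[r]:
            raise RuntimeError(f"candidate references consumed bead {r}")
        if not topology.active[a]:
            raise RuntimeError(f"candidate references inactive bead {a}")
        topology.add_polymer_bond(a, r, params.bond_r0, params.bond_k)
        deg = topology.polymer_degree()
        for bead in (a, r):
            if deg[bead] == 2:
                partners = [j if i == bead else i
                            for i, j in topology.polymer_bond_idx if bead in (i, j)]
                topology.add_polymer_angle(partners[0], bead, partners[1],
                                           params.backbone_angle_theta0, params.backbone_angle_k)
            ester = _ester_neighbor(topology, bead)
            if ester is not None:
                other = r if bead == a else a
                topology.add_polymer_angle(other, bead, ester,
                                           params.sidechain_angle_theta0, params.sidechain_angle_k)
        topology.active[a] = False
        topology.active[r] = True
        topology.reactive_available[r] = False
        topology.consumed[r] = True
        used_active.add(a)
        used_reactive.add(r)
        formed.append((a, r, dist))
    return formed


def polymerization_run(
    state: SystemState,
    topology: Topology,
    ff: ForceField,
    schedule: PolymerizationSchedule,
    ensemble: EnsembleSpec | None = None,
    params: PolymerBondParams = PolymerBondParams(),
    count_initiators_as_reacted: bool = True,
    minimize_steps: int = 200,
) -> tuple[SystemState, list[AttemptRecord], list[BondEvent]]:
    """Run the full bond/relax/terminate loop.

    Each attempt finds candidates and applies greedy bonding.  After an
    accumulated ``bonds_per_relaxation`` successes the system is energy
    minimized and relaxed by ``relax_steps`` of NPT MD; an empty attempt
    triggers ``retry_steps`` of MD and increments the consecutive-failure
    counter (reset by any success); the run terminates at
    ``max_failed_attempts`` consecutive failures.  Returns the final state,
    the per-attempt trace and the audited bond event log.
    """
    from .analysis import conversion

    ens = ensemble or EnsembleSpec()
    st = state
    records: list[AttemptRecord] = []
    events: list[BondEvent] = []
    failures = 0
    since_relax = 0
    attempt = 0
    while failures < schedule.max_failed_attempts:
        attempt += 1
        if schedule.max_attempts is not None and attempt > schedule.max_attempts:
            break
        cands = find_candidates(st, topology, schedule.bonding_cutoff)
        formed = apply_bonding(st, topology, cands, params)
        n_formed = len(formed)
        conv = conversion(topology, count_initiators_as_reacted)
        for i, j, d in formed:
            events.append(BondEvent(attempt, i, j, d, conv, st.volume))
        records.append(AttemptRecord(attempt, n_formed, conv, st.volume))
        if n_formed > 0:
            failures = 0
            since_relax += n_formed
            # a fresh bond can form near the cutoff, far above its 0.31 nm
            # rest length; a short minimization right away keeps the next MD
            # segment stable (the classic simulated-polymerization recipe
            # minimizes after every topology update)
            st = minimize(st, topology, ff, max_steps=max(minimize_steps // 4, 25))
            if since_relax >= schedule.bonds_per_relaxation:
                st = minimize(st, topology, ff, max_steps=minimize_steps)
                st, _ = run_md(st, topology, ff, ens, schedule.relax_steps,
                               seed=schedule.seed + attempt)
                since_relax = 0
        else:
            failures += 1
            if failures >= schedule.max_failed_attempts:
                break
            st, _ = run_md(st, topology, ff, ens, schedule.retry_steps,
                           seed=schedule.seed + attempt)
    return st, records, events


def write_event_log(path, events: list[BondEvent]):
    """TSV event log: attempt, bead_i, bead_j, distance_nm, conversion, volume."""
    with open(path, "w") as fh:
        fh.write("attempt\tbead_i\tbead_j\tdistance_nm\tconversion_after\tvolume_nm3\n")
        for e in events:
            fh.write(f"{e.attempt}\t{e.bead_i}\t{e.bead_j}\t{e.distance:.6f}\t"
                     f"{e.conversion_after:.6f}\t{e.volume_nm3:.6f}\n")
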