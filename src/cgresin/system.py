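"""System assembly: topology instantiation, box packing, periodic geometry.

A :class:`Topology` is the system-wide instantiation of molecule templates:
static bonded terms are laid down once at packing time and never change,
while polymerization later appends *dynamic* bonds and angles and flips
per-bead reaction labels (``reactive_available`` / ``active`` / ``consumed``).

Boxes are orthorhombic and periodic.  Positions are stored unwrapped
internally (so volumes, shrinkage and diffusion are well defined) and are
wrapped into the primary cell only on file output.

Packing follows the published insertion order: initiator molecules first,
then Bis-GMA, then the remaining TEGDMA, each with a random position and
orientation, rejecting insertions that put any intermolecular bead pair
closer than a hard-core distance (default 0.25 nm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .forcefield import ForceField
from .molecules import (
    Formulation,
    MoleculeTemplate,
    Species,
    bisgma_template,
    tegdma_template,
)

__all__ = [
    "Topology",
    "SystemState",
    "PackingError",
    "GeometryError",
    "pack_box",
    "neighbor_pairs",
    "minimum_image",
    "write_gro",
    "read_gro",
    "write_xyz",
    "read_xyz",
    "write_lammps_data",
]

AMU_TO_G = 1.66053906660e-24
NM3_TO_CM3 = 1.0e-21


class PackingError(RuntimeError):
    pass


class GeometryError(ValueError):
    pass


def minimum_image(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement ``a - b`` in an orthorhombic box.

    Each returned component has magnitude <= box/2.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    box = np.asarray(box, dtype=float)
    d = a - b
    return d - box * np.round(d / box)


@dataclass
class SystemState:
    """Positions/velocities (nm, nm/ps), orthorhombic box (nm) and RNG record."""

    positions: np.ndarray
    velocities: np.ndarray
    box: np.ndarray
    seed: int | None = None

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    def wrapped_positions(self) -> np.ndarray:
        return np.mod(self.positions, self.box)

    def copy(self) -> "SystemState":
        return SystemState(self.positions.copy(), self.velocities.copy(), self.box.copy(), self.seed)


class Topology:
    """Beads, static bonded terms and dynamically grown polymer terms."""

    def __init__(self):
        self.species: list[Species] = []  # per molecule
        self.mol_start: list[int] = []  # first bead index per molecule
        self.mol_id = np.zeros(0, dtype=int)
        self.type_codes: list[str] = []
        self.mapping_labels = np.zeros(0, dtype=int)
        self.heavy_atoms = np.zeros(0, dtype=int)
        # static terms (index arrays + parameter arrays)
        self.bond_idx = np.zeros((0, 2), dtype=int)
        self.bond_r0 = np.zeros(0)
        self.bond_k = np.zeros(0)
        self.constraint_idx = np.zeros((0, 2), dtype=int)
        self.constraint_d0 = np.zeros(0)
        self.angle_idx = np.zeros((0, 3), dtype=int)
        self.angle_theta0 = np.zeros(0)
        self.angle_k = np.zeros(0)
        self.dihedral_idx = np.zeros((0, 4), dtype=int)
        self.dihedral_phi0 = np.zeros(0)
        self.dihedral_k = np.zeros(0)
        self.dihedral_n = np.zeros(0, dtype=int)
        self.dihedral_improper = np.zeros(0, dtype=bool)
        # dynamic polymer terms
        self.polymer_bond_idx: list[tuple[int, int]] = []
        self.polymer_bond_r0: list[float] = []
        self.polymer_bond_k: list[float] = []
        self.polymer_angle_idx: list[tuple[int, int, int]] = []
        self.polymer_angle_theta0: list[float] = []
        self.polymer_angle_k: list[float] = []
        # reaction labels
        self.reactive_available = np.zeros(0, dtype=bool)
        self.active = np.zeros(0, dtype=bool)
        self.consumed = np.zeros(0, dtype=bool)
        self._exclusion_cache: np.ndarray | None = None
        self._static_frozen = False

    # -- construction ------------------------------------------------------

    def add_molecule(self, template: MoleculeTemplate) -> int:
        """Instantiate a template; returns the new molecule id."""
        if self._static_frozen:
            raise RuntimeError("static topology is frozen after packing")
        off = len(self.type_codes)
        mol = len(self.species)
        self.species.append(template.species)
        self.mol_start.append(off)
        n = template.n_beads
        self.mol_id = np.concatenate([self.mol_id, np.full(n, mol, dtype=int)])
        self.type_codes.extend(spec.type_code for _, spec, _ in template.beads)
        self.mapping_labels = np.concatenate(
            [self.mapping_labels, np.array(template.mapping_labels, dtype=int)])
        self.heavy_atoms = np.concatenate(
            [self.heavy_atoms, np.array([spec.heavy_atoms for _, spec, _ in template.beads], dtype=int)])
        hb = template.harmonic_bonds()
        self.bond_idx = np.vstack([self.bond_idx, [[b.bead_indices[0] + off, b.bead_indices[1] + off] for b in hb]]) if hb else self.bond_idx
        self.bond_r0 = np.concatenate([self.bond_r0, [b.r0 for b in hb]])
        self.bond_k = np.concatenate([self.bond_k, [b.k for b in hb]])
        cons_idx, cons_d0 = [], []
        for b in template.constrained_bonds():
            cons_idx.append([b.bead_indices[0] + off, b.bead_indices[1] + off])
            cons_d0.append(b.r0)
        # angle constraints become the equivalent third-distance constraint
        cb = {tuple(sorted(b.bead_indices)): b.r0 for b in template.constrained_bonds()}
        for a in template.constrained_angles():
            i, j, k = a.bead_indices
            dij = cb.get(tuple(sorted((i, j))))
            djk = cb.get(tuple(sorted((j, k))))
            if dij is None or djk is None:
                raise ValueError("constrained angle must sit between two constrained bonds")
            th = math.radians(a.theta0)
            dik = math.sqrt(dij**2 + djk**2 - 2 * dij * djk * math.cos(th))
            cons_idx.append([i + off, k + off])
            cons_d0.append(dik)
        if cons_idx:
            self.constraint_idx = np.vstack([self.constraint_idx, cons_idx])
            self.constraint_d0 = np.concatenate([self.constraint_d0, cons_d0])
        ha = template.harmonic_angles()
        if ha:
            self.angle_idx = np.vstack([self.angle_idx, [[i + off for i in a.bead_indices] for a in ha]])
            self.angle_theta0 = np.concatenate([self.angle_theta0, [a.theta0 for a in ha]])
            self.angle_k = np.concatenate([self.angle_k, [a.k for a in ha]])
        dh = template.dihedrals
        if dh:
            self.dihedral_idx = np.vstack([self.dihedral_idx, [[i + off for i in d.bead_indices] for d in dh]])
            self.dihedral_phi0 = np.concatenate([self.dihedral_phi0, [d.phi0 for d in dh]])
            self.dihedral_k = np.concatenate([self.dihedral_k, [d.k for d in dh]])
            self.dihedral_n = np.concatenate([self.dihedral_n, np.array([d.n for d in dh], dtype=int)])
            self.dihedral_improper = np.concatenate(
                [self.dihedral_improper, np.array([d.improper for d in dh], dtype=bool)])
        reactive = np.zeros(n, dtype=bool)
        reactive[template.reactive_bead_locals] = True
        self.reactive_available = np.concatenate([self.reactive_available, reactive])
        self.active = np.concatenate([self.active, np.zeros(n, dtype=bool)])
        self.consumed = np.concatenate([self.consumed, np.zeros(n, dtype=bool)])
        self._exclusion_cache = None
        return mol

    def freeze_static(self):
        self._static_frozen = True

    # -- queries -----------------------------------------------------------

    @property
    def n_beads(self) -> int:
        return len(self.type_codes)

    @property
    def n_molecules(self) -> int:
        return len(self.species)

    def masses(self, ff: ForceField) -> np.ndarray:
        return np.array([ff.masses[t] for t in self.type_codes])

    def real_masses(self) -> np.ndarray:
        """Per-bead masses distributing each species' real molar mass evenly
        over its beads (used for density with real molecular weights)."""
        from .molecules import MW_BISGMA, MW_TEGDMA
        out = np.zeros(self.n_beads)
        for mol, (sp, start) in enumerate(zip(self.species, self.mol_start)):
            n = 15 if sp == Species.BISGMA else 6
            mw = MW_BISGMA if sp == Species.BISGMA else MW_TEGDMA
            out[start:start + n] = mw / n
        return out

    def all_bond_pairs(self) -> np.ndarray:
        """Static harmonic bonds + constraints + dynamic polymer bonds, (n, 2)."""
        parts = [self.bond_idx, self.constraint_idx]
        if self.polymer_bond_idx:
            parts.append(np.array(self.polymer_bond_idx, dtype=int))
        return np.vstack([p for p in parts if len(p)]) if any(len(p) for p in parts) else np.zeros((0, 2), dtype=int)

    def bonded_adjacency(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {i: set() for i in range(self.n_beads)}
        for i, j in self.all_bond_pairs():
            adj[int(i)].add(int(j))
            adj[int(j)].add(int(i))
        return adj

    def has_bond(self, i: int, j: int) -> bool:
        key = (min(i, j), max(i, j))
        for a, b in self.all_bond_pairs():
            if (min(a, b), max(a, b)) == key:
                return True
        return False

    def exclusion_keys(self) -> np.ndarray:
        """Sorted encoded keys (i*N + j, i<j) of 1-2 and 1-3 bonded pairs."""
        if self._exclusion_cache is None:
            n = self.n_beads
            adj = self.bonded_adjacency()
            excl: set[int] = set()
            for i in range(n):
                for j in adj[i]:
                    a, b = (i, j) if i < j else (j, i)
                    excl.add(a * n + b)
                    for k in adj[j]:
                        if k != i:
                            a, b = (i, k) if i < k else (k, i)
                            if a != b:
                                excl.add(a * n + b)
            self._exclusion_cache = np.array(sorted(excl), dtype=np.int64)
        return self._exclusion_cache

    def polymer_degree(self) -> np.ndarray:
        deg = np.zeros(self.n_beads, dtype=int)
        for i, j in self.polymer_bond_idx:
            deg[i] += 1
            deg[j] += 1
        return deg

    # -- dynamic growth ----------------------------------------------------

    def add_polymer_bond(self, i: int, j: int, r0: float, k: float):
        if any({i, j} == {a, b} for a, b in self.polymer_bond_idx) or self.has_bond(i, j):
            raise ValueError(f"duplicate bond ({i}, {j})")
        self.polymer_bond_idx.append((i, j))
        self.polymer_bond_r0.append(r0)
        self.polymer_bond_k.append(k)
        self._exclusion_cache = None

    def add_polymer_angle(self, i: int, j: int, k: int, theta0: float, kf: float):
        self.polymer_angle_idx.append((i, j, k))
        self.polymer_angle_theta0.append(theta0)
        self.polymer_angle_k.append(kf)
        self._exclusion_cache = None


# ---------------------------------------------------------------------------
# packing
# ---------------------------------------------------------------------------

def pack_box(
    formulation: Formulation,
    n_active: int,
    target_density_guess: float = 0.9,
    seed: int = 0,
    min_dist: float = 0.25,
    max_tries: int = 2000,
    box_scale: float = 1.0,
) -> tuple[Topology, SystemState]:
    """Randomly pack a formulation into a cubic periodic box.

    Insertion order: initiator molecules (one methacrylate bead flagged
    active each) first, then Bis-GMA, then the remaining TEGDMA.  Initiators
    are drawn from the TEGDMA allotment when available, else from Bis-GMA.
    An insertion is rejected when any intermolecular bead distance falls
    below ``min_dist``; after ``max_tries`` rejections a
    :class:`PackingError` suggests a larger box.
    """
    n_teg, n_bis = formulation.n_tegdma, formulation.n_bisgma
    if n_active > n_teg + n_bis:
        raise ValueError("more initiators requested than reactive molecules")
    rng = np.random.default_rng(seed)
    total_mass = formulation.total_mass_amu
    if total_mass <= 0:
        raise ValueError("empty formulation")
    vol_nm3 = total_mass * AMU_TO_G / target_density_guess / NM3_TO_CM3 * box_scale**3
    length = vol_nm3 ** (1.0 / 3.0)
    box = np.full(3, length)

    teg, bis = tegdma_template(), bisgma_template()
    n_active_teg = min(n_active, n_teg)
    n_active_bis = n_active - n_active_teg
    # insertion order per the published packing recipe
    order: list[tuple[MoleculeTemplate, bool]] = (
        [(teg, True)] * n_active_teg
        + [(bis, True)] * n_active_bis
        + [(bis, False)] * (n_bis - n_active_bis)
        + [(teg, False)] * (n_teg - n_active_teg)
    )

    topo = Topology()
    placed: list[np.ndarray] = []
    tree: cKDTree | None = None
    for template, is_initiator in order:
        ref = template.reference_coords - template.reference_coords.mean(axis=0)
        ok = False
        for _ in range(max_tries):
            rot = Rotation.random(random_state=rng).as_matrix()
            shift = rng.random(3) * box
            coords = ref @ rot.T + shift
            if tree is not None:
                d, _ = tree.query(np.mod(coords, box), k=1)
                if np.min(d) < min_dist:
                    continue
            ok = True
            break
        if not ok:
            raise PackingError(
                "could not insert molecule without overlap; "
                "lower target_density_guess or raise box_scale"
            )
        mol = topo.add_molecule(template)
        if is_initiator:
            start = topo.mol_start[mol]
            local = template.reactive_bead_locals[int(rng.integers(len(template.reactive_bead_locals)))]
            topo.active[start + local] = True
            topo.reactive_available[start + local] = False
        placed.append(coords)
        tree = cKDTree(np.mod(np.vstack(placed), box), boxsize=box)
    topo.freeze_static()
    positions = np.vstack(placed) if placed else np.zeros((0, 3))
    state = SystemState(
        positions=positions,
        velocities=np.zeros_like(positions),
        box=box,
        seed=seed,
    )
    return topo, state


# ---------------------------------------------------------------------------
# neighbor search
# ---------------------------------------------------------------------------

def neighbor_pairs(
    state: SystemState,
    topology: Topology,
    cutoff: float,
    skin: float = 0.2,
) -> np.ndarray:
    """Unordered nonbonded pairs within ``cutoff + skin`` (minimum image).

    Pairs connected by a bond or sharing an angle path (first and second
    bonded neighbors) are excluded.  Raises :class:`GeometryError` when any
    box dimension is below twice the search radius (the minimum-image
    convention would otherwise miss periodic copies).
    """
    r = cutoff + skin
    if np.any(state.box < 2.0 * r):
        raise GeometryError(
            f"box {state.box} too small for search radius {r} (need >= {2*r} per dimension)"
        )
    pos = np.mod(state.positions, state.box)
    # guard against positions exactly at the upper box edge after fmod
    pos = np.where(pos >= state.box, 0.0, pos)
    tree = cKDTree(pos, boxsize=state.box)
    pairs = tree.query_pairs(r, output_type="ndarray")
    if len(pairs) == 0:
        return np.zeros((0, 2), dtype=int)
    pairs = np.sort(pairs, axis=1)
    n = topology.n_beads
    keys = pairs[:, 0].astype(np.int64) * n + pairs[:, 1]
    excl = topology.exclusion_keys()
    keep = ~np.isin(keys, excl)
    pairs = pairs[keep]
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return pairs[order]


# ---------------------------------------------------------------------------
# coordinate file formats
# ---------------------------------------------------------------------------

def write_gro(path, topology: Topology, state: SystemState, title: str = "cgresin"):
    """Fixed-width GRO file (nm, positions wrapped into the primary cell)."""
    pos = state.wrapped_positions()
    with open(path, "w") as fh:
        fh.write(f"{title}\n{state.n_beads:5d}\n")
        for i in range(state.n_beads):
            mol = topology.mol_id[i] if topology.n_beads else 0
            resname = topology.species[mol].value[:5] if topology.n_beads else "MOL"
            name = topology.type_codes[i] if topology.n_beads else "X"
            fh.write(
                f"{(mol % 99999) + 1:5d}{resname:<5s}{name:>5s}{(i % 99999) + 1:5d}"
                f"{pos[i,0]:8.3f}{pos[i,1]:8.3f}{pos[i,2]:8.3f}\n"
            )
        fh.write(f"{state.box[0]:10.5f}{state.box[1]:10.5f}{state.box[2]:10.5f}\n")


def read_gro(path):
    """Read a GRO file -> (names, positions nm, box nm)."""
    lines = open(path).read().splitlines()
    n = int(lines[1])
    names, pos = [], np.zeros((n, 3))
    for i in range(n):
        line = lines[2 + i]
        names.append(line[10:15].strip())
        pos[i] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
    box = np.array([float(x) for x in lines[2 + n].split()[:3]])
    return names, pos, box


def write_xyz(path, topology: Topology, state: SystemState, comment: str = "", append: bool = False):
    """XYZ file in Angstrom (wrapped positions); supports multi-frame append."""
    pos = state.wrapped_positions() * 10.0
    with open(path, "a" if append else "w") as fh:
        fh.write(f"{state.n_beads}\n{comment}\n")
        for i in range(state.n_beads):
            name = topology.type_codes[i] if topology.n_beads else "X"
            fh.write(f"{name:<6s}{pos[i,0]:14.6f}{pos[i,1]:14.6f}{pos[i,2]:14.6f}\n")


def read_xyz(path):
    """Read all frames of an XYZ file -> list of (names, positions nm)."""
    lines = open(path).read().splitlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            break
        n = int(lines[i])
        names, pos = [], np.zeros((n, 3))
        for j in range(n):
            f = lines[i + 2 + j].split()
            names.append(f[0])
            pos[j] = [float(f[1]), float(f[2]), float(f[3])]
        frames.append((names, pos / 10.0))
        i += 2 + n
    return frames


def write_lammps_data(path, topology: Topology, state: SystemState, ff: ForceField):
    """LAMMPS data file (atom_style full) of the current topology and box.

    Constrained bonds are exported as their own bond types (zero-k harmonic
    placeholders) so the network is complete in the file; dynamic polymer
    bonds/angles are included.
    """
    types = sorted(set(topology.type_codes))
    t_index = {t: i + 1 for i, t in enumerate(types)}
    bonds = []
    for (i, j), r0, k in zip(topology.bond_idx, topology.bond_r0, topology.bond_k):
        bonds.append((int(i), int(j), r0, k))
    for (i, j), d0 in zip(topology.constraint_idx, topology.constraint_d0):
        bonds.append((int(i), int(j), d0, 0.0))
    for (i, j), r0, k in zip(topology.polymer_bond_idx, topology.polymer_bond_r0, topology.polymer_bond_k):
        bonds.append((i, j, r0, k))
    bond_types = sorted({(r0, k) for _, _, r0, k in bonds})
    bt_index = {p: i + 1 for i, p in enumerate(bond_types)}
    angles = [(int(i), int(j), int(k), t0, kf) for (i, j, k), t0, kf in
              zip(topology.angle_idx, topology.angle_theta0, topology.angle_k)]
    angles += [(i, j, k, t0, kf) for (i, j, k), t0, kf in
               zip(topology.polymer_angle_idx, topology.polymer_angle_theta0, topology.polymer_angle_k)]
    angle_types = sorted({(t0, kf) for *_, t0, kf in angles})
    at_index = {p: i + 1 for i, p in enumerate(angle_types)}
    prop = topology.dihedral_idx[~topology.dihedral_improper]
    prop_p = list(zip(topology.dihedral_phi0[~topology.dihedral_improper],
                      topology.dihedral_k[~topology.dihedral_improper],
                      topology.dihedral_n[~topology.dihedral_improper]))
    impr = topology.dihedral_idx[topology.dihedral_improper]
    impr_p = list(zip(topology.dihedral_phi0[topology.dihedral_improper],
                      topology.dihedral_k[topology.dihedral_improper],
                      topology.dihedral_n[topology.dihedral_improper]))
    dtypes = sorted(set(prop_p))
    dt_index = {p: i + 1 for i, p in enumerate(dtypes)}
    itypes = sorted(set(impr_p))
    it_index = {p: i + 1 for i, p in enumerate(itypes)}
    pos = state.wrapped_positions() * 10.0  # Angstrom
    box_a = state.box * 10.0
    with open(path, "w") as fh:
        fh.write("LAMMPS data file generated by cgresin\n\n")
        fh.write(f"{topology.n_beads} atoms\n{len(bonds)} bonds\n{len(angles)} angles\n")
        fh.write(f"{len(prop)} dihedrals\n{len(impr)} impropers\n\n")
        fh.write(f"{len(types)} atom types\n{len(bond_types)} bond types\n")
        fh.write(f"{len(angle_types)} angle types\n{len(dtypes)} dihedral types\n{len(itypes)} improper types\n\n")
        fh.write(f"0.0 {box_a[0]:.6f} xlo xhi\n0.0 {box_a[1]:.6f} ylo yhi\n0.0 {box_a[2]:.6f} zlo zhi\n\n")
        fh.write("Masses\n\n")
        for t in types:
            fh.write(f"{t_index[t]} {ff.masses[t]:.4f}  # {t}\n")
        fh.write("\nAtoms  # full\n\n")
        for i in range(topology.n_beads):
            fh.write(f"{i+1} {topology.mol_id[i]+1} {t_index[topology.type_codes[i]]} 0.0 "
                     f"{pos[i,0]:.6f} {pos[i,1]:.6f} {pos[i,2]:.6f}\n")
        if bonds:
            fh.write("\nBonds\n\n")
            for bi, (i, j, r0, k) in enumerate(bonds, 1):
                fh.write(f"{bi} {bt_index[(r0, k)]} {i+1} {j+1}\n")
        if angles:
            fh.write("\nAngles\n\n")
            for ai, (i, j, k, t0, kf) in enumerate(angles, 1):
                fh.write(f"{ai} {at_index[(t0, kf)]} {i+1} {j+1} {k+1}\n")
        if len(prop):
            fh.write("\nDihedrals\n\n")
            for di, (q, p) in enumerate(zip(prop, prop_p), 1):
                fh.write(f"{di} {dt_index[p]} {q[0]+1} {q[1]+1} {q[2]+1} {q[3]+1}\n")
        if len(impr):
            fh.write("\nImpropers\n\n")
            for di, (q, p) in enumerate(zip(impr, impr_p), 1):
                fh.write(f"{di} {it_index[p]} {q[0]+1} {q[1]+1} {q[2]+1} {q[3]+1}\n")
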