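"""Coarse-grain monomer templates and formulation arithmetic.

Two species are modelled, both bifunctional methacrylates:

* **TEGDMA** (triethylene glycol dimethacrylate, 286.32 g/mol) — a linear
  6-bead chain with mapping labels 1-2-7-7-2-1: two methacrylate beads
  (label 1, SC4), two ester beads (label 2, N4a) and two glycol-ether beads
  (label 7, SN3a).  20 heavy atoms.

* **Bis-GMA** (bisphenol A-glycidyl methacrylate, 512.59 g/mol) — 15 beads:
  two symmetric methacrylate arms with labels 1-2-3-4 (SC4, N4a, TP1, TN2a),
  two aromatic rings of three TC5 beads each (label 5) and a central
  isopropylidene bridge bead (label 6, SC2).  37 heavy atoms.

Each aromatic ring is a rigid three-bead triangle held by two constrained
bonds (0.229 nm on the edge adjacent to the arm's label-4 bead, 0.197 nm on
the other) plus one constrained angle; two periodic dihedrals per ring
reproduce the bimodal ring-rotation statistics, and two improper dihedrals
keep ring substituents planar.

The reactive beads (one per chain end, label 1) carry the polymerizable
C=C group; polymerization bonds are formed between them at run time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .forcefield import AngleTerm, BeadSpec, BondTerm, DihedralTerm, bead_spec

__all__ = [
    "Species",
    "MoleculeTemplate",
    "Formulation",
    "MW_BISGMA",
    "MW_TEGDMA",
    "LABEL_TYPES",
    "tegdma_template",
    "bisgma_template",
    "formulation_counts",
    "make_formulation",
    "FORMULATION_TABLE_WEIGHT_FRACTIONS",
]

MW_BISGMA = 512.59  # g/mol
MW_TEGDMA = 286.32  # g/mol

#: Martini 3 bead type per mapping label (Table-driven: label -> type code)
LABEL_TYPES = {1: "SC4", 2: "N4a", 3: "TP1", 4: "TN2a", 5: "TC5", 6: "SC2", 7: "SN3a"}

# harmonic bond table, keyed by unordered mapping-label pair: (r0 nm, k kJ/mol/nm^2)
BOND_TABLE = {
    (1, 2): (0.355, 35000.0),
    (2, 3): (0.230, 5000.0),
    (3, 4): (0.240, 28000.0),
    (4, 5): (0.300, 15000.0),
    (5, 6): (0.271, 35000.0),
    (2, 7): (0.345, 6000.0),
    (7, 7): (0.370, 9000.0),
}
#: constrained ring-edge lengths (nm): long edge adjacent to the label-4 bead
RING_BOND_LONG = 0.229
RING_BOND_SHORT = 0.197
#: constrained ring angle (deg) at the middle ring bead; the value is a
#: package convention (only the fact of the constraint is prescribed) chosen
#: to give a near-equilateral triangle
RING_ANGLE_CONSTRAINT = 60.0

# harmonic angle table, keyed by mapping-label triple: (theta0 deg, k kJ/mol/rad^2)
ANGLE_TABLE = {
    (1, 2, 3): (108.0, 110.0),
    (2, 3, 4): (76.0, 120.0),
    (3, 4, 5): (130.0, 40.0),
    (4, 5, 5): (120.0, 80.0),
    (5, 5, 6): (140.0, 130.0),
    (5, 6, 5): (70.0, 700.0),
    (1, 2, 7): (115.0, 100.0),
    (2, 7, 7): (124.0, 100.0),
}

# proper dihedral table: label quadruple -> (phi0 deg, k kJ/mol, multiplicity)
DIHEDRAL_TABLE = {
    (1, 2, 3, 4): (0.0, 35.0, 1),
    (3, 4, 5, 5): (313.0, 8.46, 2),  # ring rotation (tabulated against a mislabelled quadruple upstream)
    (1, 2, 7, 7): (0.0, 2.0, 3),
    (2, 7, 7, 2): (0.0, 2.0, 3),
}
# improper dihedral table (ring planarity)
IMPROPER_TABLE = {
    (4, 5, 5, 5): (0.0, 65.0, 1),
    (5, 5, 5, 6): (180.0, 100.0, 1),
}


class Species(str, Enum):
    BISGMA = "BISGMA"
    TEGDMA = "TEGDMA"


@dataclass
class MoleculeTemplate:
    """Per-species bead list, bonded-term lists and reference geometry."""

    species: Species
    beads: list[tuple[int, BeadSpec, int]]  # (local index, spec, mapping label)
    bonds: list[BondTerm]  # includes constrained ring edges
    angles: list[AngleTerm]  # includes the constrained ring angle
    dihedrals: list[DihedralTerm]  # propers + impropers (flagged)
    reactive_bead_locals: list[int]
    reference_coords: np.ndarray = field(repr=False)  # (n_beads, 3) nm

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def heavy_atoms(self) -> int:
        return sum(spec.heavy_atoms for _, spec, _ in self.beads)

    @property
    def mapping_labels(self) -> list[int]:
        return [lab for _, _, lab in self.beads]

    def harmonic_bonds(self) -> list[BondTerm]:
        return [b for b in self.bonds if not b.constrained]

    def constrained_bonds(self) -> list[BondTerm]:
        return [b for b in self.bonds if b.constrained]

    def harmonic_angles(self) -> list[AngleTerm]:
        return [a for a in self.angles if not a.constrained]

    def constrained_angles(self) -> list[AngleTerm]:
        return [a for a in self.angles if a.constrained]

    def propers(self) -> list[DihedralTerm]:
        return [d for d in self.dihedrals if not d.improper]

    def impropers(self) -> list[DihedralTerm]:
        return [d for d in self.dihedrals if d.improper]

    def bond_graph_edges(self) -> set[tuple[int, int]]:
        """All bonded edges, counting constrained ring edges and the implicit
        third triangle edge closed by each constrained angle."""
        edges = {tuple(sorted(b.bead_indices)) for b in self.bonds}
        for a in self.constrained_angles():
            i, _, k = a.bead_indices
            edges.add(tuple(sorted((i, k))))
        return edges

    def to_itp_block(self, name: str | None = None) -> str:
        """GROMACS-itp-style text block (moleculetype, atoms, bonds, ...)."""
        name = name or self.species.value
        out = [f"[ moleculetype ]\n; name  nrexcl\n{name}  2\n", "[ atoms ]\n;  nr type resnr residue atom cgnr charge mass\n"]
        for i, spec, lab in self.beads:
            out.append(f"{i+1:5d} {spec.type_code:>5s} 1 {name[:4]:>5s} B{lab:<3d} {i+1:4d} 0.0 {spec.mass:8.3f}\n")
        out.append("[ bonds ]\n")
        for b in self.harmonic_bonds():
            i, j = b.bead_indices
            out.append(f"{i+1:5d} {j+1:5d} 1 {b.r0:8.4f} {b.k:10.1f}\n")
        out.append("[ constraints ]\n")
        for b in self.constrained_bonds():
            i, j = b.bead_indices
            out.append(f"{i+1:5d} {j+1:5d} 1 {b.r0:8.4f}\n")
        out.append("[ angles ]\n")
        for a in self.harmonic_angles():
            i, j, k = a.bead_indices
            out.append(f"{i+1:5d} {j+1:5d} {k+1:5d} 1 {a.theta0:8.2f} {a.k:10.1f}\n")
        for a in self.constrained_angles():
            i, j, k = a.bead_indices
            out.append(f"; constrained angle {i+1}-{j+1}-{k+1} at {a.theta0:.2f} deg\n")
        out.append("[ dihedrals ]\n")
        for d in self.propers():
            i, j, k, l = d.bead_indices
            out.append(f"{i+1:5d} {j+1:5d} {k+1:5d} {l+1:5d} 1 {d.phi0:8.2f} {d.k:8.3f} {d.n:3d}\n")
        for d in self.impropers():
            i, j, k, l = d.bead_indices
            out.append(f"{i+1:5d} {j+1:5d} {k+1:5d} {l+1:5d} 4 {d.phi0:8.2f} {d.k:8.3f} {d.n:3d}\n")
        return "".join(out)


# ---------------------------------------------------------------------------
# reference geometry: sequential internal-coordinate (z-matrix) placement
# ---------------------------------------------------------------------------

def _place_zmatrix(entries) -> np.ndarray:
    """NeRF-style placement.  Each entry after the third is
    ``(i_bond, i_angle, i_dihedral, r, theta_deg, phi_deg)``."""
    n = len(entries)
    xyz = np.zeros((n, 3))
    for idx, e in enumerate(entries):
        if idx == 0:
            continue
        if idx == 1:
            xyz[1] = [e[3], 0.0, 0.0]
            continue
        ib, ia, idh, r, theta, phi = e
        if idx == 2:
            th = math.radians(theta)
            b = xyz[ib]
            a = xyz[ia]
            u = (a - b) / np.linalg.norm(a - b)
            # place in xy-plane
            perp = np.array([-u[1], u[0], 0.0])
            if np.linalg.norm(perp) < 1e-12:
                perp = np.array([0.0, 1.0, 0.0])
            perp /= np.linalg.norm(perp)
            xyz[2] = b + r * (math.cos(th) * u + math.sin(th) * perp)
            continue
        b, a, d = xyz[ib], xyz[ia], xyz[idh]
        th, ph = math.radians(theta), math.radians(phi)
        bc = b - a
        bc /= np.linalg.norm(bc)
        ab = a - d
        nvec = np.cross(ab, bc)
        nn = np.linalg.norm(nvec)
        if nn < 1e-12:
            nvec = np.array([0.0, 0.0, 1.0])
            nn = 1.0
        nvec /= nn
        m = np.cross(nvec, bc)
        d2 = np.array([
            -r * math.cos(th),
            r * math.sin(th) * math.cos(ph),
            r * math.sin(th) * math.sin(ph),
        ])
        xyz[idx] = b + d2[0] * bc + d2[1] * m + d2[2] * nvec
    return xyz


def _bond(i, j, lab_i, lab_j) -> BondTerm:
    key = tuple(sorted((lab_i, lab_j)))
    r0, k = BOND_TABLE[key]
    return BondTerm(bead_indices=(i, j), r0=r0, k=k)


def _angle(i, j, k, labs) -> AngleTerm:
    key = labs if labs in ANGLE_TABLE else labs[::-1]
    th, kf = ANGLE_TABLE[key]
    return AngleTerm(bead_indices=(i, j, k), theta0=th, k=kf)


def tegdma_template() -> MoleculeTemplate:
    """The 6-bead TEGDMA template (labels 1-2-7-7-2-1)."""
    labels = [1, 2, 7, 7, 2, 1]
    beads = [(i, bead_spec(LABEL_TYPES[lab]), lab) for i, lab in enumerate(labels)]
    bonds = [_bond(i, i + 1, labels[i], labels[i + 1]) for i in range(5)]
    angles = [_angle(i, i + 1, i + 2, tuple(labels[i:i + 3])) for i in range(4)]
    dihedrals = []
    for i in range(3):
        labq = tuple(labels[i:i + 4])
        key = labq if labq in DIHEDRAL_TABLE else labq[::-1]
        phi0, k, n = DIHEDRAL_TABLE[key]
        dihedrals.append(DihedralTerm(bead_indices=(i, i + 1, i + 2, i + 3), phi0=phi0, k=k, n=n))
    rs = [b.r0 for b in bonds]
    ths = [a.theta0 for a in angles]
    z = [(None,) * 6, (0, None, None, rs[0], None, None)]
    z.append((1, 0, None, rs[1], ths[0], None))
    for i in range(3, 6):
        z.append((i - 1, i - 2, i - 3, rs[i - 1], ths[i - 2], 180.0))
    coords = _place_zmatrix(z)
    return MoleculeTemplate(
        species=Species.TEGDMA, beads=beads, bonds=bonds, angles=angles,
        dihedrals=dihedrals, reactive_bead_locals=[0, 5], reference_coords=coords,
    )


def bisgma_template() -> MoleculeTemplate:
    """The 15-bead Bis-GMA template.

    Canonical bead order (symmetric under the arm swap ``i <-> 14 - i``):

    ==  =====  ==============================
    0   SC4    arm A methacrylate (label 1)
    1   N4a    arm A ester (label 2)
    2   TP1    arm A hydroxyl (label 3)
    3   TN2a   arm A ether-aromatic (label 4)
    4-6 TC5    ring A (4 bonded to bead 3's arm, 6 to the bridge)
    7   SC2    isopropylidene bridge (label 6)
    8-10 TC5   ring B (8 bonded to the bridge, 10 to arm B)
    11  TN2a   arm B ether-aromatic (label 4)
    12  TP1    arm B hydroxyl (label 3)
    13  N4a    arm B ester (label 2)
    14  SC4    arm B methacrylate (label 1)
    ==  =====  ==============================
    """
    labels = [1, 2, 3, 4, 5, 5, 5, 6, 5, 5, 5, 4, 3, 2, 1]
    beads = [(i, bead_spec(LABEL_TYPES[lab]), lab) for i, lab in enumerate(labels)]

    bonds = [
        _bond(0, 1, 1, 2), _bond(1, 2, 2, 3), _bond(2, 3, 3, 4), _bond(3, 4, 4, 5),
        BondTerm(bead_indices=(4, 5), r0=RING_BOND_LONG, constrained=True),
        BondTerm(bead_indices=(5, 6), r0=RING_BOND_SHORT, constrained=True),
        _bond(6, 7, 5, 6),
        _bond(7, 8, 5, 6),
        BondTerm(bead_indices=(8, 9), r0=RING_BOND_SHORT, constrained=True),
        BondTerm(bead_indices=(9, 10), r0=RING_BOND_LONG, constrained=True),
        _bond(10, 11, 4, 5),
        _bond(11, 12, 3, 4), _bond(12, 13, 2, 3), _bond(13, 14, 1, 2),
    ]
    angles = [
        _angle(0, 1, 2, (1, 2, 3)), _angle(1, 2, 3, (2, 3, 4)), _angle(2, 3, 4, (3, 4, 5)),
        _angle(3, 4, 5, (4, 5, 5)),
        AngleTerm(bead_indices=(4, 5, 6), theta0=RING_ANGLE_CONSTRAINT, constrained=True),
        _angle(5, 6, 7, (5, 5, 6)),
        _angle(6, 7, 8, (5, 6, 5)),
        _angle(7, 8, 9, (5, 5, 6)[::-1] if (6, 5, 5) in ANGLE_TABLE else (5, 5, 6)),
        AngleTerm(bead_indices=(8, 9, 10), theta0=RING_ANGLE_CONSTRAINT, constrained=True),
        _angle(9, 10, 11, (5, 5, 4) if (5, 5, 4) in ANGLE_TABLE else (4, 5, 5)),
        _angle(10, 11, 12, (3, 4, 5)), _angle(11, 12, 13, (2, 3, 4)), _angle(12, 13, 14, (1, 2, 3)),
    ]
    ring_phi0, ring_k, ring_n = DIHEDRAL_TABLE[(3, 4, 5, 5)]
    arm_phi0, arm_k, arm_n = DIHEDRAL_TABLE[(1, 2, 3, 4)]
    dihedrals = [
        DihedralTerm(bead_indices=(0, 1, 2, 3), phi0=arm_phi0, k=arm_k, n=arm_n),
        DihedralTerm(bead_indices=(14, 13, 12, 11), phi0=arm_phi0, k=arm_k, n=arm_n),
        # ring rotation: two dihedrals per ring, one across the arm-side bond
        # (label path 3-4-5-5) and one across the bridge-side bond (5-6-5-5);
        # placing both on the arm side would put the second quadruple at a
        # permanently near-collinear geometry where the torsion is singular
        DihedralTerm(bead_indices=(2, 3, 4, 5), phi0=ring_phi0, k=ring_k, n=ring_n),
        DihedralTerm(bead_indices=(8, 7, 6, 5), phi0=ring_phi0, k=ring_k, n=ring_n),
        DihedralTerm(bead_indices=(12, 11, 10, 9), phi0=ring_phi0, k=ring_k, n=ring_n),
        DihedralTerm(bead_indices=(6, 7, 8, 9), phi0=ring_phi0, k=ring_k, n=ring_n),
        # impropers: ring planarity, two per ring
        DihedralTerm(bead_indices=(3, 4, 5, 6), phi0=IMPROPER_TABLE[(4, 5, 5, 5)][0],
                     k=IMPROPER_TABLE[(4, 5, 5, 5)][1], n=1, improper=True),
        DihedralTerm(bead_indices=(4, 5, 6, 7), phi0=IMPROPER_TABLE[(5, 5, 5, 6)][0],
                     k=IMPROPER_TABLE[(5, 5, 5, 6)][1], n=1, improper=True),
        DihedralTerm(bead_indices=(11, 10, 9, 8), phi0=IMPROPER_TABLE[(4, 5, 5, 5)][0],
                     k=IMPROPER_TABLE[(4, 5, 5, 5)][1], n=1, improper=True),
        DihedralTerm(bead_indices=(10, 9, 8, 7), phi0=IMPROPER_TABLE[(5, 5, 5, 6)][0],
                     k=IMPROPER_TABLE[(5, 5, 5, 6)][1], n=1, improper=True),
    ]
    # reference geometry via sequential placement along the backbone path;
    # dihedral values are chosen so every improper starts at its minimum
    # (ring substituents coplanar with their ring) and the ring-rotation
    # torsions near theirs (2*phi = phi0 - 180 -> phi ~ 66.5 deg)
    z = [
        (None,) * 6,
        (0, None, None, 0.355, None, None),
        (1, 0, None, 0.230, 108.0, None),
        (2, 1, 0, 0.240, 76.0, 180.0),
        (3, 2, 1, 0.300, 130.0, 180.0),
        (4, 3, 2, RING_BOND_LONG, 120.0, 66.5),
        (5, 4, 3, RING_BOND_SHORT, RING_ANGLE_CONSTRAINT, 180.0),
        (6, 5, 4, 0.271, 140.0, 0.0),
        (7, 6, 5, 0.271, 70.0, 90.0),
        (8, 7, 6, RING_BOND_SHORT, 140.0, 180.0),
        (9, 8, 7, RING_BOND_LONG, RING_ANGLE_CONSTRAINT, 0.0),
        (10, 9, 8, 0.300, 120.0, 180.0),
        (11, 10, 9, 0.240, 130.0, 66.5),
        (12, 11, 10, 0.230, 76.0, 180.0),
        (13, 12, 11, 0.355, 108.0, 180.0),
    ]
    coords = _place_zmatrix(z)
    return MoleculeTemplate(
        species=Species.BISGMA, beads=beads, bonds=bonds, angles=angles,
        dihedrals=dihedrals, reactive_bead_locals=[0, 14], reference_coords=coords,
    )


# ---------------------------------------------------------------------------
# formulation arithmetic
# ---------------------------------------------------------------------------

#: the nine tabulated formulation compositions (Bis-GMA weight fractions)
FORMULATION_TABLE_WEIGHT_FRACTIONS = (0.0, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 1.0)


@dataclass(frozen=True)
class Formulation:
    w_bisgma: float
    n_tegdma: int
    n_bisgma: int
    mw_bisgma: float = MW_BISGMA
    mw_tegdma: float = MW_TEGDMA

    @property
    def total_mass_amu(self) -> float:
        return self.n_tegdma * self.mw_tegdma + self.n_bisgma * self.mw_bisgma

    @property
    def realized_w_bisgma(self) -> float:
        m = self.total_mass_amu
        return self.n_bisgma * self.mw_bisgma / m if m > 0 else 0.0


def formulation_counts(
    w_bisgma: float,
    mass_basis: int = 1000,
    mw: tuple[float, float] = (MW_TEGDMA, MW_BISGMA),
) -> tuple[int, int]:
    """Molecule counts ``(n_tegdma, n_bisgma)`` for a target weight fraction.

    The total target mass is ``mass_basis`` TEGDMA-equivalents; each species
    count is the nearest integer realizing its mass share.  With the default
    molar masses and ``mass_basis=1000`` this reproduces the nine tabulated
    composition tuples, e.g. ``w=0.5 -> (500, 279)``.
    """
    if not 0.0 <= w_bisgma <= 1.0:
        raise ValueError("weight fraction must lie in [0, 1]")
    if mass_basis <= 0:
        raise ValueError("mass basis must be positive")
    mw_teg, mw_bis = mw
    total_mass = mass_basis * mw_teg
    n_teg = round((1.0 - w_bisgma) * total_mass / mw_teg)
    n_bis = round(w_bisgma * total_mass / mw_bis)
    return int(n_teg), int(n_bis)


def make_formulation(w_bisgma: float, mass_basis: int = 1000) -> Formulation:
    n_teg, n_bis = formulation_counts(w_bisgma, mass_basis)
    return Formulation(w_bisgma=w_bisgma, n_tegdma=n_teg, n_bisgma=n_bis)
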