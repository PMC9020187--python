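"""Interaction functional forms and parameter tables.

The model uses four bonded term classes — harmonic bonds, harmonic angles,
periodic (proper and improper) dihedrals — plus a shifted 12-6 Lennard-Jones
nonbonded potential between coarse-grain beads.  Seven Martini-3 bead types
appear in the Bis-GMA/TEGDMA resin model: SC4, N4a, TP1, TN2a, TC5, SC2 and
SN3a.  The leading letter encodes the size class (``T`` tiny, ``S`` small,
otherwise regular), which fixes both the simulation mass (36/54/72 amu by
default) and the number of heavy atoms a bead absorbs (2/3/4).

Energies are kJ mol^-1, distances nm, angles degrees at the API surface
(radians internally where noted).  The harmonic prefactor convention is
``1/2 k (x - x0)^2``; the alternative ``k (x - x0)^2`` convention can be
selected with ``prefactor="full"`` since force constants in the literature
are quoted under either convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "BEAD_TYPES",
    "SIZE_CLASS",
    "DEFAULT_MASSES",
    "HEAVY_ATOMS",
    "BeadSpec",
    "BondTerm",
    "AngleTerm",
    "DihedralTerm",
    "NonbondedTable",
    "ForceField",
    "bead_spec",
    "harmonic_bond_energy",
    "harmonic_angle_energy",
    "periodic_dihedral_energy",
    "lj_energy",
    "load_forcefield",
    "default_forcefield",
]

BEAD_TYPES = ("SC4", "N4a", "TP1", "TN2a", "TC5", "SC2", "SN3a")

#: size class per bead-type prefix: T -> tiny, S -> small, else regular
SIZE_CLASS = {t: ("tiny" if t[0] == "T" else "small" if t[0] == "S" else "regular") for t in BEAD_TYPES}

#: standard Martini masses by size class (amu)
DEFAULT_MASSES = {"regular": 72.0, "small": 54.0, "tiny": 36.0}

#: heavy atoms absorbed per bead, by size class
HEAVY_ATOMS = {"regular": 4, "small": 3, "tiny": 2}


class ForceFieldError(ValueError):
    """Raised for invalid parameter files or out-of-domain evaluations."""


@dataclass(frozen=True)
class BeadSpec:
    """A coarse-grain bead type: chemical code, size class, mass, mapping size."""

    type_code: str
    size_class: str
    mass: float
    heavy_atoms: int

    def __post_init__(self):
        if self.type_code not in BEAD_TYPES:
            raise ForceFieldError(f"unknown bead type code {self.type_code!r}")
        if SIZE_CLASS[self.type_code] != self.size_class:
            raise ForceFieldError(
                f"size class {self.size_class!r} inconsistent with type {self.type_code!r}"
            )
        if self.heavy_atoms != HEAVY_ATOMS[self.size_class]:
            raise ForceFieldError(
                f"{self.size_class} bead must absorb {HEAVY_ATOMS[self.size_class]} heavy atoms"
            )


def bead_spec(type_code: str, mass: float | None = None) -> BeadSpec:
    """Build the canonical :class:`BeadSpec` for a Martini type code."""
    if type_code not in SIZE_CLASS:
        raise ForceFieldError(f"unknown bead type code {type_code!r}")
    size = SIZE_CLASS[type_code]
    return BeadSpec(
        type_code=type_code,
        size_class=size,
        mass=DEFAULT_MASSES[size] if mass is None else mass,
        heavy_atoms=HEAVY_ATOMS[size],
    )


@dataclass(frozen=True)
class BondTerm:
    bead_indices: tuple[int, int]
    r0: float  # nm
    k: float | None = None  # kJ mol^-1 nm^-2; None for constrained bonds
    constrained: bool = False

    def __post_init__(self):
        if self.r0 <= 0:
            raise ForceFieldError("bond equilibrium distance must be positive")
        if not self.constrained and (self.k is None or self.k <= 0):
            raise ForceFieldError("unconstrained bond needs a positive force constant")


@dataclass(frozen=True)
class AngleTerm:
    bead_indices: tuple[int, int, int]
    theta0: float  # degrees
    k: float | None = None  # kJ mol^-1 rad^-2; None for constrained angles
    constrained: bool = False

    def __post_init__(self):
        if not 0 < self.theta0 <= 180:
            raise ForceFieldError("equilibrium angle must lie in (0, 180] degrees")
        if not self.constrained and (self.k is None or self.k <= 0):
            raise ForceFieldError("unconstrained angle needs a positive force constant")


@dataclass(frozen=True)
class DihedralTerm:
    bead_indices: tuple[int, int, int, int]
    phi0: float  # degrees
    k: float  # kJ mol^-1
    n: int = 1
    improper: bool = False

    def __post_init__(self):
        if self.n < 1:
            raise ForceFieldError("dihedral multiplicity must be >= 1")
        if self.k < 0:
            raise ForceFieldError("dihedral energy constant must be >= 0")


@dataclass
class NonbondedTable:
    """Symmetric LJ pair coefficients (sigma nm, epsilon kJ mol^-1) for bead types."""

    pair_coefficients: dict[tuple[str, str], tuple[float, float]]
    cutoff: float = 1.1  # nm
    shift_mode: str = "potential-shift"  # or "none"

    def __post_init__(self):
        canon = {}
        for (a, b), (sig, eps) in self.pair_coefficients.items():
            if a not in BEAD_TYPES or b not in BEAD_TYPES:
                raise ForceFieldError(f"unknown bead type in pair ({a}, {b})")
            if sig <= 0 or eps <= 0:
                raise ForceFieldError(f"nonpositive LJ coefficient for pair ({a}, {b})")
            key = tuple(sorted((a, b)))
            if key in canon and canon[key] != (sig, eps):
                raise ForceFieldError(f"conflicting duplicate entries for pair ({a}, {b})")
            canon[key] = (sig, eps)
        n = len(BEAD_TYPES)
        expected = n * (n + 1) // 2
        if len(canon) != expected:
            missing = sorted(
                tuple(sorted((a, b)))
                for i, a in enumerate(BEAD_TYPES)
                for b in BEAD_TYPES[i:]
                if tuple(sorted((a, b))) not in canon
            )
            raise ForceFieldError(f"nonbonded table incomplete; missing pairs: {missing}")
        self.pair_coefficients = canon

    def lookup(self, a: str, b: str) -> tuple[float, float]:
        return self.pair_coefficients[tuple(sorted((a, b)))]

    def matrices(self, type_order: tuple[str, ...] = BEAD_TYPES) -> tuple[np.ndarray, np.ndarray]:
        """Dense (sigma, epsilon) matrices in the given type order, for vectorized lookups."""
        n = len(type_order)
        sig = np.zeros((n, n))
        eps = np.zeros((n, n))
        for i, a in enumerate(type_order):
            for j, b in enumerate(type_order):
                sig[i, j], eps[i, j] = self.lookup(a, b)
        return sig, eps


@dataclass
class ForceField:
    """Full parameter set used by the engine: LJ table, masses and conventions."""

    nonbonded: NonbondedTable
    masses: dict[str, float] = field(default_factory=lambda: {
        t: DEFAULT_MASSES[SIZE_CLASS[t]] for t in BEAD_TYPES
    })
    prefactor: str = "half"  # "half": 1/2 k dx^2 ; "full": k dx^2

    @property
    def _pref(self) -> float:
        return 0.5 if self.prefactor == "half" else 1.0


# ---------------------------------------------------------------------------
# scalar energy evaluations (the engine vectorizes these same forms)
# ---------------------------------------------------------------------------

def harmonic_bond_energy(r: float, term: BondTerm, prefactor: str = "half") -> tuple[float, float]:
    """Energy and force magnitude of a harmonic bond at separation ``r`` (nm).

    Returns ``(E, F)`` with ``E = 1/2 k (r - r0)^2`` and ``F = -dE/dr``
    (positive F pushes the beads apart).
    """
    if r <= 0:
        raise ForceFieldError("bond distance must be positive")
    if term.constrained:
        raise ForceFieldError("constrained bonds carry no harmonic energy")
    c = 0.5 if prefactor == "half" else 1.0
    dr = r - term.r0
    return c * term.k * dr * dr, -2.0 * c * term.k * dr


def harmonic_angle_energy(theta: float, term: AngleTerm, prefactor: str = "half") -> tuple[float, float]:
    """Energy and generalized force ``-dE/dtheta`` (per radian) of a harmonic angle.

    ``theta`` in degrees; the squared deviation is taken in radians.
    """
    if not 0 <= theta <= 180:
        raise ForceFieldError("angle must lie in [0, 180] degrees")
    c = 0.5 if prefactor == "half" else 1.0
    dth = math.radians(theta - term.theta0)
    return c * term.k * dth * dth, -2.0 * c * term.k * dth


def periodic_dihedral_energy(phi: float, term: DihedralTerm) -> float:
    """Periodic torsion energy ``k (1 + cos(n phi - phi0))``, angles in degrees.

    The same functional form serves proper and improper dihedrals.
    """
    return term.k * (1.0 + math.cos(math.radians(term.n * phi - term.phi0)))


def lj_energy(
    r: float,
    pair: tuple[float, float],
    cutoff: float | None = None,
    shift: bool = True,
) -> float:
    """12-6 Lennard-Jones energy, optionally potential-shifted to zero at the cutoff."""
    if r <= 0:
        raise ForceFieldError("LJ distance must be positive")
    sigma, epsilon = pair
    if cutoff is not None and r > cutoff:
        return 0.0
    sr6 = (sigma / r) ** 6
    e = 4.0 * epsilon * (sr6 * sr6 - sr6)
    if shift and cutoff is not None:
        src6 = (sigma / cutoff) ** 6
        e -= 4.0 * epsilon * (src6 * src6 - src6)
    return e


# ---------------------------------------------------------------------------
# parameter file I/O
# ---------------------------------------------------------------------------

def load_forcefield(path: str | Path, prefactor: str = "half") -> ForceField:
    """Load a force field from the plain-text ``[masses]`` / ``[pairs]`` format.

    Pairs are listed as ``TYPE1 TYPE2 sigma_nm epsilon_kJmol``; ``#`` starts a
    comment.  Missing pairs, unknown type codes and nonpositive coefficients
    are validation errors — nothing is silently defaulted.
    """
    path = Path(path)
    masses: dict[str, float] = {}
    pairs: dict[tuple[str, str], tuple[float, float]] = {}
    cutoff = 1.1
    shift_mode = "potential-shift"
    section = None
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip().lower()
            continue
        fields = line.split()
        if section == "masses":
            if len(fields) != 2:
                raise ForceFieldError(f"{path}:{lineno}: expected 'TYPE mass_amu'")
            t, m = fields[0], float(fields[1])
            if t not in BEAD_TYPES:
                raise ForceFieldError(f"{path}:{lineno}: unknown type code {t!r}")
            if m <= 0:
                raise ForceFieldError(f"{path}:{lineno}: nonpositive mass for {t}")
            masses[t] = m
        elif section == "pairs":
            if len(fields) != 4:
                raise ForceFieldError(f"{path}:{lineno}: expected 'TYPE1 TYPE2 sigma epsilon'")
            a, b = fields[0], fields[1]
            sig, eps = float(fields[2]), float(fields[3])
            for t in (a, b):
                if t not in BEAD_TYPES:
                    raise ForceFieldError(f"{path}:{lineno}: unknown type code {t!r}")
            if sig <= 0 or eps <= 0:
                raise ForceFieldError(
                    f"{path}:{lineno}: nonpositive LJ coefficient for pair ({a}, {b})"
                )
            pairs[(a, b)] = (sig, eps)
        elif section == "options":
            key = fields[0].lower()
            if key == "cutoff_nm":
                cutoff = float(fields[1])
            elif key == "shift":
                shift_mode = "potential-shift" if fields[1].lower() in ("yes", "true", "on") else "none"
            else:
                raise ForceFieldError(f"{path}:{lineno}: unknown option {key!r}")
        else:
            raise ForceFieldError(f"{path}:{lineno}: data outside a known section")
    table = NonbondedTable(pair_coefficients=pairs, cutoff=cutoff, shift_mode=shift_mode)
    full_masses = {t: DEFAULT_MASSES[SIZE_CLASS[t]] for t in BEAD_TYPES}
    full_masses.update(masses)
    return ForceField(nonbonded=table, masses=full_masses, prefactor=prefactor)


def default_forcefield(prefactor: str = "half") -> ForceField:
    """The bundled default parameter file (synthetic nonbonded stand-in table)."""
    with resources.as_file(
        resources.files("cgresin").joinpath("data/nonbonded_synthetic.ff")
    ) as p:
        return load_forcefield(p, prefactor=prefactor)
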