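# Methods

`cgresin` simulates the photopolymerizable organic phase of dental composites
— Bis-GMA diluted with TEGDMA — at Martini-3-style coarse-grain resolution,
generates crosslinked networks by simulated chain-growth polymerization, and
measures the observables that matter for resin development: density, curing
shrinkage, double-bond conversion and the glass transition.

## Coarse-grain model

Groups of 2–4 heavy atoms map to single beads in three Martini size classes
(tiny/small/regular: 2/3/4 heavy atoms; simulation masses 36/54/72 amu).
Seven standard bead types appear: SC4 (methacrylate, the reactive C=C
carrier), N4a (ester), TP1 (hydroxyl), TN2a (ether-aromatic), TC5 (aromatic
carbon), SC2 (isopropylidene bridge) and SN3a (glycol ether).  TEGDMA is a
linear 6-bead chain (SC4–N4a–SN3a–SN3a–N4a–SC4, 20 heavy atoms); Bis-GMA has
15 beads — two methacrylate arms, two aromatic rings of three TC5 beads and
a central SC2 bridge (37 heavy atoms).  Bead positions correspond to
centre-of-geometry mapping; `analysis.cg_map` implements that convention for
mapping all-atom trajectories.

Bonded interactions are harmonic bonds E = ½k(r−r₀)², harmonic angles
E = ½k(θ−θ₀)² and periodic torsions V = k(1 + cos(nφ−φ₀)) used for both
proper and improper dihedrals.  The ½k prefactor convention matches the
tabulated units (kJ mol⁻¹ nm⁻², kJ mol⁻¹ rad⁻²); the force-field object
accepts `prefactor="full"` for parameter sets quoted under the k(x−x₀)²
convention.  Each aromatic ring is a rigid triangle: two constrained bonds
(0.229 nm on the edge adjacent to the arm, 0.197 nm on the other — the
longer constrained edge sits next to the ether-aromatic bead) plus one
constrained angle.  The constrained ring angle has no published value; we
fix it at 60°, which by the law of cosines turns the angle constraint into a
third distance of 0.21477 nm and gives a near-equilateral triangle.  Two
improper dihedrals per ring keep the arm and bridge substituents in the ring
plane, and two soft periodic torsions per ring (k = 8.46 kJ/mol, n = 2,
φ₀ = 313°) reproduce the bimodal ring-rotation statistics.

One modelling choice deserves emphasis: the two ring-rotation torsions are
placed one on the arm-side bond path (3-4-5-5) and one on the bridge-side
path (5-6-5-5).  Putting both on the arm side would require a quadruple
through the far ring vertex whose three inner beads are permanently close to
collinear — exactly where the torsion gradient is singular — and is
numerically untenable.

## Nonbonded interactions

Beads are uncharged; the only nonbonded term is a 12-6 Lennard-Jones
potential, potential-shifted to zero at a 1.1 nm cutoff, with 1-2 and 1-3
bonded neighbors excluded.  The bundled pair table
(`data/nonbonded_synthetic.ff`) is a synthetic stand-in constructed from the
published Martini 3 size-class sigmas (0.47/0.41/0.34 nm) and a
chemistry-informed epsilon ladder (geometric mean with a polarity-mismatch
reduction, self-epsilons 2.6–4.3 kJ/mol).  It yields condensed phases with
realistic densities (the equilibrated 50 wt% resin comes out near
1.1–1.2 g/cm³) but it is *not* the published Martini 3 interaction matrix;
quantitative production work should substitute that matrix in the same file
format.  The engine itself is parameter-agnostic: any complete 28-pair table
for the seven types is accepted, and incomplete or invalid tables are
rejected at load time rather than defaulted.

In boxes narrower than twice the nominal cutoff (small demonstration
systems) the interaction range is truncated to half the box edge minus the
neighbor skin, so the minimum-image convention stays exact.

## Dynamics

Velocity-Verlet integration at a 20 fs production timestep (internal units
nm/ps/amu/K/bar; 1 amu nm² ps⁻² = 1 kJ/mol).  Temperature is controlled by
Bussi-style stochastic velocity rescaling (τ = 1.0 ps), chosen for canonical
sampling with strict seed reproducibility; pressure by an isotropic
Berendsen weak-coupling barostat (τ = 12 ps, compressibility 3×10⁻⁴ bar⁻¹,
a typical value for a coarse-grained organic liquid).  Ring constraints are
enforced by SHAKE on positions (Gauss-Seidel sweeps over bead-disjoint
constraint groups, reference-direction corrections, relative tolerance 10⁻⁴)
and a RATTLE-style velocity projection; after each barostat rescaling the
constraints are re-projected.  Degrees of freedom for the kinetic
temperature subtract constraints and the removed centre-of-mass motion.

Neighbor search uses a periodic k-d tree with a 0.2 nm skin; the pair list
is rebuilt when any bead's Euclidean displacement since the last build
exceeds 0.45 × skin.  The pressure virial accumulates pairwise r·f for
bonds and LJ terms, molecule-local r·f for angles and torsions, and an
estimate of the constraint contribution from projecting the unconstrained
forces onto the constraint directions.

Two numerical safeguards: (1) per-torsion forces are capped at
2000 kJ mol⁻¹ nm⁻¹ — the torsion gradient diverges when three of its beads
pass through collinearity, which the soft 40 kJ mol⁻¹ rad⁻² arm angle makes
reachable in rare fluctuations; the cap is applied to all four force
contributions of the affected term jointly, preserving zero net force and
torque.  (2) freshly packed boxes are relaxed by `equilibrate_system`:
minimization, a 2 fs warm-up NVT segment, a second minimization, then the
production NPT run.  Hard-core packing leaves steep repulsive contacts that
the production timestep cannot integrate directly.

Energy minimization is steepest descent with adaptive step control and a
0.02 nm displacement cap; accepted steps never increase the energy and the
constraint manifold is re-projected after every accepted move.

## System preparation

`pack_box` inserts molecules in the published order — initiator molecules
first, then Bis-GMA, then the remaining TEGDMA — with random positions and
orientations, rejecting any insertion that puts two intermolecular beads
closer than 0.25 nm.  Initiators are drawn from the TEGDMA allotment when
the formulation has any, else from Bis-GMA; one of each initiator's two
methacrylate beads (seeded choice) carries the active (radical) label and is
no longer counted as an unreacted double bond.  The initial box volume comes
from a density guess (default 0.9 g/cm³) and is corrected by the barostat;
the packing rejection distance and density guess are configuration values,
since neither is prescribed by the source tables.  Formulation molecule
counts follow nearest-integer mass partitioning over a TEGDMA-equivalent
mass basis; with the default molar masses (286.32 / 512.59 g/mol) and basis
1000 this reproduces the nine published composition tuples exactly.

Coordinates are stored unwrapped internally (volumes, shrinkage and
diffusion stay well-defined) and wrapped only on file output (GRO in nm,
XYZ in Å, LAMMPS data in Å).

## Simulated polymerization

Only propagation is modelled — no termination or combination reactions, and
no rate constants: bonding is purely geometric.  At each attempt every
(active, reactive) bead pair within the 0.55 nm cutoff (inclusive) is a
candidate; candidates are matched greedily nearest-first with ties broken by
bead index, each active bead forms at most one bond per attempt, and each
reactive bead is consumed at most once.  On bonding, the backbone potential
is added (bond k = 35 000 kJ mol⁻¹ nm⁻², r₀ = 0.31 nm; backbone angle
350 kJ mol⁻¹ rad⁻² at 125°; backbone-sidechain angles 50 kJ mol⁻¹ rad⁻² at
80°; no backbone torsions) and the active label transfers to the partner, so
a newly activated bead becomes eligible only at the next attempt.
Cyclization is permitted except between two methacrylate beads of the same
monomer whose static bond path is five bonds or shorter (a TEGDMA reacting
with itself would close a numerically degenerate loop); both rules are
configurable.  Reacted beads keep their Martini type.

The schedule mirrors the published recipe: after ten accumulated bonds the
system is minimized and relaxed by 40 000 MD steps; an attempt that forms no
bond triggers a 20 000-step retry run; the run terminates after 40
*consecutive* empty attempts (the consecutive reading of the failure window
is an interpretation; the counter resets on any success).  A short
minimization also follows every successful attempt, because a bond formed
near the cutoff starts 0.24 nm beyond its rest length.  Every formed bond is
logged with its formation-time distance, enabling replay audits.  Conversion
is the fraction of methacrylate beads consumed; by default initiator
radicals count as reacted (their double bond opened at initiation), and both
conventions are available.

## Analyses

*Density* divides the real molar masses (not the Martini masses used for
dynamics) by the box volume.  *Shrinkage* is the percent volume decrease
from the time-averaged pre-cure NPT volume (last quarter of the
equilibration run) to the post-cure volume.  *Glass transition*: a heating
sweep ramps the thermostat set point linearly (default 150→500 K over 10⁶
steps, run as equal NPT segments with the density of each segment's second
half attributed to its midpoint temperature); the sweep is fitted by two
free straight lines with the breakpoint chosen by scanning all interior
splits for minimum total squared residual, and Tg is reported as the
intersection of the two lines.  Collinear sweeps produce a degenerate-fit
warning and a single-line result.  *Bonded distributions* histogram bond
lengths, angles and torsion angles over trajectory frames, with peak
counting (prominence-thresholded) for bimodality checks of the ring-rotation
torsions.

## Problem sizes used in tests and the acceptance script

The bundled test systems are deliberately small so the full pipeline runs in
minutes on one core: the mixed fixture has 10 TEGDMA + 4 Bis-GMA (120
beads), engine physics checks use 30–50 TEGDMA boxes (180–300 beads), and
the acceptance script cures a 50 wt% formulation at mass basis 25 (12 TEGDMA
+ 7 Bis-GMA, 177 beads, 2 initiators) with the relaxation segments of the
polymerization schedule and the sweeps scaled down accordingly (400/200-step
relax/retry, 24 000-step sweeps in 16 segments).  Full-scale packing (the
(500; 279) box, 7185 beads) is exercised in the tests; full-scale dynamics
at 10⁶-step sweeps is the same code path at a larger `n_steps` and is not
run in the default suite.

What the small systems do and do not show: they exercise every algorithmic
contract (label conservation, audit distances, schedule semantics,
constraint tolerances, fit recovery) and give qualitatively correct physics
(thermal expansion, curing shrinkage, conversion plateaus).  They do not
give converged material properties: Tg estimates from 177-bead,
24 000-step sweeps carry tens-of-kelvin statistical uncertainty, finite-size
effects inflate conversion (a radical finds partners more easily in a small
periodic box), and the synthetic nonbonded table shifts absolute densities.

## Known limitations

- No electrostatics (all beads uncharged) and no triclinic boxes.
- Berendsen pressure coupling does not generate a rigorous NPT ensemble;
  it was chosen for robustness on small, far-from-equilibrium boxes.
- The constraint virial is an approximation (force projection), so reported
  pressures on constrained systems carry a small systematic error.
- The torsion force cap makes the force field non-conservative during rare
  near-collinear events; NVE validation is therefore done on TEGDMA boxes,
  where the cap never engages.
- Termination kinetics are absent by design; the number of active sites is
  an effective parameter, not a measured initiator concentration.
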