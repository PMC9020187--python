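# cgresin

Coarse-grained molecular simulation of photopolymerizable dental resins:
Bis-GMA/TEGDMA formulations, Martini-3-style bead models, simulated
chain-growth polymerization, and the curing observables that drive resin
development — density, volumetric shrinkage, double-bond conversion and
glass-transition estimates.

## Who this is for

Light-cured dimethacrylate resins (restorative dentistry, vat
photopolymerization) are usually optimized by trial and error because no
experiment sees the crosslinked network directly.  `cgresin` is a
self-contained desk-scale simulator for exploring that network
computationally: it builds Bis-GMA (bisphenol A-glycidyl methacrylate,
512.59 g/mol) and TEGDMA (triethylene glycol dimethacrylate, 286.32 g/mol)
mixtures as coarse-grain bead models, cures them with a geometric
radical-propagation algorithm, and analyses the result.  Everything — force
field evaluation, MD engine with SHAKE-constrained aromatic rings, NPT
ensembles, network generation, fits — is implemented in Python on
numpy/scipy, seeded and reproducible.

## The model in brief

* **Mapping.** 2–4 heavy atoms per bead (Martini tiny/small/regular size
  classes, masses 36/54/72 amu).  TEGDMA: 6 beads, SC4–N4a–SN3a–SN3a–N4a–SC4.
  Bis-GMA: 15 beads — two SC4–N4a–TP1–TN2a arms, two rigid three-bead TC5
  rings, one SC2 bridge.  Both monomers are bifunctional: the terminal SC4
  beads carry the polymerizable C=C groups.
* **Potentials.** Harmonic bonds ½k(r−r₀)² and angles ½k(θ−θ₀)², periodic
  torsions V = k(1 + cos(nφ−φ₀)) for propers and impropers, shifted 12-6
  Lennard-Jones with a 1.1 nm cutoff.  Each aromatic ring is held rigid by
  two constrained bonds and one constrained angle, enforced with SHAKE.
* **Simulated polymerization.** Beads are labelled *reactive* (unreacted
  C=C) or *active* (radical).  An active–reactive pair within 5.5 Å bonds;
  the backbone potential is added and the active label transfers to the
  partner, so chains grow.  After ten bonds the network is minimized and
  relaxed by MD; empty attempts trigger retry runs, and 40 consecutive empty
  attempts terminate the cure.  Only propagation is modelled — no
  termination reactions.
* **Observables.** Densities use the monomers' real molar masses (the
  coarse-grain masses serve only the dynamics).  Shrinkage is the percent
  volume loss of the NPT box upon curing.  Conversion is the fraction of
  methacrylate beads consumed.  Tg comes from a heating sweep
  (150→500 K) fitted piecewise by two straight lines; the intersection
  temperature is the estimate.

The bundled nonbonded table is a clearly-labelled synthetic stand-in built
from Martini 3 size-class sigmas and a chemistry-informed epsilon ladder
(see `docs/methods.md`); substitute the published Martini 3 matrix in the
same text format for production work.

## Worked example

Cure a scaled-down 50 wt% Bis-GMA formulation (12 TEGDMA + 7 Bis-GMA,
177 beads, 2 radicals) and measure the curing observables:

```python
from cgresin import (EnsembleSpec, Formulation, PolymerizationSchedule,
                     conversion, density, pack_box, polymerization_run, shrinkage)
from cgresin.engine import equilibrate_system
from cgresin.forcefield import default_forcefield

ff = default_forcefield()
f = Formulation(w_bisgma=0.5, n_tegdma=12, n_bisgma=7)
topo, state = pack_box(f, n_active=2, target_density_guess=0.7, seed=3)

ens = EnsembleSpec(temperature=298.0, pressure=1.0, timestep_fs=20.0)
state, obs = equilibrate_system(state, topo, ff, ens, 6000, seed=4)
v0 = obs["V_nm3"].iloc[-len(obs)//4:].mean()
print(f"resin density {density(state, topo):.3f} g/cm3")

sched = PolymerizationSchedule(bonding_cutoff=0.55, relax_steps=400,
                               retry_steps=200, max_failed_attempts=6, seed=5)
state, records, events = polymerization_run(state, topo, ff, sched, ens)
print(f"{len(topo.polymer_bond_idx)} bonds, conversion {conversion(topo):.2f}, "
      f"shrinkage {shrinkage(v0, state.volume):.1f} %")
```

Typical output (seeds as shown):

```
resin density 1.193 g/cm3
25 bonds, conversion 0.71, shrinkage 7.6 %
```

The density is the physical mass density of the equilibrated resin; the
conversion says 71 % of the methacrylate groups reacted before the radical
mobility criterion terminated the cure, and the box lost ~7 % of its volume
— the polymerization shrinkage that causes debonding and warpage in
practice.  Small periodic boxes over-convert relative to experiment (a
radical finds partners easily); trends across formulations are the
meaningful output at this scale.

The same pipeline is scriptable from a YAML config through the CLI:

```bash
cgresin pack config.yaml && cgresin minimize config.yaml \
  && cgresin equilibrate config.yaml && cgresin polymerize config.yaml \
  && cgresin sweep config.yaml && cgresin analyze config.yaml
```

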