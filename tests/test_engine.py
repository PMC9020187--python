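"""Force correctness, constraint projection, integrators and ensembles."""

import numpy as np
import pytest

from cgresin.engine import (
    EnsembleSpec,
    MinimizationError,
    compute_forces,
    equilibrate_system,
    initialize_velocities,
    minimize,
    run_md,
    shake_project,
    temperature_sweep,
)
from cgresin.forcefield import AngleTerm, BondTerm, DihedralTerm, bead_spec
from cgresin.molecules import MoleculeTemplate, Species
from cgresin.system import SystemState, Topology

BIG_BOX = np.array([50.0, 50.0, 50.0])
EMPTY_PAIRS = np.zeros((0, 2), dtype=int)


def _template(n, bonds=(), angles=(), dihedrals=(), coords=None):
    coords = coords if coords is not None else np.zeros((n, 3))
    return MoleculeTemplate(
        species=Species.TEGDMA,
        beads=[(i, bead_spec("SC4"), 1) for i in range(n)],
        bonds=list(bonds), angles=list(angles), dihedrals=list(dihedrals),
        reactive_bead_locals=[], reference_coords=np.asarray(coords, dtype=float),
    )


def _system(template, positions):
    topo = Topology()
    topo.add_molecule(template)
    state = SystemState(np.asarray(positions, dtype=float), np.zeros((template.n_beads, 3)), BIG_BOX.copy())
    return topo, state


def _fd_check(topo, positions, ff, pairs, n_trials, rng, rtol=1e-5):
    state = SystemState(positions, np.zeros_like(positions), BIG_BOX.copy())
    forces, _, _ = compute_forces(state, topo, ff, pairs=pairs)
    h = 1e-6
    for _ in range(n_trials):
        i = rng.integers(len(positions))
        d = rng.integers(3)
        pp = positions.copy()
        pp[i, d] += h
        pm = positions.copy()
        pm[i, d] -= h
        ep = compute_forces(SystemState(pp, positions * 0, BIG_BOX.copy()), topo, ff, pairs=pairs)[1]["potential"]
        em = compute_forces(SystemState(pm, positions * 0, BIG_BOX.copy()), topo, ff, pairs=pairs)[1]["potential"]
        num = -(ep - em) / (2 * h)
        assert num == pytest.approx(forces[i, d], rel=rtol, abs=1e-4)
    return forces


class TestComputeForces:
    def test_template_equilibrium_has_zero_bonded_energy(self, teg, ff):
        topo, state = _system(teg, teg.reference_coords + 25.0)
        _, e, _ = compute_forces(state, topo, ff, pairs=EMPTY_PAIRS)
        assert e["bond"] == pytest.approx(0.0, abs=1e-9)
        assert e["angle"] == pytest.approx(0.0, abs=1e-9)

    def test_two_bead_lj_closed_form(self, ff):
        t = _template(2)
        r = 0.45
        topo, state = _system(t, [[25, 25, 25], [25 + r, 25, 25]])
        pairs = np.array([[0, 1]])
        forces, e, _ = compute_forces(state, topo, ff, pairs=pairs)
        sigma, eps = ff.nonbonded.lookup("SC4", "SC4")
        rc = 1.1
        sr6 = (sigma / r) ** 6
        src6 = (sigma / rc) ** 6
        expected = 4 * eps * (sr6**2 - sr6) - 4 * eps * (src6**2 - src6)
        assert e["lj"] == pytest.approx(expected, rel=1e-12)
        fmag = 24 * eps * (2 * sr6**2 - sr6) / r
        assert forces[1, 0] == pytest.approx(fmag, rel=1e-12)

    def test_forces_match_finite_differences_per_term_type(self, ff):
        """Analytic forces vs central differences for bond, angle, proper and
        improper dihedral and LJ terms on 100 random configurations each."""
        rng = np.random.default_rng(42)
        n_cfg = 25  # 25 configurations x 4 probes each = 100 random checks
        for _ in range(n_cfg):
            # bond
            t = _template(2, bonds=[BondTerm((0, 1), 0.355, k=35000.0)])
            pos = np.array([[25.0, 25, 25], [25.3, 25.1, 24.9]]) + rng.normal(scale=0.05, size=(2, 3))
            topo, _ = _system(t, pos)
            _fd_check(topo, pos, ff, EMPTY_PAIRS, 4, rng)
            # angle
            t = _template(3, bonds=[BondTerm((0, 1), 0.3, k=100.0), BondTerm((1, 2), 0.3, k=100.0)],
                          angles=[AngleTerm((0, 1, 2), 120.0, k=700.0)])
            pos = np.array([[24.7, 25, 25], [25.0, 25, 25], [25.2, 25.25, 25.1]]) + rng.normal(scale=0.04, size=(3, 3))
            topo, _ = _system(t, pos)
            _fd_check(topo, pos, ff, EMPTY_PAIRS, 4, rng)
            # proper and improper dihedral (same functional form)
            for improper in (False, True):
                t = _template(4, dihedrals=[DihedralTerm((0, 1, 2, 3), 313.0, 35.0, 2, improper=improper)])
                pos = np.array([[24.6, 25, 25], [25, 25, 25], [25.3, 25.2, 25], [25.5, 25.2, 25.4]])
                pos = pos + rng.normal(scale=0.04, size=(4, 3))
                topo, _ = _system(t, pos)
                _fd_check(topo, pos, ff, EMPTY_PAIRS, 4, rng)
            # shifted LJ pair away from the cutoff discontinuity
            t = _template(2)
            r = 0.38 + 0.5 * rng.random()
            pos = np.array([[25.0, 25, 25], [25 + r, 25, 25]])
            topo, _ = _system(t, pos)
            _fd_check(topo, pos, ff, np.array([[0, 1]]), 4, rng)

    def test_isolated_term_forces_sum_to_zero(self, ff, bis):
        rng = np.random.default_rng(3)
        topo, state = _system(bis, bis.reference_coords + rng.normal(scale=0.02, size=(15, 3)) + 25)
        forces, _, _ = compute_forces(state, topo, ff, pairs=EMPTY_PAIRS)
        assert np.max(np.abs(forces.sum(axis=0))) < 1e-10

    def test_overlapping_beads_raise(self, ff):
        t = _template(2, bonds=[BondTerm((0, 1), 0.3, k=100.0)])
        topo, state = _system(t, [[25, 25, 25], [25, 25, 25]])
        with pytest.raises(FloatingPointError):
            compute_forces(state, topo, ff, pairs=EMPTY_PAIRS)


class TestShake:
    def _ring_cluster(self):
        import math
        idx = np.array([[0, 1], [1, 2], [0, 2]])
        third = math.sqrt(0.229**2 + 0.197**2 - 2 * 0.229 * 0.197 * math.cos(math.radians(60)))
        d0 = np.array([0.229, 0.197, third])
        masses = np.full(3, 36.0)
        # satisfied triangle
        import math
        pos = np.array([
            [0.0, 0.0, 0.0],
            [0.229, 0.0, 0.0],
            [0.229 - 0.197 * math.cos(math.radians(60)), 0.197 * math.sin(math.radians(60)), 0.0],
        ])
        # place so that |p0-p2| = 0.21477 (law of cosines at vertex 1)
        return idx, d0, masses, pos + 5.0

    def test_satisfied_constraints_identity(self):
        idx, d0, masses, pos = self._ring_cluster()
        out, iters = shake_project(pos, idx, d0, masses, BIG_BOX, tol=1e-6)
        assert iters == 0
        assert np.array_equal(out, pos)

    def test_stretched_edge_restored(self):
        idx, d0, masses, pos = self._ring_cluster()
        bad = pos.copy()
        bad[1] += (bad[1] - bad[0]) * 0.05  # stretch first edge by 5%
        out, _ = shake_project(bad, idx, d0, masses, BIG_BOX, tol=1e-8)
        for (i, j), d in zip(idx, d0):
            assert np.linalg.norm(out[i] - out[j]) == pytest.approx(d, rel=1e-7)

    def test_angle_constraint_third_distance_law_of_cosines(self, bis):
        """The 60-degree constrained ring angle maps to a 0.21477 nm
        bead-to-bead distance between the outer ring beads."""
        topo = Topology()
        topo.add_molecule(bis)
        import math
        expected = math.sqrt(0.229**2 + 0.197**2 - 2 * 0.229 * 0.197 * math.cos(math.radians(60)))
        derived = [d for d in topo.constraint_d0 if not np.isclose(d, 0.229) and not np.isclose(d, 0.197)]
        assert len(derived) == 2
        for d in derived:
            assert d == pytest.approx(expected, rel=1e-12)

    def test_perturbed_ring_constraints_restored_by_minimize(self, bis, ff):
        rng = np.random.default_rng(5)
        topo = Topology()
        topo.add_molecule(bis)
        pos = bis.reference_coords + rng.normal(scale=0.01, size=(15, 3)) + 25
        state = SystemState(pos, np.zeros_like(pos), BIG_BOX.copy())
        out = minimize(state, topo, ff, force_tol=100.0, max_steps=200)
        for (i, j), d in zip(topo.constraint_idx, topo.constraint_d0):
            r = np.linalg.norm(out.positions[i] - out.positions[j])
            assert r == pytest.approx(d, rel=1e-5)


class TestMinimize:
    def test_stretched_dimer_relaxes_to_r0(self, ff):
        t = _template(2, bonds=[BondTerm((0, 1), 0.355, k=35000.0)])
        topo, state = _system(t, [[25, 25, 25], [25.6, 25, 25]])
        out = minimize(state, topo, ff, force_tol=0.01, max_steps=2000)
        r = np.linalg.norm(out.positions[1] - out.positions[0])
        # LJ between the pair shifts the minimum marginally off r0
        assert r == pytest.approx(0.355, abs=5e-3)

    def test_energy_never_increases(self, mixed14, ff):
        topo, state = mixed14
        e_prev = compute_forces(state, topo, ff)[1]["potential"]
        out = minimize(state, topo, ff, force_tol=50.0, max_steps=150)
        e_post = compute_forces(out, topo, ff)[1]["potential"]
        assert e_post <= e_prev


class TestDynamics:
    def test_zero_steps_leaves_state_unchanged(self, mixed14, ff):
        topo, state = mixed14
        out, obs = run_md(state, topo, ff, EnsembleSpec(), 0, seed=1)
        assert np.array_equal(out.positions, state.positions)
        assert len(obs) == 0

    def test_determinism_same_seed_identical_trajectory(self, equilibrated_tegdma30, ff):
        topo, state = equilibrated_tegdma30
        ens = EnsembleSpec(temperature=298.0, pressure=1.0)
        o1, t1 = run_md(state.copy(), topo, ff, ens, 100, seed=5)
        o2, t2 = run_md(state.copy(), topo, ff, ens, 100, seed=5)
        assert np.array_equal(o1.positions, o2.positions)
        assert np.array_equal(o1.velocities, o2.velocities)
        assert t1.equals(t2)

    def test_momentum_conserved_without_thermostat(self, equilibrated_tegdma30, ff):
        topo, state = equilibrated_tegdma30
        masses = topo.masses(ff)
        nve = EnsembleSpec(temperature=None, pressure=None, timestep_fs=10.0)
        out, _ = run_md(state.copy(), topo, ff, nve, 300, seed=2)
        p0 = (masses[:, None] * state.velocities).sum(axis=0)
        p1 = (masses[:, None] * out.velocities).sum(axis=0)
        assert np.allclose(p1, p0, atol=1e-9)

    def test_nvt_temperature_matches_set_point(self, equilibrated_tegdma30, ff):
        topo, state = equilibrated_tegdma30
        ens = EnsembleSpec(temperature=298.0, pressure=None)
        _, obs = run_md(state.copy(), topo, ff, ens, 4000, seed=8, sample_stride=20)
        tail = obs["T_K"].iloc[len(obs) // 4:]
        # tau_t = 1 ps = 50 steps; samples 20 steps apart are weakly correlated
        se = tail.std() / np.sqrt(len(tail) / 4)
        assert abs(tail.mean() - 298.0) < 3 * se + 3.0

    def test_npt_barostat_tracks_pressure(self, equilibrated_tegdma30, ff):
        topo, state = equilibrated_tegdma30
        ens = EnsembleSpec(temperature=298.0, pressure=1.0)
        _, obs = run_md(state.copy(), topo, ff, ens, 6000, seed=9, sample_stride=20)
        tail = obs["P_bar"].iloc[len(obs) // 2:]
        se = tail.std() / np.sqrt(len(tail) / 8)
        assert abs(tail.mean() - 1.0) < 3 * se + 20.0


class TestTemperatureSweep:
    def test_schedule_is_monotone_ramp(self, equilibrated_tegdma30, ff):
        topo, state = equilibrated_tegdma30
        series = temperature_sweep(state.copy(), topo, ff, 150.0, 500.0,
                                   n_steps=1000, seed=3, n_segments=10)
        assert len(series) == 10
        assert np.all(np.diff(series.temperatures) > 0)
        assert series.temperatures[0] >= 150.0
        assert series.temperatures[-1] <= 500.0

    def test_same_seed_identical_series(self, equilibrated_tegdma30, ff):
        topo, state = equilibrated_tegdma30
        s1 = temperature_sweep(state.copy(), topo, ff, 200.0, 400.0, n_steps=600, seed=4, n_segments=6)
        s2 = temperature_sweep(state.copy(), topo, ff, 200.0, 400.0, n_steps=600, seed=4, n_segments=6)
        assert np.array_equal(s1.densities, s2.densities)
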