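"""Chain-growth bonding rules, label bookkeeping and the reaction schedule."""

import numpy as np
import pytest

from cgresin.analysis import conversion
from cgresin.engine import EnsembleSpec
from cgresin.fixtures import make_fixture
from cgresin.molecules import Formulation
from cgresin.polymerize import (
    PolymerBondParams,
    PolymerizationSchedule,
    apply_bonding,
    find_candidates,
    polymerization_run,
)
from cgresin.system import minimum_image, pack_box


@pytest.fixture()
def reactive_pair():
    """Two TEGDMA molecules, one initiator, positioned with the active bead
    a controlled distance from a reactive bead of the other molecule."""
    f = Formulation(w_bisgma=0.0, n_tegdma=2, n_bisgma=0)
    topo, state = pack_box(f, n_active=1, target_density_guess=0.02, seed=1)
    return topo, state


def _set_distance(topo, state, d):
    """Move the second molecule so the nearest active-reactive distance is d."""
    a = int(np.flatnonzero(topo.active)[0])
    partner_mol = 1 - topo.mol_id[a]
    r_candidates = [i for i in np.flatnonzero(topo.reactive_available)
                    if topo.mol_id[i] == partner_mol]
    r = r_candidates[0]
    shift = state.positions[a] + np.array([d, 0, 0]) - state.positions[r]
    sel = topo.mol_id == partner_mol
    state.positions[sel] += shift
    return a, r


class TestFindCandidates:
    def test_pair_inside_cutoff_found(self, reactive_pair):
        topo, state = reactive_pair
        a, r = _set_distance(topo, state, 0.54)
        cands = find_candidates(state, topo, cutoff=0.55)
        assert (a, r) in {(c[0], c[1]) for c in cands}

    def test_pair_exactly_at_cutoff_included(self, reactive_pair):
        topo, state = reactive_pair
        a, r = _set_distance(topo, state, 0.55)
        cands = find_candidates(state, topo, cutoff=0.55)
        assert any(c[0] == a and c[1] == r for c in cands)

    def test_pair_beyond_cutoff_excluded(self, reactive_pair):
        topo, state = reactive_pair
        _set_distance(topo, state, 0.56 + 1e-6)
        assert find_candidates(state, topo, cutoff=0.55) == [] or all(
            c[2] <= 0.55 for c in find_candidates(state, topo, cutoff=0.55))

    def test_no_reactive_beads_empty(self, reactive_pair):
        topo, state = reactive_pair
        topo.reactive_available[:] = False
        assert find_candidates(state, topo, cutoff=5.0) == []

    def test_sorted_ascending_by_distance(self, reactive_pair):
        topo, state = reactive_pair
        _set_distance(topo, state, 0.4)
        cands = find_candidates(state, topo, cutoff=2.0)
        dists = [c[2] for c in cands]
        assert dists == sorted(dists)

    def test_same_molecule_short_loop_excluded(self, reactive_pair):
        """A TEGDMA's own two methacrylate beads (5 bonds apart) never react
        with each other under the short-loop rule."""
        topo, state = reactive_pair
        a = int(np.flatnonzero(topo.active)[0])
        own = [i for i in np.flatnonzero(topo.reactive_available)
               if topo.mol_id[i] == topo.mol_id[a]]
        cands = find_candidates(state, topo, cutoff=100.0)
        assert not any(c[1] in own for c in cands)


class TestApplyBonding:
    def test_label_transferred_not_consumed(self, reactive_pair):
        topo, state = reactive_pair
        a, r = _set_distance(topo, state, 0.5)
        n_active_before = int(topo.active.sum())
        formed = apply_bonding(state, topo, find_candidates(state, topo, 0.55))
        assert len(formed) == 1
        assert int(topo.active.sum()) == n_active_before
        assert not topo.active[a] and topo.active[r]
        assert topo.consumed[r] and not topo.reactive_available[r]

    def test_backbone_terms_added(self, reactive_pair):
        topo, state = reactive_pair
        _set_distance(topo, state, 0.5)
        formed = apply_bonding(state, topo, find_candidates(state, topo, 0.55))
        (a, r, _), = formed
        params = PolymerBondParams()
        assert (a, r) in topo.polymer_bond_idx
        assert topo.polymer_bond_r0[-1] == params.bond_r0
        assert topo.polymer_bond_k[-1] == params.bond_k
        # two backbone-sidechain angles (one per partner), no backbone angle yet
        assert len(topo.polymer_angle_idx) == 2
        assert all(t == 80.0 for t in topo.polymer_angle_theta0)

    def test_two_actives_one_reactive_single_bond(self):
        f = Formulation(w_bisgma=0.0, n_tegdma=3, n_bisgma=0)
        topo, state = pack_box(f, n_active=2, target_density_guess=0.02, seed=2)
        actives = np.flatnonzero(topo.active)
        reactive = [i for i in np.flatnonzero(topo.reactive_available)
                    if topo.mol_id[i] not in topo.mol_id[actives]][0]
        # place both actives near the same reactive bead, one slightly closer
        state.positions[actives[0]] = state.positions[reactive] + [0.30, 0, 0]
        state.positions[actives[1]] = state.positions[reactive] + [0, 0.35, 0]
        formed = apply_bonding(state, topo, find_candidates(state, topo, 0.55))
        assert len([f_ for f_ in formed if f_[1] == reactive]) == 1
        assert formed[0][0] == actives[0]  # nearest active wins

    def test_chain_growth_induction(self):
        """n sequential bonding events involve n+1 methacrylate beads with
        the terminal one active, and conversion follows (n+1)/total."""
        topo, state = make_fixture("chain5", seed=0)
        deg = topo.polymer_degree()
        assert len(topo.polymer_bond_idx) == 5
        assert int((deg > 0).sum()) == 6
        assert int(topo.active.sum()) == 1
        terminal = int(np.flatnonzero(topo.active)[0])
        assert deg[terminal] == 1  # chain end
        assert np.all(deg <= 2)
        # every degree-2 bead carries exactly one backbone angle
        backbone_angles = [a for a, t in zip(topo.polymer_angle_idx, topo.polymer_angle_theta0)
                           if t == 125.0]
        assert len(backbone_angles) == int((deg == 2).sum())
        assert conversion(topo, count_initiators_as_reacted=False) == pytest.approx(6 / 20)


class TestPolymerizationRun:
    def _tiny(self, n_active=2, seed=5):
        f = Formulation(w_bisgma=0.0, n_tegdma=10, n_bisgma=0)
        return pack_box(f, n_active=n_active, target_density_guess=0.45, seed=seed)

    def test_terminates_after_max_failures_when_no_actives(self, ff):
        topo, state = self._tiny(n_active=0)
        sched = PolymerizationSchedule(bonding_cutoff=0.55, max_failed_attempts=1,
                                       relax_steps=2, retry_steps=2, seed=1)
        _, records, events = polymerization_run(state, topo, ff, sched)
        assert len(records) == 1
        assert records[0].conversion == 0.0
        assert events == []

    def test_consecutive_failure_termination_count(self, ff):
        """With bonding impossible every attempt fails; the loop stops after
        exactly max_failed_attempts attempts."""
        topo, state = self._tiny(n_active=2)
        topo.reactive_available[:] = False  # disable bonding entirely
        sched = PolymerizationSchedule(bonding_cutoff=0.55, max_failed_attempts=4,
                                       relax_steps=2, retry_steps=2, seed=1)
        _, records, _ = polymerization_run(state, topo, ff, sched)
        assert len(records) == 4
        assert all(r.bonds_formed == 0 for r in records)

    def test_audited_bonds_within_cutoff_and_trace_monotone(self, ff):
        topo, state = self._tiny(n_active=2)
        cutoff = 0.9  # generous so the tiny box reacts quickly
        sched = PolymerizationSchedule(bonding_cutoff=cutoff, bonds_per_relaxation=4,
                                       relax_steps=60, retry_steps=30,
                                       max_failed_attempts=3, seed=2)
        _, records, events = polymerization_run(state, topo, ff, sched,
                                                EnsembleSpec(temperature=298.0, pressure=1.0))
        assert len(events) > 0
        for e in events:
            assert e.distance <= cutoff + 1e-12
        convs = [r.conversion for r in records]
        assert all(b >= a for a, b in zip(convs, convs[1:]))
        assert int(topo.active.sum()) == 2  # label count conserved
        # never bond active-active or reactive-reactive: every bond has one
        # end that was the initiator chain (consumed flag pattern)
        for i, j in topo.polymer_bond_idx:
            assert topo.mapping_labels[i] == 1 and topo.mapping_labels[j] == 1
        deg = topo.polymer_degree()
        assert np.all(deg <= 2)

    def test_static_inventory_unchanged_by_polymerization(self, ff):
        topo, state = self._tiny(n_active=2)
        before = (len(topo.bond_idx), len(topo.angle_idx), len(topo.dihedral_idx),
                  topo.n_beads, topo.n_molecules)
        sched = PolymerizationSchedule(bonding_cutoff=0.9, bonds_per_relaxation=4,
                                       relax_steps=40, retry_steps=20,
                                       max_failed_attempts=2, seed=3)
        polymerization_run(state, topo, ff, sched, EnsembleSpec(temperature=298.0, pressure=1.0))
        after = (len(topo.bond_idx), len(topo.angle_idx), len(topo.dihedral_idx),
                 topo.n_beads, topo.n_molecules)
        assert before == after
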