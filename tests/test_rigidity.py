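"""Pebble-game decomposition, dilution, energy selection, labels, index."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flexsig.interactions import Interaction, Kind, find_all_interactions
from flexsig.rigidity import (AnalysisConfig, ConstraintNetwork,
                              DilutionProfile, DilutionStep,
                              RigidDecomposition, build_constraint_network,
                              compute_flexibility_index,
                              hydrogen_bond_dilution, label_residues,
                              run_pebble_game, select_energy_cutoff)
from flexsig.synthetic import make_bodybar_network, make_helix_peptide
from flexsig.experiments import RankOracle


def _hb(i, j, energy):
    return Interaction(i, j, Kind.HBOND, energy, donor=i, acceptor=j)


def _cov(i, j):
    return Interaction(i, j, Kind.COVALENT_ROTATABLE)


class TestConstraintNetwork:
    def test_cutoff_filters_weak_bonds(self):
        inter = [_cov(1, 2), _cov(2, 3), _hb(1, 3, -1.2), _hb(2, 4, -4.0),
                 _cov(3, 4)]
        net = build_constraint_network(inter, energy_cutoff=-2.0)
        assert (2, 4) in net.edges and (1, 3) not in net.edges

    def test_zero_cutoff_keeps_everything(self):
        inter = [_cov(1, 2), _hb(1, 3, -1.2), _cov(2, 3)]
        net = build_constraint_network(inter, 0.0)
        assert set(net.edges) == {(1, 2), (1, 3), (2, 3)}

    def test_covalent_only_independent_of_cutoff(self):
        inter = [_cov(1, 2), _cov(2, 3)]
        assert (build_constraint_network(inter, 0.0).edges
                == build_constraint_network(inter, -10.0).edges)

    def test_empty_interactions_rejected(self):
        with pytest.raises(ValueError):
            build_constraint_network([], 0.0)


class TestPebbleGame:
    def test_two_bodies_five_bars_one_floppy_mode(self):
        net = ConstraintNetwork(bodies=(1, 2), edges={(1, 2): 5})
        d = run_pebble_game(net)
        assert d.floppy_modes == 1
        assert len(d.clusters) == 2  # a dihedral remains: not mutually rigid

    def test_two_bodies_six_bars_locked(self):
        net = ConstraintNetwork(bodies=(1, 2), edges={(1, 2): 6})
        d = run_pebble_game(net)
        assert d.floppy_modes == 0
        assert len(d.clusters) == 1

    def test_six_body_ring_is_rigid(self):
        """36 DOF - 30 bars - 6 trivial = 0: the ring closes into one
        cluster (verified independently by the rank oracle)."""
        net = make_bodybar_network("ring", 6, bars=5)
        d = run_pebble_game(net)
        assert d.floppy_modes == 0
        assert len(d.clusters) == 1
        oracle = RankOracle(net, seed=3)
        assert oracle.floppy_modes() == 0
        assert oracle.pair_rigid(1, 4)

    def test_disconnected_components_counted_separately(self):
        net = ConstraintNetwork(bodies=(1, 2, 3, 4),
                                edges={(1, 2): 5, (3, 4): 6})
        assert run_pebble_game(net).floppy_modes == 1

    def test_determinism(self):
        net = make_bodybar_network("random", 10, seed=5)
        a, b = run_pebble_game(net), run_pebble_game(net)
        assert a.cluster_of == b.cluster_of
        assert a.floppy_modes == b.floppy_modes

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 10))
    def test_maxwell_bound(self, seed, n):
        """Independent bars never exceed the total: floppy modes are at
        least the global Maxwell count."""
        net = make_bodybar_network("random", n, seed=seed)
        d = run_pebble_game(net)
        assert d.floppy_modes >= 6 * len(net.bodies) - 6 - net.total_bars
        assert d.independent_bars <= net.total_bars

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_rank_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        net = make_bodybar_network("random", n, seed=seed)
        d = run_pebble_game(net)
        oracle = RankOracle(net, seed=seed + 1)
        assert d.floppy_modes == oracle.floppy_modes()


def _fake_profile(fractions, energies):
    steps = [DilutionStep(energy=e, removed_donor=None, removed_acceptor=None,
                          labels=("largest",), fraction_rigid=f,
                          floppy_modes=0, largest_cluster_residues=1)
             for f, e in zip(fractions, energies)]
    return DilutionProfile(steps=steps)


class TestEnergySelection:
    def test_most_negative_step_above_threshold(self):
        p = _fake_profile([0.95, 0.80, 0.72, 0.55], [-1.0, -2.0, -3.0, -4.0])
        assert select_energy_cutoff(p) == -3.0

    def test_all_above_threshold_takes_last(self):
        p = _fake_profile([0.95, 0.80, 0.75], [-1.0, -2.0, -3.0])
        assert select_energy_cutoff(p) == -3.0

    def test_none_above_threshold_falls_back_with_warning(self):
        p = _fake_profile([0.5, 0.4], [-1.0, -2.0])
        with pytest.warns(UserWarning):
            assert select_energy_cutoff(p) == -1.0

    def test_first_below_rule(self):
        p = _fake_profile([0.95, 0.72, 0.55], [-1.0, -2.0, -3.0])
        cfg = AnalysisConfig(cutoff_rule="first_below")
        assert select_energy_cutoff(p, cfg) == -3.0


class TestDilution:
    def test_removal_order_weakest_first(self, helix12):
        inter = find_all_interactions(helix12)
        profile = hydrogen_bond_dilution(helix12, inter)
        energies = profile.energies()
        assert all(b <= a + 1e-9 for a, b in zip(energies, energies[1:]))

    def test_floppy_modes_never_decrease(self, helix12):
        inter = find_all_interactions(helix12)
        profile = hydrogen_bond_dilution(helix12, inter)
        floppy = [s.floppy_modes for s in profile.steps]
        assert floppy == sorted(floppy)
        assert len(profile.steps) >= 2

    def test_rigid_pairs_shrink_monotonically(self):
        """Every pair of bodies rigid after a removal was rigid before."""
        helix = make_helix_peptide(8, with_hbonds=True, seed=4, jitter=0.03)
        inter = find_all_interactions(helix)
        from flexsig.rigidity import removal_order
        order = removal_order(inter)
        current = list(inter)
        prev = run_pebble_game(build_constraint_network(current, 0.0))
        for bond in order:
            current = [it for it in current if it is not bond]
            now = run_pebble_game(build_constraint_network(current, 0.0))
            for u, v in [(a, b) for a in now.bodies[:20]
                         for b in now.bodies[:20] if a < b]:
                if now.same_cluster(u, v) and len(
                        now.clusters[now.cluster_of[u]]) > 1:
                    assert prev.same_cluster(u, v)
            prev = now


class TestLabels:
    def _decomp_for(self, s, groups):
        """Build a decomposition by assigning each residue's atoms to the
        cluster id in ``groups`` (one per residue)."""
        cluster_of = {}
        members = {}
        for res, g in zip(s.residues, groups):
            for a in res.atoms:
                cluster_of[a.serial] = g
                members.setdefault(g, []).append(a.serial)
        clusters = {g: tuple(sorted(m)) for g, m in members.items()}
        return RigidDecomposition(
            bodies=tuple(sorted(cluster_of)), cluster_of=cluster_of,
            clusters=clusters, floppy_modes=0, independent_bars=0)

    def test_all_one_cluster_all_largest(self, helix12):
        d = self._decomp_for(helix12, [0] * 12)
        assert set(label_residues(d, helix12)) == {"largest"}

    def test_largest_separate_flexible_split(self, helix12):
        # 6 residues in cluster 0, 3 in cluster 1, 3 singleton clusters
        groups = [0] * 6 + [1] * 3 + [2, 3, 4]
        labels = label_residues(self._decomp_for(helix12, groups), helix12)
        assert labels[:6] == ["largest"] * 6
        assert labels[6:9] == ["separate"] * 3
        assert labels[9:] == ["flexible"] * 3

    def test_size_tie_broken_by_minimum_serial(self, helix12):
        groups = [0] * 6 + [1] * 6
        labels = label_residues(self._decomp_for(helix12, groups), helix12)
        assert labels[:6] == ["largest"] * 6
        assert labels[6:] == ["separate"] * 6


class TestFlexibilityIndex:
    def test_fully_rigid_network_scores_zero(self, helix12):
        inter = find_all_interactions(helix12)
        net = build_constraint_network(inter, 0.0)
        locked = {pair: 6 for pair in net.edges}
        net6 = ConstraintNetwork(bodies=net.bodies, edges=locked)
        d = run_pebble_game(net6)
        idx = compute_flexibility_index(d, net6, helix12)
        np.testing.assert_allclose(idx, 0.0)

    def test_free_chain_scores_hundred(self, strand12):
        """With every rotatable bond independent (a tree), each region's
        floppy modes equal its rotatable-bond count."""
        from flexsig.interactions import find_covalent_bonds
        inter = find_covalent_bonds(strand12)
        net = build_constraint_network(inter, 0.0)
        d = run_pebble_game(net)
        idx = compute_flexibility_index(d, net, strand12)
        np.testing.assert_allclose(idx, 100.0)

    def test_mixed_structure_matches_region_rank_oracle(self):
        helix = make_helix_peptide(10, with_hbonds=True, seed=9, jitter=0.02)
        inter = find_all_interactions(helix)
        # keep only the strongest half of the hydrogen bonds: part rigid,
        # part flexible
        from flexsig.rigidity import removal_order
        order = removal_order(inter)
        drop = set(id(b) for b in order[:len(order) // 2])
        kept = [it for it in inter if id(it) not in drop]
        net = build_constraint_network(kept, 0.0)
        d = run_pebble_game(net)
        idx = compute_flexibility_index(d, net, helix)
        assert idx.min() >= 0.0 and idx.max() <= 100.0
        assert idx.max() > 0.0  # partially diluted: some flexibility


def test_full_pipeline_on_helix_selects_energy(helix12):
    from flexsig.pipeline import analyze_rigidity
    analysis = analyze_rigidity(helix12)
    assert analysis.energy_cutoff <= 0.0
    assert len(analysis.residue_labels) == 12
    fr = sum(l != "flexible" for l in analysis.residue_labels) / 12
    assert fr >= 0.70  # the selected energy keeps the helix mostly rigid
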