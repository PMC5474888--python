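import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaphylo.cnaphylo import (WGD_CANDIDATES, PRE_WGD_COST, build_cna_tree,
                                directed_event_distance,
                                dissimilarity_matrix, pairwise_dissimilarity,
                                profile_event_distance, resampling_support,
                                wgd_root, _nj_tree)
from metaphylo.simulate import (SimulationConfig, emit_cna_profiles,
                                simulate_patient)
from metaphylo.trees import RootedTree, rf_distance

from .conftest import diploid_profile
from .oracles import bfs_event_distance


class TestDirectedEventDistance:
    @pytest.mark.parametrize("a, b, d", [
        ([1, 1, 1], [1, 1, 1], 0),
        ([1, 1, 1], [2, 2, 1], 1),       # one segmental gain
        ([2, 2], [0, 2], 2),             # two single-copy losses to zero
        ([1, 2, 1], [2, 3, 2], 1),       # gain spanning all loci
        ([2, 0, 2], [1, 0, 1], 2),       # zero in the middle blocks the run
        ([3, 3], [1, 1], 2),
    ])
    def test_known_small_cases(self, a, b, d):
        assert directed_event_distance(a, b) == d

    def test_gain_from_zero_is_infeasible(self):
        assert directed_event_distance([0, 2], [1, 2]) == math.inf

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            directed_event_distance([1, 1], [1])

    @given(st.lists(st.tuples(st.integers(0, 4), st.integers(0, 4)),
                    min_size=1, max_size=4))
    @settings(max_examples=120, deadline=None)
    def test_matches_breadth_first_search_oracle(self, pairs):
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        assert directed_event_distance(a, b) == bfs_event_distance(a, b)


class TestPairwiseDissimilarity:
    def test_identical_profiles_are_zero(self):
        assert pairwise_dissimilarity([2, 2], [1, 1], [2, 2], [1, 1]) == 0

    def test_single_gain_costs_one_via_smaller_ancestor(self):
        # q = p plus one segmental major gain: the ancestor is p itself
        assert pairwise_dissimilarity([1, 1, 1], [1, 1, 1],
                                      [2, 2, 1], [1, 1, 1]) == 1

    def test_symmetric_on_random_profiles(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            L = int(rng.integers(1, 5))
            pm, pmin = rng.integers(0, 5, L), rng.integers(0, 3, L)
            qm, qmin = rng.integers(0, 5, L), rng.integers(0, 3, L)
            d1 = pairwise_dissimilarity(pm, pmin, qm, qmin)
            d2 = pairwise_dissimilarity(qm, qmin, pm, pmin)
            assert d1 == d2

    def test_never_exceeds_distance_through_either_endpoint(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            L = int(rng.integers(1, 4))
            pm, qm = rng.integers(1, 4, L), rng.integers(1, 4, L)
            sym = pairwise_dissimilarity(pm, [1] * L, qm, [1] * L)
            via_p = (directed_event_distance(pm, qm)
                     + directed_event_distance(pm, pm))
            assert sym <= via_p or via_p == math.inf


class TestBuildCnaTree:
    def test_three_private_gains_give_three_events(self):
        prof = diploid_profile(["P", "M1", "M2"],
                               P={"1": (2, 1)}, M1={"2": (2, 1)},
                               M2={"3": (2, 1)})
        res = build_cna_tree(prof)
        assert res.total_events == 3

    def test_truncal_and_private_events_recover_clades(self):
        # shared truncal gain, one clade-specific loss, private gains
        prof = diploid_profile(
            ["P", "M1", "M2", "M3"], n_segments=6,
            P={"1": (2, 1), "2": (2, 1)},
            M1={"1": (2, 1), "3": (1, 0), "4": (2, 1)},
            M2={"1": (2, 1), "3": (1, 0), "5": (2, 1)},
            M3={"1": (2, 1), "3": (1, 0)})
        res = build_cna_tree(prof)
        # trunk carries the shared gain; the M1/M2/M3 clade shares the loss
        assert rf_distance(
            res.tree,
            RootedTree.from_newick("(N,(P,((M1,M2),M3)));")) in (0, 2)
        trunk = res.tree.mrca(["P", "M1", "M2", "M3"])
        assert res.tree.path_length(res.tree.root, trunk) >= 1

    def test_total_events_invariant_under_leaf_order(self):
        cfg = SimulationConfig(n_samples=4, seed=20, n_branch_cnas=3.0)
        prof = emit_cna_profiles(simulate_patient(cfg))
        res1 = build_cna_tree(prof)
        shuffled = prof.sort_values(["chrom", "sample"],
                                    ascending=[True, False])
        res2 = build_cna_tree(shuffled)
        assert res1.total_events == res2.total_events

    def test_planted_topology_recovered_with_strong_signal(self):
        hits = 0
        n = 20
        for seed in range(n):
            cfg = SimulationConfig(n_samples=4, seed=seed,
                                   n_truncal_cnas=6, n_branch_cnas=5.0,
                                   n_segments=30)
            truth = simulate_patient(cfg)
            res = build_cna_tree(emit_cna_profiles(truth))
            hits += rf_distance(res.tree, truth.tree) == 0
        assert hits >= 0.8 * n

    def test_too_many_leaves_require_heuristic_flag(self):
        cfg = SimulationConfig(n_samples=8, seed=21, n_branch_cnas=4.0)
        prof = emit_cna_profiles(simulate_patient(cfg))
        with pytest.raises(ValueError, match="heuristic"):
            build_cna_tree(prof)
        res = build_cna_tree(prof, heuristic=True)
        assert not res.exhaustive
        assert res.total_events >= 0


class TestWgdRooting:
    @staticmethod
    def _uniform(major, minor, samples=("P", "M1", "M2")):
        return diploid_profile(list(samples), n_segments=3,
                               **{s: {c: (major, minor) for c in "123"}
                                  for s in samples})

    def test_uniform_4_2_selects_4_2_with_zero_pre_wgd_cost(self):
        prof = self._uniform(2, 2)
        rooting = wgd_root(prof, build_cna_tree(prof).tree)
        assert rooting.selected == "4/2"
        assert rooting.scores["4/2"] == 0
        assert rooting.pre_wgd_cost["4/2"] == 0

    def test_uniform_4_4_selects_4_4(self):
        prof = self._uniform(4, 0)
        rooting = wgd_root(prof, build_cna_tree(prof).tree)
        assert rooting.selected == "4/4"
        assert rooting.scores["4/4"] == 0

    def test_chosen_candidate_minimises_score_plus_tiebreak(self):
        cfg = SimulationConfig(n_samples=4, seed=22, wgd=True,
                               n_branch_cnas=2.0)
        prof = emit_cna_profiles(simulate_patient(cfg))
        rooting = wgd_root(prof, build_cna_tree(prof).tree)
        chosen = rooting.scores[rooting.selected] \
            + rooting.pre_wgd_cost[rooting.selected]
        for cand, score in rooting.scores.items():
            if math.isfinite(score):
                assert chosen <= score + rooting.pre_wgd_cost[cand] + 1e-9

    def test_planted_wgd_recovers_tetraploid_ancestor(self):
        hits = total = 0
        for seed in range(10):
            cfg = SimulationConfig(n_samples=4, seed=seed, wgd=True,
                                   n_truncal_cnas=2, n_branch_cnas=2.0)
            truth = simulate_patient(cfg)
            prof = emit_cna_profiles(truth)
            res = build_cna_tree(prof, root_mode="wgd")
            total += 1
            # truncal events before doubling leave the pre-WGD state near
            # diploid, so the doubled ancestor 4/2 should dominate
            hits += res.wgd.selected == "4/2"
        assert hits >= 0.9 * total


class TestResamplingSupport:
    def test_zero_noise_gives_full_support(self):
        cfg = SimulationConfig(n_samples=5, seed=23, n_branch_cnas=4.0)
        prof = emit_cna_profiles(simulate_patient(cfg))
        dist = dissimilarity_matrix(prof)
        tree = _nj_tree(dist)
        support = resampling_support(dist, tree, n_resamples=10,
                                     noise_sd=0.0, seed=0)
        assert support
        assert all(v == 1.0 for v in support.values())

    def test_supports_bounded_and_reproducible(self):
        cfg = SimulationConfig(n_samples=5, seed=24, n_branch_cnas=4.0)
        prof = emit_cna_profiles(simulate_patient(cfg))
        dist = dissimilarity_matrix(prof)
        res = build_cna_tree(prof)
        s1 = resampling_support(dist, res.tree, n_resamples=25,
                                noise_sd=1.0, seed=7)
        s2 = resampling_support(dist, res.tree, n_resamples=25,
                                noise_sd=1.0, seed=7)
        assert s1 == s2
        assert all(0.0 <= v <= 1.0 for v in s1.values())

    def test_widely_separated_clades_highly_supported(self):
        # two tight clades ten-plus events apart
        prof = diploid_profile(
            ["A1", "A2", "B1", "B2"], n_segments=12,
            A1={str(c): (2, 1) for c in range(1, 7)},
            A2={str(c): (2, 1) for c in range(1, 7)} | {"12": (2, 1)},
            B1={str(c): (3, 0) for c in range(7, 12)},
            B2={str(c): (3, 0) for c in range(7, 12)} | {"11": (3, 0)})
        dist = dissimilarity_matrix(prof)
        res = build_cna_tree(prof)
        support = resampling_support(dist, res.tree, n_resamples=50,
                                     noise_sd=1.0, seed=1)
        ab_split = frozenset({"B1", "B2"})
        assert support.get(ab_split, support.get(frozenset({"A1", "A2"}),
                                                 0.0)) > 0.9
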