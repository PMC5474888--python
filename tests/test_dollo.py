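import numpy as np
import pandas as pd
import pytest

from metaphylo.dollo import (acctran_reconstruct, break_ties_with_cna,
                             dollo_score, dollo_search, verify_reversions)
from metaphylo.simulate import (SimulationConfig, emit_cna_profiles,
                                emit_read_counts, simulate_patient)
from metaphylo.tiers import CharacterMatrix, apply_tier3_filters
from metaphylo.trees import RootedTree, rf_distance

from .oracles import dollo_brute_force, dollo_tree_score


def _matrix(data, samples, snvs):
    return CharacterMatrix(pd.DataFrame(data, index=samples, columns=snvs,
                                        dtype=float))


class TestDolloSearch:
    def test_perfectly_nested_matrix_has_unique_zero_loss_tree(self):
        # characters nested like clades: no homoplasy, no losses
        m = _matrix([[1, 1, 0, 0],
                     [1, 1, 1, 0],
                     [1, 0, 0, 1],
                     [1, 0, 0, 1]],
                    ["A", "B", "C", "D"], ["trunk", "ab", "b", "cd"])
        res = dollo_search(m)
        assert res.score == 0
        assert len(res.trees) == 1
        best = res.trees[0]
        assert rf_distance(
            best, RootedTree.from_newick("(N,((A,B),(C,D)));")) == 0

    def test_reversion_pattern_places_loss_on_nested_sample(self):
        # SNVs shared by P and M3 but missing from M2, which the rest of
        # the data nests inside the P/M3 clade: the best tree keeps M2
        # nested and explains the absences as losses on the M2 branch
        snvs = {
            "trunk1": [1, 1, 1], "trunk2": [1, 1, 1], "trunk3": [1, 1, 1],
            "rev1": [1, 0, 1], "rev2": [1, 0, 1],
            "m2_m3_a": [0, 1, 1], "m2_m3_b": [0, 1, 1], "m2_m3_c": [0, 1, 1],
            "m2_m3_d": [0, 1, 1], "m2_m3_e": [0, 1, 1], "m2_m3_f": [0, 1, 1],
            "p_priv": [1, 0, 0],
        }
        m = CharacterMatrix(pd.DataFrame(snvs, index=["P", "M2", "M3"],
                                         dtype=float))
        res = dollo_search(m)
        best = res.trees[0]
        assert rf_distance(best,
                           RootedTree.from_newick("(N,(P,(M2,M3)));")) == 0
        rec = acctran_reconstruct(best, m)
        assert rec.loss_branches["rev1"] == ["M2"]
        assert rec.loss_branches["rev2"] == ["M2"]

    @pytest.mark.parametrize("n_leaves", [4, 5])
    def test_score_matches_independent_brute_force(self, n_leaves):
        rng = np.random.default_rng(123)
        labels = [f"S{i}" for i in range(n_leaves)]
        for _ in range(20):
            data = rng.integers(0, 2, size=(n_leaves, 7))
            m = _matrix(data, labels, [f"v{j}" for j in range(7)])
            res = dollo_search(m)
            chars = [({labels[i] for i in range(n_leaves) if data[i, j]},
                      {labels[i] for i in range(n_leaves) if not data[i, j]})
                     for j in range(7)]
            assert res.score == dollo_brute_force(list(range(n_leaves)), [
                ({i for i in range(n_leaves) if data[i, j]},
                 {i for i in range(n_leaves) if not data[i, j]})
                for j in range(7)])

    def test_missing_cells_do_not_force_losses(self):
        m = _matrix([[1, 1], [np.nan, 1], [0, 1]],
                    ["A", "B", "C"], ["v", "trunk"])
        res = dollo_search(m)
        assert res.score == 0  # B missing for v is uninformative

    def test_refuses_untractable_size_without_heuristic_flag(self):
        labels = [f"S{i}" for i in range(10)]
        m = _matrix(np.ones((10, 3)), labels, ["a", "b", "c"])
        with pytest.raises(ValueError, match="heuristic"):
            dollo_search(m)
        res = dollo_search(m, heuristic=True)
        assert not res.exhaustive
        assert res.score == 0

    def test_search_never_beats_rescoring_of_truth(self, reversion_patient):
        _, truth, counts = reversion_patient
        m = apply_tier3_filters(counts)
        res = dollo_search(m)
        assert res.score <= dollo_score(truth.tree, m)


class TestTieBreaking:
    def test_single_tree_returned_unchanged(self):
        t = RootedTree.from_newick("(N,((A,B),C));")
        assert break_ties_with_cna([t], t) is t

    def test_tree_matching_cna_topology_wins(self):
        t1 = RootedTree.from_newick("(N,((A,B),(C,D)));")
        t2 = RootedTree.from_newick("(N,((A,C),(B,D)));")
        cna = RootedTree.from_newick("(N,((A,C),(B,D)));")
        assert break_ties_with_cna([t1, t2], cna) is t2

    def test_disjoint_leaf_sets_rejected(self):
        t = RootedTree.from_newick("(N,((A,B),C));")
        cna = RootedTree.from_newick("(N,((X,Y),Z));")
        with pytest.raises(ValueError, match="no leaves"):
            break_ties_with_cna([t, t.copy()], cna)

    def test_residual_tie_broken_deterministically(self):
        t1 = RootedTree.from_newick("(N,((A,B),(C,D)));")
        t2 = RootedTree.from_newick("(N,((A,C),(B,D)));")
        cna = RootedTree.from_newick("(N,(A,(B,(C,D))));")
        first = break_ties_with_cna([t1, t2], cna)
        second = break_ties_with_cna([t2, t1], cna)
        assert first.to_newick() == second.to_newick()


class TestAcctran:
    def test_truncal_character_gains_on_trunk_without_losses(self):
        m = _matrix([[1], [1], [1]], ["A", "B", "C"], ["t"])
        tree = RootedTree.from_newick("(N,((A,B),C));")
        rec = acctran_reconstruct(tree, m)
        trunk = rec.tree.mrca(["A", "B", "C"]).name
        assert rec.gain_branch["t"] == trunk
        assert rec.loss_branches["t"] == []

    def test_private_character_gains_on_terminal_branch(self):
        m = _matrix([[1], [0], [0]], ["A", "B", "C"], ["p"])
        tree = RootedTree.from_newick("(N,((A,B),C));")
        rec = acctran_reconstruct(tree, m)
        assert rec.gain_branch["p"] == "A"
        assert rec.loss_branches["p"] == []

    def test_all_absent_character_excluded_with_warning(self):
        m = _matrix([[0, 1], [0, 1], [0, 1]], ["A", "B", "C"], ["dead", "t"])
        tree = RootedTree.from_newick("(N,((A,B),C));")
        with pytest.warns(UserWarning, match="absent everywhere"):
            rec = acctran_reconstruct(tree, m)
        assert "dead" not in rec.gain_branch

    def test_branch_lengths_equal_assigned_events(self):
        m = _matrix([[1, 1, 0], [1, 0, 0], [0, 0, 1]],
                    ["A", "B", "C"], ["ab", "a", "c"])
        tree = RootedTree.from_newick("(N,((A,B),C));")
        rec = acctran_reconstruct(tree, m)
        total = sum(n.length for n in rec.tree.postorder()
                    if n.length is not None)
        gains = len(rec.gain_branch)
        losses = sum(len(v) for v in rec.loss_branches.values())
        assert total == gains + losses

    def test_reconstruction_score_matches_search_score(self, reversion_patient):
        _, _, counts = reversion_patient
        m = apply_tier3_filters(counts)
        res = dollo_search(m)
        rec = acctran_reconstruct(res.trees[0], m)
        assert rec.score == res.score

    def test_gains_match_planted_branches_without_homoplasy(self,
                                                            clean_patient):
        cfg, truth, counts = clean_patient
        m = apply_tier3_filters(counts)
        res = dollo_search(m)
        best = min(res.trees, key=lambda t: rf_distance(t, truth.tree))
        assert rf_distance(best, truth.tree) == 0
        rec = acctran_reconstruct(best, m)
        # name internal nodes of the truth tree by their leaf sets
        def clades(tree):
            out = {}
            for node in tree.postorder():
                if node.name == "N" or node.parent is None:
                    continue
                leaves = frozenset(
                    l.name for l in tree.postorder()
                    if l.is_leaf and _is_descendant(l, node))
                out[node.name] = leaves
            return out

        def _is_descendant(leaf, node):
            x = leaf
            while x is not None:
                if x is node:
                    return True
                x = x.parent
            return False

        truth_clades = clades(truth.tree)
        rec_clades = clades(rec.tree)
        matched = 0
        for snv, branch in rec.gain_branch.items():
            planted = truth.snv_gain_branch[snv]
            if truth.snv_loss_branches[snv]:
                continue  # reversions move the apparent gain point
            if truth.multiplicity.loc[:, snv].gt(0).sum() == 0:
                continue
            if rec_clades[branch] == truth_clades[planted]:
                matched += 1
        informative = [s for s in rec.gain_branch
                       if not truth.snv_loss_branches[s]]
        # natural copy losses can still delete the odd mutation; demand
        # near-perfect agreement rather than literal totality
        assert matched >= 0.95 * len(informative)


class TestReversionVerification:
    def test_unchanged_copy_state_reported_unexplained(self):
        m = _matrix([[1, 1, 1], [0, 1, 1], [1, 1, 1], [1, 0, 0]],
                    ["A", "B", "C", "D"],
                    ["rev", "bc", "d_absent"])
        tree = RootedTree.from_newick("(N,(((A,B),C),D));")
        rec = acctran_reconstruct(tree, m)
        assert rec.loss_branches["rev"] == ["B"]
        profiles = pd.concat([
            pd.DataFrame(dict(sample=s, chrom=["1"], start=[1], end=[1000],
                              total=[2], major=[1], minor=[1]))
            for s in ["A", "B", "C", "D"]])
        depths = pd.DataFrame(5000, index=["A", "B", "C", "D"],
                              columns=["rev", "bc", "d_absent"])
        calls = verify_reversions(
            rec, profiles,
            pd.DataFrame(dict(snv_id=["rev"], chrom=["1"], pos=[500])),
            depths, {s: 1.0 for s in "ABCD"})
        rev = [c for c in calls if c.snv == "rev"][0]
        assert rev.status == "unexplained"

    def test_low_power_absence_flagged_not_asserted(self):
        m = _matrix([[1, 1], [0, 1], [1, 1]], ["A", "B", "C"], ["rev", "t"])
        tree = RootedTree.from_newick("(N,((A,B),C));")
        rec = acctran_reconstruct(tree, m)
        profiles = pd.concat([
            pd.DataFrame(dict(sample=s, chrom=["1"], start=[1], end=[1000],
                              total=[2], major=[1], minor=[1]))
            for s in ["A", "B", "C"]])
        depths = pd.DataFrame([[5000, 5000], [40, 5000], [5000, 5000]],
                              index=["A", "B", "C"], columns=["rev", "t"])
        calls = verify_reversions(
            rec, profiles,
            pd.DataFrame(dict(snv_id=["rev"], chrom=["1"], pos=[500])),
            depths, {"A": 1.0, "B": 0.1, "C": 1.0})
        rev = [c for c in calls if c.snv == "rev"][0]
        assert rev.status == "possible_false_negative"

    def test_planted_loh_annotated_with_overlapping_loss(self,
                                                         reversion_patient):
        cfg, truth, counts = reversion_patient
        m = apply_tier3_filters(counts)
        res = dollo_search(m)
        rec = acctran_reconstruct(res.trees[0], m)
        counts = counts.assign(depth=counts.ref_reads + counts.alt_reads)
        depths = counts.pivot_table(index="sample", columns="snv_id",
                                    values="depth", aggfunc="first")
        calls = verify_reversions(rec, emit_cna_profiles(truth),
                                  truth.snv_meta[["snv_id", "chrom", "pos"]],
                                  depths, truth.sample_ccf)
        planted = {k: v[0] for k, v in truth.snv_loss_branches.items() if v}
        assert planted
        by_snv = {c.snv: c for c in calls}
        for snv, branch in planted.items():
            assert snv in by_snv
            assert by_snv[snv].status == "supported"
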