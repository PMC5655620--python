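"""Cluster matching, stayer/mover classification, co-mover collection
and same-profile detection."""

import numpy as np
import pytest

from coreorg.community_detection import GenePartition
from coreorg.io_formats import ExpressionMatrix, FocalGeneList
from coreorg.reorganization import (NEW, classify_genes, comovers,
                                    compare_conditions, match_clusters,
                                    same_profile_pairs)


def partition(clusters, isolated=(), singletons=(), label=""):
    assignment = {g: cid for cid, members in enumerate(clusters) for g in members}
    return GenePartition(assignment, frozenset(isolated), frozenset(singletons),
                         label)


class TestMatchClusters:
    def test_worked_jaccard_example(self):
        before = partition([{"a", "b", "c", "d"}, {"e", "f", "g"}])
        after = partition([{"a", "b", "c"}, {"d", "e", "f", "g"}])
        m = match_clusters(before, after, j_min=0.0)
        assert m.mapping == {0: 0, 1: 1}
        assert m.jaccard[0] == pytest.approx(0.75)   # 3 / 4
        assert m.jaccard[1] == pytest.approx(0.75)   # |{d,e,f,g} & {e,f,g}| = 3, union 4

    def test_identity_partitions(self):
        p = partition([{"a", "b"}, {"c", "d", "e"}])
        m = match_clusters(p, p, j_min=0.0)
        assert m.mapping == {0: 0, 1: 1}
        assert all(j == pytest.approx(1.0) for j in m.jaccard.values())

    def test_leftover_cluster_maps_new(self):
        # after-cluster {x,y} draws one gene from each of two before-
        # clusters that both matched better elsewhere.
        before = partition([{"a", "b", "c", "x"}, {"d", "e", "f", "y"}])
        after = partition([{"a", "b", "c"}, {"d", "e", "f"}, {"x", "y"}])
        m = match_clusters(before, after, j_min=0.0)
        assert m.mapping == {0: 0, 1: 1, 2: NEW}

    def test_j_min_gates_weak_matches(self):
        before = partition([{"a", "b", "c", "d", "e", "f", "g", "h"}])
        after = partition([{"a", "b"}], singletons=set("cdefgh"))
        # J({a,b}, before) = 2/8 = 0.25 < j_min=0.3 -> NEW
        m = match_clusters(before, after, j_min=0.3)
        assert m.mapping[0] == NEW
        m2 = match_clusters(before, after, j_min=0.25)
        assert m2.mapping[0] == 0


class TestClassifyGenes:
    def test_worked_example(self):
        before = partition([{"a", "b", "c", "d"}, {"e", "f", "g"}])
        after = partition([{"a", "b", "c"}, {"d", "e", "f", "g"}])
        m = match_clusters(before, after, j_min=0.0)
        stayers, movers = classify_genes(before, after, m)
        assert movers == frozenset({"d"})
        assert stayers == frozenset({"a", "b", "c", "e", "f", "g"})

    def test_identity_partitions_no_movers(self):
        p = partition([{"a", "b"}, {"c", "d"}], isolated={"e"})
        m = match_clusters(p, p, j_min=0.0)
        stayers, movers = classify_genes(p, p, m)
        assert movers == frozenset()
        assert stayers == frozenset("abcde")

    def test_status_class_changes_are_moves(self):
        before = partition([{"a", "b"}], isolated={"c"}, singletons={"d"})
        after = partition([{"a", "b"}], isolated={"d"}, singletons={"c"})
        m = match_clusters(before, after, j_min=0.0)
        stayers, movers = classify_genes(before, after, m)
        assert movers == frozenset({"c", "d"})  # swapped pseudo-classes
        assert stayers == frozenset({"a", "b"})

    def test_partitions_cover_universe(self):
        before = partition([{"a", "b", "c"}, {"d", "e"}], isolated={"f"})
        after = partition([{"a", "b"}, {"c", "d", "e"}], isolated={"f"})
        m = match_clusters(before, after, j_min=0.0)
        stayers, movers = classify_genes(before, after, m)
        assert stayers | movers == before.genes
        assert stayers & movers == frozenset()


class TestComovers:
    def _pair(self):
        # f, g1, g2 move together C0 -> (matched C1 cluster); g3 stays in
        # C0's match; g4/k1/k2 are in the after-cluster from other sources.
        before = partition([{"f", "g1", "g2", "g3", "h1", "h2"},
                            {"g4", "k1", "k2"}])
        after = partition([{"g3", "h1", "h2"},
                           {"f", "g1", "g2", "g4", "k1", "k2"}])
        m = match_clusters(before, after, j_min=0.0)
        assert m.mapping == {0: 0, 1: 1}
        return before, after, m

    def test_comovers_and_joiners(self):
        before, after, m = self._pair()
        co, join = comovers(before, after, m, FocalGeneList(("f",)))
        assert co["f"] == frozenset({"g1", "g2"})
        assert join["f"] == frozenset({"g4", "k1", "k2"})

    def test_focal_stayer_empty(self):
        before, after, m = self._pair()
        co, _ = comovers(before, after, m, FocalGeneList(("g3",)))
        assert co["g3"] == frozenset()

    def test_two_focal_movers_are_mutual(self):
        before, after, m = self._pair()
        co, _ = comovers(before, after, m, FocalGeneList(("f", "g1")))
        assert "g1" in co["f"] and "f" in co["g1"]

    def test_absent_focal_skipped(self, caplog):
        before, after, m = self._pair()
        with caplog.at_level("WARNING"):
            co, _ = comovers(before, after, m, FocalGeneList(("nope", "f")))
        assert "nope" not in co and "f" in co

    def test_comovers_subset_of_movers(self):
        before, after, m = self._pair()
        _, movers = classify_genes(before, after, m)
        co, _ = comovers(before, after, m, FocalGeneList(("f",)))
        assert co["f"] <= movers


class TestSameProfilePairs:
    def _em(self, rows):
        tags = list(rows)
        return ExpressionMatrix(tags, [f"s{j}" for j in range(len(next(iter(rows.values()))))],
                                np.array([rows[t] for t in tags], dtype=float))

    def test_affine_copy_detected(self):
        a = np.array([1.0, 2.0, 4.0, 3.0])
        em = self._em({"a": a, "b": 2 * a + 3, "c": a + np.array([0, 0, 1, 0])})
        pairs = same_profile_pairs(em, ["a", "b", "c"], epsilon=1e-9)
        assert pairs == frozenset({("a", "b")})

    def test_anticorrelated_not_detected(self):
        a = np.array([1.0, 2.0, 4.0, 3.0])
        em = self._em({"a": a, "b": -a})
        assert same_profile_pairs(em, ["a", "b"], epsilon=1e-6) == frozenset()

    def test_transitive_at_zero_epsilon(self):
        a = np.array([0.0, 1.0, 5.0, 2.0])
        em = self._em({"a": a, "b": 3 * a - 1, "c": 0.5 * a + 7, "d": a[::-1]})
        pairs = same_profile_pairs(em, ["a", "b", "c", "d"], epsilon=1e-12)
        assert pairs == frozenset({("a", "b"), ("a", "c"), ("b", "c")})

    def test_zero_variance_excluded(self, caplog):
        em = self._em({"a": [1.0, 2, 3], "flat": [5.0, 5, 5]})
        with caplog.at_level("WARNING"):
            pairs = same_profile_pairs(em, ["a", "flat"])
        assert pairs == frozenset()
        assert any("flat" in r.message for r in caplog.records)


class TestEndToEndRecovery:
    def test_planted_movers_and_comovers_recovered(self):
        import coreorg as co
        from coreorg.synthetic_data import MoverSet, SyntheticSpec, generate

        spec = SyntheticSpec(
            n_genes=95, n_samples=20, module_sizes=(30, 30, 30), n_isolated=5,
            within_module_corr=0.9,
            movers=(MoverSet(tuple(range(10)), 0, 1),),
            focal_assignment={"PA0153": 0, "PA1966": 5}, seed=42)
        before, after, truth = generate(spec)
        pb = co.detect_communities(co.build_network(before, 0.8))
        pa = co.detect_communities(co.build_network(after, 0.8))
        report = compare_conditions(pb, pa, FocalGeneList(("PA0153", "PA1966")),
                                    em_after=after, j_min=0.25)
        assert report.movers == truth.true_movers
        for f in ("PA0153", "PA1966"):
            assert report.comovers[f] == truth.true_comovers[f]
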