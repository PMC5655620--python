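"""Category cross-tabulation, aggregation, list intersection and
cluster-composition percentages."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coreorg.category_analysis import (CategoryMatrix, aggregate,
                                       categorize_comovers, composition,
                                       intersect_lists)
from coreorg.community_detection import GenePartition
from coreorg.errors import ValidationError, VocabularyMismatchError
from coreorg.io_formats import UNCLASSIFIED, GeneAnnotation
from coreorg.reorganization import ClusterMatch, ReorganizationReport


def report_with(comovers, label="pair"):
    return ReorganizationReport(
        match=ClusterMatch({}, {}, 0.25),
        stayers=frozenset(), movers=frozenset().union(*comovers.values(), frozenset()),
        comovers=comovers, joiners={f: frozenset() for f in comovers},
        same_profile_pairs=frozenset(), condition_pair_label=label,
    )


def ann_table(mapping):
    return {tag: GeneAnnotation(tag, cat) for tag, cat in mapping.items()}


class TestCategorizeComovers:
    def test_counts_by_hand(self):
        rep = report_with({"f": frozenset({"g1", "g2", "g3"})})
        ann = ann_table({"g1": "catA", "g2": "catA", "g3": "catB"})
        cm = categorize_comovers(rep, ann)
        assert cm.data.loc["catA", "f"] == 2
        assert cm.data.loc["catB", "f"] == 1

    def test_empty_report_all_zero(self):
        rep = report_with({"f": frozenset(), "g": frozenset()})
        cm = categorize_comovers(rep, ann_table({"x": "catA"}))
        assert (cm.data.to_numpy() == 0).all()
        assert cm.focal_tags == ["f", "g"]

    def test_unannotated_counted_unclassified(self):
        rep = report_with({"f": frozenset({"mystery"})})
        cm = categorize_comovers(rep, ann_table({"other": "catA"}))
        assert cm.data.loc[UNCLASSIFIED, "f"] == 1

    def test_column_sums_equal_comover_sizes(self, rng):
        genes = [f"g{i}" for i in range(40)]
        cats = ["c1", "c2", "c3"]
        ann = ann_table({g: cats[i % 3] for i, g in enumerate(genes[:30])})
        comov = {
            f"f{k}": frozenset(rng.choice(genes, size=rng.integers(0, 15),
                                          replace=False))
            for k in range(5)
        }
        cm = categorize_comovers(report_with(comov), ann)
        for f, members in comov.items():
            assert cm.data[f].sum() == len(members)

    def test_joiner_source_flag(self):
        rep = ReorganizationReport(
            ClusterMatch({}, {}, 0.25), frozenset(), frozenset(),
            comovers={"f": frozenset({"a"})}, joiners={"f": frozenset({"b", "c"})},
            same_profile_pairs=frozenset(), condition_pair_label="x")
        ann = ann_table({"a": "catA", "b": "catB", "c": "catB"})
        assert categorize_comovers(rep, ann, source="joiners").data.loc["catB", "f"] == 2
        with pytest.raises(ValidationError, match="source"):
            categorize_comovers(rep, ann, source="both")


class TestAggregate:
    def _cm(self, cells, scope="s"):
        return CategoryMatrix(pd.DataFrame(cells), scope)

    def test_doubling(self):
        cm = self._cm({"f1": {"catA": 1, "catB": 2}})
        agg = aggregate([cm, cm])
        assert (agg.data == 2 * cm.data).all().all()

    def test_single_matrix_identity(self):
        cm = self._cm({"f1": {"catA": 1, "catB": 0}})
        assert aggregate([cm]).data.equals(cm.data)

    def test_three_matrices_hand_sum(self):
        m1 = self._cm({"f1": {"catA": 1, "catB": 0}})
        m2 = self._cm({"f1": {"catA": 2, "catB": 5}})
        m3 = self._cm({"f2": {"catA": 3, "catB": 1}})
        agg = aggregate([m1, m2, m3])
        assert agg.data.loc["catA", "f1"] == 3
        assert agg.data.loc["catB", "f1"] == 5
        assert agg.data.loc["catA", "f2"] == 3
        assert agg.data.loc["catB", "f2"] == 1

    def test_associative_commutative(self, rng):
        mats = [self._cm(pd.DataFrame(
            rng.integers(0, 5, size=(3, 2)),
            index=["c1", "c2", "c3"], columns=["f1", "f2"]))
            for _ in range(3)]
        a = aggregate([aggregate(mats[:2]), mats[2]])
        b = aggregate([mats[2], mats[1], mats[0]])
        assert a.data.loc[b.data.index, b.data.columns].equals(b.data)

    def test_vocabulary_mismatch_lists_labels(self):
        m1 = self._cm({"f1": {"catA": 1}})
        m2 = self._cm({"f1": {"catZ": 1}})
        with pytest.raises(VocabularyMismatchError, match="catZ"):
            aggregate([m1, m2])


class TestIntersectLists:
    def test_basic_overlap(self):
        rep = report_with({"f": frozenset({"a", "b", "c"})})
        table = intersect_lists(rep, {"up": {"b", "c", "d"}})
        assert table.counts.loc["f", "up"] == 2
        assert table.sets[("f", "up")] == frozenset({"b", "c"})

    def test_disjoint_flags_independent(self):
        rep = report_with({"f": frozenset({"a"}), "g": frozenset({"b"})})
        table = intersect_lists(rep, {"up": {"z"}, "down": {"b"}})
        assert table.independent == frozenset({"f"})

    def test_empty_list_all_zero(self):
        rep = report_with({"f": frozenset({"a", "b"})})
        table = intersect_lists(rep, {"up": set()})
        assert table.counts["up"].sum() == 0


class TestComposition:
    def test_worked_example(self):
        target = GenePartition({"a": 0, "b": 0, "c": 0, "d": 0},
                               frozenset(), frozenset())
        source = GenePartition({"a": 0, "b": 0, "c": 1, "z": 1},
                               frozenset({"d"}), frozenset())
        table = composition(source, target, top_k=1)
        assert table.percentages[0] == {"0": 50.0, "1": 25.0, "ISOLATED": 25.0}

    def test_cluster_wholly_from_one_source(self):
        target = GenePartition({"a": 0, "b": 0}, frozenset(), frozenset())
        source = GenePartition({"a": 0, "b": 0, "c": 1, "d": 1},
                               frozenset(), frozenset())
        assert composition(source, target, 1).percentages[0] == {"0": 100.0}

    def test_top_k_clamped_with_warning(self, caplog):
        target = GenePartition({"a": 0, "b": 0}, frozenset(), frozenset())
        source = GenePartition({"a": 0, "b": 0}, frozenset(), frozenset())
        with caplog.at_level("WARNING"):
            table = composition(source, target, top_k=5)
        assert list(table.percentages) == [0]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_percentages_conserved_on_random_partitions(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 400))
        genes = [f"g{i}" for i in range(n)]

        def random_partition():
            labels = rng.integers(0, max(2, n // 8), size=n)
            groups = {}
            for g, lab in zip(genes, labels):
                groups.setdefault(lab, set()).add(g)
            clusters = [m for m in groups.values() if len(m) >= 2]
            leftover = {g for m in groups.values() if len(m) < 2 for g in m}
            iso = {g for g in leftover if rng.random() < 0.5}
            assignment = {g: cid for cid, m in enumerate(clusters) for g in m}
            return GenePartition(assignment, frozenset(iso),
                                 frozenset(leftover - iso))

        source, target = random_partition(), random_partition()
        k = min(5, max(1, target.n_clusters))
        if target.n_clusters == 0:
            return
        table = composition(source, target, top_k=k)
        for pie in table.percentages.values():
            assert sum(pie.values()) == pytest.approx(100.0, abs=0.05)

    def test_top_k_must_be_positive(self):
        p = GenePartition({"a": 0, "b": 0}, frozenset(), frozenset())
        with pytest.raises(ValidationError):
            composition(p, p, 0)
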