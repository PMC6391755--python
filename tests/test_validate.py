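"""Ground-truth inference, AMI, weighted B-cubed, and MAG rank classifiers."""

import numpy as np
import pandas as pd
import pytest

from hicbin.contigs import ContigRecord
from hicbin.validate import (
    SoftTruth,
    ami,
    rank_mag,
    read_alignments,
    truth_from_alignments,
    weighted_b3,
)

from oracles import ami_direct, b3_enumerate, random_soft_instance


def _table(lengths):
    return [ContigRecord(id=c, length=ln, gc=0.5) for c, ln in lengths.items()]


def _aln(rows):
    return pd.DataFrame(rows, columns=["query", "reference", "qstart", "qend", "identity"])


class TestTruthFromAlignments:
    def test_coverage_above_threshold_assigned(self):
        truth, excluded = truth_from_alignments(
            _aln([("c1", "X", 0, 600, 0.99)]), _table({"c1": 1000})
        )
        assert truth.labels == {"c1": frozenset({"X"})}
        assert excluded == []

    def test_overlapping_sources_both_assigned(self):
        truth, _ = truth_from_alignments(
            _aln([("c1", "X", 0, 600, 0.99), ("c1", "Y", 300, 900, 0.99)]),
            _table({"c1": 1000}),
        )
        assert truth.labels["c1"] == frozenset({"X", "Y"})
        assert truth.weight["c1"] == 1000.0

    def test_interval_union_not_sum(self):
        # two heavily overlapping alignments cover only 600/1000
        truth, excluded = truth_from_alignments(
            _aln([("c1", "X", 0, 500, 0.9), ("c1", "X", 100, 600, 0.9)]),
            _table({"c1": 1000}),
        )
        assert truth.covered_fraction["c1"]["X"] == pytest.approx(0.6)

    def test_below_threshold_not_assigned(self):
        truth, excluded = truth_from_alignments(
            _aln([("c1", "X", 0, 490, 0.99)]), _table({"c1": 1000})
        )
        assert "c1" not in truth.labels
        assert excluded == ["c1"]

    def test_malformed_interval_errors(self):
        with pytest.raises(ValueError, match="qend"):
            truth_from_alignments(_aln([("c1", "X", 600, 600, 0.9)]), _table({"c1": 1000}))

    def test_tsv_roundtrip(self, tmp_path):
        truth = SoftTruth(
            labels={"a": frozenset({"X"}), "b": frozenset({"X", "Y"})},
            weight={"a": 1500.0, "b": 800.0},
        )
        truth.save(tmp_path / "truth.tsv")
        back = SoftTruth.load(tmp_path / "truth.tsv")
        assert back.labels == truth.labels
        assert back.weight == truth.weight


def test_blast6_dialect_converts_coordinates(tmp_path):
    path = tmp_path / "aln.tsv"
    path.write_text("c1\trefA\t98.5\t600\t5\t1\t1\t600\t100\t700\t1e-50\t500\n")
    df = read_alignments(path, dialect="blast6")
    row = df.iloc[0]
    assert (row.query, row.reference, row.qstart, row.qend) == ("c1", "refA", 0, 600)
    assert row.identity == pytest.approx(0.985)


def test_maf_dialect(tmp_path):
    path = tmp_path / "aln.maf"
    path.write_text(
        "a score=100\n"
        "s refA 10 600 + 5000 ACGT\n"
        "s c1 0 600 + 1000 ACGT\n\n"
        "a score=50\n"
        "s refB 0 300 + 9000 ACGT\n"
        "s c1 100 300 - 1000 ACGT\n"
    )
    df = read_alignments(path, dialect="maf")
    assert df.iloc[0].tolist()[:4] == ["c1", "refA", 0, 600]
    # minus-strand query coordinates flip to forward
    assert df.iloc[1][["qstart", "qend"]].tolist() == [600, 900]


class TestAmi:
    def test_identical_partitions(self):
        assert ami([0, 0, 1, 1], [5, 5, 9, 9]) == pytest.approx(1.0)

    def test_one_cluster_vs_singletons_is_zero(self):
        assert ami([0] * 8, list(range(8))) == pytest.approx(0.0, abs=1e-12)

    def test_example_matches_direct_formula(self):
        t, p = [0, 0, 1, 1, 2, 2], [0, 0, 1, 2, 2, 2]
        assert ami(t, p) == pytest.approx(ami_direct(t, p), abs=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_instances_match_direct_formula(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        t = rng.integers(0, 4, n).tolist()
        p = rng.integers(0, 4, n).tolist()
        assert ami(t, p) == pytest.approx(ami_direct(t, p), abs=1e-10)

    def test_relabelling_invariant(self):
        t = [0, 0, 1, 1, 2, 2]
        p = [0, 1, 1, 2, 2, 2]
        relabelled = [{0: 7, 1: 3, 2: 5}[x] for x in p]
        assert ami(t, p) == pytest.approx(ami(t, relabelled))

    def test_single_item(self):
        assert ami({"a": 0}, {"a": 4}) == 1.0


def _hard_truth(assign, weights=None):
    return SoftTruth(
        labels={k: frozenset([v]) for k, v in assign.items()},
        weight={k: 1.0 if weights is None else weights[k] for k in assign},
    )


class TestWeightedB3:
    def test_perfect_clustering(self):
        truth = _hard_truth({"a": "X", "b": "X", "c": "Y"}, {"a": 5.0, "b": 2.0, "c": 9.0})
        score = weighted_b3(truth, {"a": 0, "b": 0, "c": 1})
        assert (score.precision, score.recall, score.f) == (1.0, 1.0, 1.0)

    def test_two_pairs_merged_into_one_bin(self):
        truth = _hard_truth({"a": "X", "b": "X", "c": "Y", "d": "Y"})
        score = weighted_b3(truth, {k: 0 for k in "abcd"})
        assert score.precision == pytest.approx(0.5)
        assert score.recall == pytest.approx(1.0)
        assert score.f == pytest.approx(2 / 3)

    def test_weight_scale_invariance(self):
        assign = {"a": "X", "b": "X", "c": "Y", "d": "Y"}
        w = {"a": 3.0, "b": 1.0, "c": 4.0, "d": 1.0}
        pred = {"a": 0, "b": 0, "c": 0, "d": 1}
        s1 = weighted_b3(_hard_truth(assign, w), pred)
        s2 = weighted_b3(_hard_truth(assign, {k: 2 * v for k, v in w.items()}), pred)
        assert s1 == s2

    def test_relabelling_invariant(self):
        truth = _hard_truth({"a": "X", "b": "X", "c": "Y", "d": "Y"})
        pred = {"a": 0, "b": 0, "c": 1, "d": 0}
        relabelled = {k: {0: 9, 1: 4}[v] for k, v in pred.items()}
        assert weighted_b3(truth, pred) == weighted_b3(truth, relabelled)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_pair_enumeration_oracle(self, seed):
        """Soft truth, weighted items: exact agreement with full enumeration."""
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(5, 21))
        items, truth_labels, pred_labels, weight = random_soft_instance(rng, n, 4, 4)
        truth = SoftTruth(labels=truth_labels, weight=weight)
        pred = {it: next(iter(pred_labels[it])) for it in items}
        got = weighted_b3(truth, pred)
        exp_p, exp_r, exp_f = b3_enumerate(truth_labels, pred_labels, weight)
        assert got.precision == pytest.approx(exp_p, abs=1e-12)
        assert got.recall == pytest.approx(exp_r, abs=1e-12)
        assert got.f == pytest.approx(exp_f, abs=1e-12)

    def test_merging_pure_bins_never_raises_precision(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(4, 12))
            assign = {f"i{k}": f"S{rng.integers(3)}" for k in range(n)}
            truth = _hard_truth(assign)
            pure = {k: f"b_{v}" for k, v in assign.items()}  # one bin per source
            merged = dict(pure)
            sources = sorted({v for v in assign.values()})
            if len(sources) < 2:
                continue
            for k, v in assign.items():  # merge first two sources
                if v in sources[:2]:
                    merged[k] = "b_merged"
            p_pure = weighted_b3(truth, pure).precision
            p_merged = weighted_b3(truth, merged).precision
            assert p_merged <= p_pure + 1e-12

    def test_splitting_pure_bin_never_raises_recall(self):
        rng = np.random.default_rng(43)
        for _ in range(20):
            n = int(rng.integers(4, 12))
            assign = {f"i{k}": f"S{rng.integers(2)}" for k in range(n)}
            truth = _hard_truth(assign)
            pure = {k: f"b_{v}" for k, v in assign.items()}
            split = {k: (f"b_{v}_{rng.integers(2)}") for k, v in assign.items()}
            assert weighted_b3(truth, split).recall <= weighted_b3(truth, pure).recall + 1e-12

    def test_all_truth_items_counts_unclustered_as_zero_recall(self):
        truth = _hard_truth({"a": "X", "b": "X", "c": "X", "d": "X"})
        pred = {"a": 0, "b": 0}
        clustered_only = weighted_b3(truth, pred)
        everything = weighted_b3(truth, pred, all_truth_items=True)
        assert clustered_only.recall == pytest.approx(1.0)
        assert everything.recall < clustered_only.recall

    def test_empty_prediction_errors(self):
        with pytest.raises(ValueError):
            weighted_b3(_hard_truth({"a": "X"}), {})


class TestRankMag:
    @pytest.mark.parametrize(
        "completeness,contamination,expected",
        [
            (90.0, 5.0, ("near", "low")),
            (89.99, 5.01, ("substantial", "medium")),
            (70.0, 10.0, ("substantial", "medium")),
            (69.99, 10.01, ("moderate", "high")),
            (50.0, 15.0, ("moderate", "high")),
            (49.99, 15.01, ("partial", "very_high")),
            (95.0, 2.0, ("near", "low")),
            (50.0, 15.0, ("moderate", "high")),
        ],
    )
    def test_simple_rank_boundaries(self, completeness, contamination, expected):
        assert rank_mag(completeness, contamination).simple_rank == expected

    @pytest.mark.parametrize(
        "completeness,contamination,rrna,expected",
        [
            (95.0, 2.0, True, "high"),
            (95.0, 2.0, None, "medium"),  # rRNA/tRNA unknown caps at medium
            (90.0, 2.0, True, "medium"),  # high needs strictly > 90
            (95.0, 5.0, True, "medium"),  # ... and strictly < 5
            (50.0, 9.99, None, "medium"),
            (49.99, 1.0, None, "low"),
            (60.0, 12.0, None, "low"),  # contamination >= 10 fails medium
        ],
    )
    def test_mimag_rank(self, completeness, contamination, rrna, expected):
        assert rank_mag(completeness, contamination, rrna_trna=rrna).mimag_rank == expected

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            rank_mag(101.0, 0.0)
        with pytest.raises(ValueError):
            rank_mag(50.0, -1.0)
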