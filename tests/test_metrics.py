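"""Ranking metrics against independent oracles, aggregation, agreement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr as scipy_spearmanr
from sklearn.metrics import average_precision_score, roc_auc_score

from remhom import (
    EvalLevel,
    RankedList,
    aggregate,
    agreement_matrix,
    auprc,
    auroc,
    hit_at_k,
    spearman,
)
from remhom.errors import ParameterError, SchemaError, UndefinedMetricError
from remhom.metrics import (
    QueryMetricRecord,
    auroc_from_scores,
    average_precision_from_order,
    records_frame,
)


def make_ranked(scores, labels, query_id="q"):
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    scores = np.asarray(scores, dtype=float)[order]
    labels = np.asarray(labels)[order]
    ids = tuple(f"c{i}" for i in range(len(scores)))
    return RankedList(query_id, ids, scores, labels)


def pairwise_auroc_oracle(labels, scores):
    """Exhaustive concordant-pair count; ties credited 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def precision_at_k_oracle(labels_in_order):
    """Direct precision@k summation over the ranks holding positives."""
    total, hits = 0.0, 0
    for k, label in enumerate(labels_in_order, start=1):
        if label == 1:
            hits += 1
            total += hits / k
    return total / sum(labels_in_order)


class TestAuroc:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ([0.9, 0.1], [1, 0], 1.0),
            ([0.9, 0.1], [0, 1], 0.0),
            ([0.9, 0.6, 0.4, 0.2], [1, 0, 1, 0], 0.75),
            ([0.5, 0.5], [1, 0], 0.5),  # tie credited 1/2
        ],
    )
    def test_examples(self, scores, labels, expected):
        assert auroc(make_ranked(scores, labels)) == pytest.approx(expected)

    def test_undefined_without_both_classes(self):
        with pytest.raises(UndefinedMetricError):
            auroc_from_scores([1, 1], [0.2, 0.1])
        with pytest.raises(UndefinedMetricError):
            auroc_from_scores([0, 0], [0.2, 0.1])

    def test_matches_pairwise_oracle_and_sklearn(self, rng):
        for _ in range(300):
            n = int(rng.integers(2, 13))
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.sum() in (0, n):
                continue
            # discretised scores force frequent ties
            scores = rng.integers(0, 4, size=n) / 3.0
            ours = auroc_from_scores(labels, scores)
            assert ours == pytest.approx(pairwise_auroc_oracle(labels, scores))
            assert ours == pytest.approx(roc_auc_score(labels, scores))

    @given(
        n=st.integers(3, 20),
        seed=st.integers(0, 10_000),
        shift=st.floats(-5, 5),
        power=st.integers(1, 3),
    )
    @settings(deadline=None, max_examples=80)
    def test_invariance_under_strictly_monotone_transforms(self, n, seed, shift, power):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=n)
        labels = np.zeros(n, dtype=int)
        labels[: max(1, n // 3)] = 1
        rng.shuffle(labels)
        transformed = np.sign(scores) * np.abs(scores) ** power if power % 2 else None
        transformed = 2.0 * scores + shift if transformed is None else transformed
        assert auroc_from_scores(labels, scores) == pytest.approx(
            auroc_from_scores(labels, transformed)
        )


class TestAuprc:
    def test_perfect_separation(self):
        assert auprc(make_ranked([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])) == 1.0

    def test_single_positive_ranked_last(self):
        assert auprc(make_ranked([0.9, 0.8, 0.7, 0.6, 0.1], [0, 0, 0, 0, 1])) == pytest.approx(0.2)

    def test_matches_direct_summation_oracle_and_sklearn(self, rng):
        for _ in range(300):
            n = int(rng.integers(2, 13))
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            scores = rng.normal(size=n)  # continuous: ties a.s. absent
            ranked = make_ranked(scores, labels)
            ours = auprc(ranked)
            assert ours == pytest.approx(precision_at_k_oracle(ranked.labels))
            assert ours == pytest.approx(average_precision_score(labels, scores))

    def test_one_iff_all_positives_first(self):
        assert average_precision_from_order([1, 1, 0]) == 1.0
        assert average_precision_from_order([1, 0, 1]) < 1.0

    def test_null_calibration_approximates_prevalence(self, rng):
        """Random scores: mean average precision approaches prevalence.

        The null mean of AP sits above prevalence by O(log n_pos / n_pos),
        so the approximation is checked in the many-positives regime."""
        n, n_pos, trials = 200, 40, 400
        labels = np.array([1] * n_pos + [0] * (n - n_pos))
        values = []
        for _ in range(trials):
            scores = rng.normal(size=n)
            values.append(auprc(make_ranked(scores, labels)))
        assert np.mean(values) == pytest.approx(n_pos / n, abs=0.035)


class TestHitAtK:
    def test_top_hit(self):
        ranked = make_ranked([0.9, 0.5], [1, 0])
        assert hit_at_k(ranked, 1) == 1

    def test_positive_at_rank_seven(self):
        labels = [0] * 6 + [1] + [0] * 5
        ranked = make_ranked(np.linspace(1, 0, 12), labels)
        assert hit_at_k(ranked, 10) == 1
        assert hit_at_k(ranked, 1) == 0

    def test_truncation_below_k(self):
        ranked = make_ranked([0.4, 0.3, 0.2, 0.1], [0, 0, 0, 1])
        assert hit_at_k(ranked, 10) == 1

    def test_k_validation(self):
        with pytest.raises(ParameterError):
            hit_at_k(make_ranked([0.5], [1]), 0)

    def test_hit10_dominates_hit1(self, rng):
        for _ in range(100):
            labels = rng.integers(0, 2, size=12)
            if labels.sum() == 0:
                labels[0] = 1
            ranked = make_ranked(rng.normal(size=12), labels)
            assert hit_at_k(ranked, 10) >= hit_at_k(ranked, 1)


def _record(query_id, sf, auroc_value, fold=None):
    return QueryMetricRecord(
        query_id=query_id, superfamily_id=sf, fold_id=fold or sf.rsplit(".", 1)[0],
        auroc=auroc_value, auprc=0.5, hit1=0, hit10=1, n_pos=2, n_neg=5,
    )


class TestAggregate:
    def test_hand_computed_two_group_example(self):
        records = [
            _record("q1", "a.1.1", 1.0),
            _record("q2", "a.1.2", 0.5),
            _record("q3", "a.1.2", 0.5),
            _record("q4", "a.1.2", 0.5),
        ]
        weighted = aggregate(records, "weighted", EvalLevel.SUPERFAMILY)
        unweighted = aggregate(records, "unweighted", EvalLevel.SUPERFAMILY)
        assert weighted.overall["auroc"] == pytest.approx(0.75)
        assert unweighted.overall["auroc"] == pytest.approx(0.625)
        assert weighted.per_group["n_queries"].tolist() == [1, 3]

    def test_equal_group_sizes_make_schemes_agree(self, rng):
        records = [
            _record(f"q{g}{i}", f"a.{g}.1", float(rng.random()))
            for g in range(4)
            for i in range(3)
        ]
        weighted = aggregate(records, "weighted", EvalLevel.SUPERFAMILY)
        unweighted = aggregate(records, "unweighted", EvalLevel.SUPERFAMILY)
        assert weighted.overall["auroc"] == pytest.approx(unweighted.overall["auroc"])

    def test_single_group_both_schemes_equal_group_mean(self):
        records = [_record("q1", "a.1.1", 0.8), _record("q2", "a.1.1", 0.4)]
        for scheme in ("weighted", "unweighted"):
            assert aggregate(records, scheme, EvalLevel.SUPERFAMILY).overall[
                "auroc"
            ] == pytest.approx(0.6)

    def test_fold_level_grouping(self):
        records = [
            _record("q1", "a.1.1", 1.0, fold="a.1"),
            _record("q2", "a.2.1", 0.0, fold="a.2"),
        ]
        result = aggregate(records, "weighted", EvalLevel.FOLD)
        assert list(result.per_group["group_id"]) == ["a.1", "a.2"]

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ParameterError):
            aggregate([_record("q", "a.1.1", 0.5)], "median", EvalLevel.SUPERFAMILY)


class TestSpearman:
    def test_closed_form_hand_example(self):
        # ranks (1,2,3,4) vs (2,1,4,3): rho = 1 - 6*4/(4*15) = 0.6
        assert spearman([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_identical_and_reversed(self):
        x = [0.3, 0.9, 0.1, 0.5]
        assert spearman(x, x) == pytest.approx(1.0)
        assert spearman(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_positive_affine_transform_gives_one(self, rng):
        x = rng.normal(size=15)
        assert spearman(x, 3.0 * x + 2.0) == pytest.approx(1.0)

    def test_symmetry_and_scipy_agreement(self, rng):
        for _ in range(50):
            x = rng.integers(0, 5, size=12).astype(float)  # ties present
            y = rng.integers(0, 5, size=12).astype(float)
            if np.unique(x).size < 2 or np.unique(y).size < 2:
                continue
            ours = spearman(x, y)
            assert ours == pytest.approx(spearman(y, x))
            assert ours == pytest.approx(scipy_spearmanr(x, y).statistic)

    def test_undefined_cases(self):
        with pytest.raises(UndefinedMetricError):
            spearman([1.0], [2.0])
        with pytest.raises(UndefinedMetricError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestAgreementMatrix:
    def _frames(self):
        base = pd.DataFrame(
            {
                "query_id": [f"q{i}" for i in range(8)],
                "superfamily_id": [f"a.{1 + i // 2}.1" for i in range(8)],
                "fold_id": [f"a.{1 + i // 2}" for i in range(8)],
                "auroc": np.linspace(0.2, 0.95, 8),
            }
        )
        return base

    def test_identical_models_all_ones(self):
        base = self._frames()
        result = agreement_matrix({"m1": base, "m2": base.copy()}, EvalLevel.SUPERFAMILY)
        np.testing.assert_allclose(result.values.to_numpy(), 1.0)
        assert result.n.loc["m1", "m2"] == 8  # per-query pairs
        assert result.n.loc["m2", "m1"] == 4  # per-group pairs

    def test_complement_model_gives_minus_one(self):
        base = self._frames()
        flipped = base.assign(auroc=1.0 - base["auroc"])
        result = agreement_matrix({"m1": base, "m2": flipped}, EvalLevel.SUPERFAMILY)
        assert result.values.loc["m1", "m2"] == pytest.approx(-1.0)
        assert result.values.loc["m2", "m1"] == pytest.approx(-1.0)

    def test_three_models_match_hand_formula(self):
        """Per-group AUROC lists on 4 groups; lower triangle must equal the
        closed-form rho computed by hand per pair."""
        groups = ["a.1.1", "a.2.1", "a.3.1", "a.4.1"]

        def frame(aurocs):
            return pd.DataFrame(
                {
                    "query_id": [f"q{g}" for g in range(4)],
                    "superfamily_id": groups,
                    "fold_id": [g.rsplit(".", 1)[0] for g in groups],
                    "auroc": aurocs,
                }
            )

        models = {
            "m1": frame([0.1, 0.2, 0.3, 0.4]),  # ranks 1,2,3,4
            "m2": frame([0.2, 0.1, 0.4, 0.3]),  # ranks 2,1,4,3 -> rho 0.6 vs m1
            "m3": frame([0.4, 0.3, 0.2, 0.1]),  # reversed -> rho -1 vs m1
        }
        result = agreement_matrix(models, EvalLevel.SUPERFAMILY)
        assert result.values.loc["m2", "m1"] == pytest.approx(0.6)
        assert result.values.loc["m3", "m1"] == pytest.approx(-1.0)
        assert result.values.loc["m3", "m2"] == pytest.approx(-0.6)
        np.testing.assert_allclose(np.diag(result.values.to_numpy()), 1.0)

    def test_alignment_uses_intersection(self):
        base = self._frames()
        subset = base.iloc[2:].reset_index(drop=True)
        result = agreement_matrix({"m1": base, "m2": subset}, EvalLevel.SUPERFAMILY)
        assert result.n.loc["m1", "m2"] == 6

    def test_disjoint_queries_rejected(self):
        base = self._frames()
        other = base.assign(query_id=[f"z{i}" for i in range(8)])
        with pytest.raises(SchemaError):
            agreement_matrix({"m1": base, "m2": other}, EvalLevel.SUPERFAMILY)

    def test_records_frame_round_trip(self):
        records = [_record("q1", "a.1.1", 0.7), _record("q2", "a.2.1", 0.9)]
        frame = records_frame(records)
        assert list(frame["query_id"]) == ["q1", "q2"]
        assert frame["auroc"].tolist() == [0.7, 0.9]
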