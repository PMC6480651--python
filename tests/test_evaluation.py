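"""Confusion bookkeeping, Q(n), TPR/FPR, ROC/AUC, RI curves, stratified folds."""

import numpy as np
import pytest

from nucloc.evaluation import (
    ClassCounts,
    ConfusionMatrix,
    build_confusion,
    fpr,
    majority_class_baseline,
    per_class_counts,
    q_n,
    ri_curve,
    roc_auc,
    stratified_kfold,
    tpr,
)
from nucloc.predictor import Prediction
from nucloc.vocabulary import COMPARTMENTS, NONE_LABEL

LBL = ("chromatin", "nucleolus", "kinetochore")


def P(pid, labels, ri=50, scores=None):
    source = "NONE" if not labels else "ML"
    return Prediction(pid, frozenset(labels), ri, source, scores=scores)


class TestBuildConfusion:
    def test_perfect_single_label_is_diagonal(self):
        obs = {"a": frozenset({"chromatin"}), "b": frozenset({"nucleolus"})}
        preds = [P("a", {"chromatin"}), P("b", {"nucleolus"})]
        cm = build_confusion(obs, preds, labels=LBL)
        assert cm.counts.at["chromatin", "chromatin"] == 1
        assert cm.counts.at["nucleolus", "nucleolus"] == 1
        assert cm.counts.values.sum() == 2

    def test_all_empty_predictions_fill_none_row(self):
        obs = {"a": frozenset({"chromatin"}), "b": frozenset({"nucleolus"})}
        preds = [P("a", set()), P("b", set())]
        cm = build_confusion(obs, preds, labels=LBL)
        assert cm.counts.loc[NONE_LABEL].sum() == 2
        assert cm.diagonal().sum() == 0

    def test_fractional_multi_label_miss(self):
        # one protein observed in kinetochore but predicted {chromatin, nucleolus}:
        # fractional mode spreads 0.5 + 0.5, column sums stay integral
        obs = {
            "a": frozenset({"chromatin"}),
            "b": frozenset({"nucleolus"}),
            "c": frozenset({"kinetochore"}),
        }
        preds = [
            P("a", {"chromatin"}),
            P("b", {"nucleolus"}),
            P("c", {"chromatin", "nucleolus"}),
        ]
        cm = build_confusion(obs, preds, attribution="fractional", labels=LBL)
        assert cm.counts.at["chromatin", "kinetochore"] == pytest.approx(0.5)
        assert cm.counts.at["nucleolus", "kinetochore"] == pytest.approx(0.5)
        np.testing.assert_allclose(cm.observed_totals.to_numpy(), [1, 1, 1])

    def test_top_score_attribution_uses_scores(self):
        obs = {"c": frozenset({"kinetochore"})}
        preds = [P("c", {"chromatin", "nucleolus"},
                   scores={"chromatin": 0.2, "nucleolus": 0.9})]
        cm = build_confusion(obs, preds, attribution="top-score", labels=LBL)
        assert cm.counts.at["nucleolus", "kinetochore"] == 1

    def test_column_sums_equal_observed_counts_both_modes(self):
        obs = {
            "a": frozenset({"chromatin", "nucleolus"}),
            "b": frozenset({"nucleolus"}),
            "c": frozenset({"kinetochore"}),
        }
        preds = [
            P("a", {"chromatin"}),
            P("b", {"chromatin", "kinetochore"}, scores={"chromatin": 1.0, "kinetochore": 2.0}),
            P("c", set()),
        ]
        for mode in ("top-score", "fractional"):
            cm = build_confusion(obs, preds, attribution=mode, labels=LBL)
            np.testing.assert_allclose(cm.observed_totals.to_numpy(), [1, 2, 1])

    def test_unknown_protein_errors(self):
        with pytest.raises(KeyError):
            build_confusion({}, [P("ghost", {"chromatin"})], labels=LBL)


class TestQn:
    def test_identity_is_100(self):
        obs = {f"p{i}": frozenset({l}) for i, l in enumerate(LBL)}
        preds = [P(f"p{i}", {l}) for i, l in enumerate(LBL)]
        assert q_n(build_confusion(obs, preds, labels=LBL)) == 100.0

    def test_class_order_permutation_invariant(self):
        obs = {"a": frozenset({"chromatin"}), "b": frozenset({"nucleolus"}),
               "c": frozenset({"kinetochore"})}
        preds = [P("a", {"nucleolus"}, scores={"nucleolus": 1.0}),
                 P("b", {"nucleolus"}), P("c", {"kinetochore"})]
        q1 = q_n(build_confusion(obs, preds, labels=LBL))
        q2 = q_n(build_confusion(obs, preds, labels=tuple(reversed(LBL))))
        assert q1 == pytest.approx(q2)

    def test_uniform_random_assignment_near_100_over_n(self, rng):
        # simulation oracle: random single-label predictions over n equal classes
        n = 4
        labels = COMPARTMENTS[:n]
        obs = {f"p{i}": frozenset({labels[rng.integers(n)]}) for i in range(4000)}
        preds = [P(pid, {labels[rng.integers(n)]}) for pid in obs]
        q = q_n(build_confusion(obs, preds, labels=labels))
        assert q == pytest.approx(100.0 / n, abs=3 * 100 / np.sqrt(4000))

    def test_empty_matrix_errors(self):
        import pandas as pd

        cm = ConfusionMatrix(pd.DataFrame(0.0, index=list(LBL) + [NONE_LABEL], columns=list(LBL)))
        with pytest.raises(ValueError):
            q_n(cm)


class TestRates:
    def test_tpr_direct_arithmetic(self):
        assert tpr(ClassCounts(8, 0, 6, 0)) == pytest.approx(100 * 8 / 14)

    def test_fpr_formula(self):
        assert fpr(ClassCounts(0, 10, 0, 90)) == pytest.approx(10.0)

    def test_perfect_classifier(self):
        c = ClassCounts(5, 0, 0, 95)
        assert tpr(c) == 100.0 and fpr(c) == 0.0

    def test_zero_denominators_warn_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(fpr(ClassCounts(3, 0, 2, 0)))
        with pytest.warns(UserWarning):
            assert np.isnan(tpr(ClassCounts(0, 1, 0, 4)))

    def test_per_class_counts_total(self):
        obs = {"a": frozenset({"chromatin"}), "b": frozenset({"nucleolus"})}
        preds = [P("a", {"chromatin"}), P("b", {"chromatin"})]
        counts = per_class_counts(obs, preds, labels=LBL)
        assert all(c.total == 2 for c in counts.values())
        assert counts["chromatin"].fp == 1


def auc_pair_counting(scores, truth):
    """Mann-Whitney oracle: (concordant + half-tied pairs) / (pos * neg)."""
    pos = [s for s, t in zip(scores, truth) if t]
    neg = [s for s, t in zip(scores, truth) if not t]
    conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return conc / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [True, True, False, False]) == 1.0

    def test_constant_scores_give_half(self):
        assert roc_auc([1.0] * 6, [True, False] * 3) == 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [True, True])

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(10):
            scores = rng.choice([0.1, 0.25, 0.5, 0.7, 0.9], size=20).tolist()
            truth = (rng.random(20) < 0.5).tolist()
            if all(truth) or not any(truth):
                continue
            assert roc_auc(scores, truth) == pytest.approx(
                auc_pair_counting(scores, truth), abs=1e-12
            )


class TestRiCurve:
    def _preds(self):
        obs = {}
        preds = []
        # RI calibrated by construction: high-RI predictions are correct
        for i in range(40):
            pid = f"p{i}"
            correct = i % 4 != 0
            ri = 80 if correct else 10
            obs[pid] = frozenset({"chromatin"})
            preds.append(P(pid, {"chromatin" if correct else "nucleolus"}, ri=ri))
        return obs, preds

    def test_threshold_zero_is_overall(self):
        obs, preds = self._preds()
        curve = ri_curve(preds, obs)
        t0, cov0, acc0 = curve[0]
        assert t0 == 0 and cov0 == 100.0
        assert acc0 == pytest.approx(q_n(build_confusion(obs, preds)))

    def test_coverage_monotone_decreasing(self):
        obs, preds = self._preds()
        curve = ri_curve(preds, obs)
        coverages = [c for _, c, _ in curve]
        assert all(a >= b for a, b in zip(coverages, coverages[1:]))

    def test_calibrated_ri_gives_nondecreasing_accuracy(self):
        obs, preds = self._preds()
        curve = ri_curve(preds, obs)
        accs = [a for _, _, a in curve if not np.isnan(a)]
        assert all(a <= b + 1e-9 for a, b in zip(accs, accs[1:]))


class TestStratifiedKfold:
    def test_balanced_two_class_folds(self):
        ids = [f"p{i}" for i in range(100)]
        labels = ["A"] * 50 + ["B"] * 50
        folds = stratified_kfold(ids, labels, k=5, seed=0)
        for fold in folds:
            assert sum(1 for pid in fold if labels[ids.index(pid)] == "A") == 10
            assert len(fold) == 20

    def test_partition_property(self, rng):
        ids = [f"p{i}" for i in range(37)]
        labels = [str(rng.integers(3)) for _ in ids]
        folds = stratified_kfold(ids, labels, k=5, seed=1)
        flat = [pid for fold in folds for pid in fold]
        assert sorted(flat) == sorted(ids)
        assert len(set(flat)) == len(flat)

    def test_tiny_class_pigeonhole(self):
        ids = [f"a{i}" for i in range(20)] + ["r1", "r2", "r3"]
        labels = ["A"] * 20 + ["rare"] * 3
        folds = stratified_kfold(ids, labels, k=5, seed=0)
        for fold in folds:
            assert sum(1 for pid in fold if pid.startswith("r")) <= 1

    def test_k_larger_than_n_errors(self):
        with pytest.raises(ValueError):
            stratified_kfold(["a"], ["A"], k=5)


def test_majority_baseline():
    import pandas as pd

    totals = pd.Series([70, 20, 10], index=list(LBL))
    assert majority_class_baseline(totals) == pytest.approx(70.0)
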