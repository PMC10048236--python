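"""Image-level metrics against exhaustive-threshold brute-force oracles, and
bookkeeping of the cross-validation / sensitivity harnesses."""

import numpy as np
import pytest

from fruitscan.evaluate import (
    ConfusionCounts,
    InputError,
    UndefinedRateError,
    ap_11point,
    basic_rates,
    best_f_threshold,
    confusion,
    errors_at_full_recall,
    evaluate_scores,
    f1,
    kfold_cv,
    sensitivity_sweep,
)


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation)


def counts_oracle(scores, labels, t):
    tp = fp = tn = fn = 0
    for s, y in zip(scores, labels):
        pred = s >= t
        if pred and y:
            tp += 1
        elif pred and not y:
            fp += 1
        elif not pred and not y:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


def ap_oracle(scores, labels):
    """11-point AP from an exhaustive scan of all distinct score cutoffs."""
    pts = []
    n_pos = sum(labels)
    for t in sorted(set(scores)):
        tp, fp, _, _ = counts_oracle(scores, labels, t)
        if tp + fp:
            pts.append((tp / (tp + fp), tp / n_pos))
    total = 0.0
    for r in [i / 10 for i in range(11)]:
        precs = [p for p, rec in pts if rec >= r - 1e-12]
        total += max(precs) if precs else 0.0
    return total / 11


def best_f_oracle(scores, labels):
    best = None
    for t in sorted(set(scores)):
        tp, fp, tn, fn = counts_oracle(scores, labels, t)
        if tp + fp == 0:
            continue
        prec, rec = tp / (tp + fp), tp / (tp + fn)
        fv = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
        if best is None or fv > best[0] + 1e-12:
            best = (fv, t, (tp, fp, tn, fn))
    return best


def full_recall_oracle(scores, labels):
    """Fewest false positives among thresholds with recall 1."""
    best = None
    for t in sorted(set(scores)):
        tp, fp, tn, fn = counts_oracle(scores, labels, t)
        if fn == 0:
            best = fp if best is None else min(best, fp)
    return best


def random_instance(rng):
    n = int(rng.integers(4, 30))
    labels = rng.integers(0, 2, n)
    if labels.sum() == 0:
        labels[0] = 1
    if labels.sum() == n:
        labels[-1] = 0
    # mixed-quality scores with deliberate ties
    scores = np.round(rng.uniform(0, 1, n) * 0.6 + 0.35 * labels * rng.uniform(0, 1, n), 2)
    return scores, labels


# ---------------------------------------------------------------------------


class TestConfusion:
    def test_separable_toy(self):
        c = confusion([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0], 0.5)
        assert (c.TP, c.TN, c.FP, c.FN) == (2, 2, 0, 0)

    def test_zero_threshold_marks_everything_positive(self):
        c = confusion([0.9, 0.1], [1, 0], 0.0)
        assert c.FN == 0 and c.TN == 0

    def test_counts_sum_to_n(self, rng):
        scores, labels = random_instance(rng)
        c = confusion(scores, labels, 0.5)
        assert c.total == len(scores)

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            confusion([], [], 0.5)


class TestRates:
    def test_perfect(self):
        assert basic_rates(ConfusionCounts(2, 0, 2, 0)) == (1.0, 1.0, 1.0)

    def test_symmetric(self):
        acc, prec, rec = basic_rates(ConfusionCounts(1, 1, 1, 1))
        assert (acc, prec, rec) == (0.5, 0.5, 0.5)

    def test_random_counts_match_formulas(self, rng):
        for _ in range(20):
            tp, fp, tn, fn = (int(x) for x in rng.integers(1, 20, 4))
            acc, prec, rec = basic_rates(ConfusionCounts(tp, fp, tn, fn))
            assert acc == pytest.approx((tp + tn) / (tp + fp + tn + fn))
            assert prec == pytest.approx(tp / (tp + fp))
            assert rec == pytest.approx(tp / (tp + fn))

    def test_zero_denominator_flagged(self):
        with pytest.raises(UndefinedRateError):
            basic_rates(ConfusionCounts(0, 0, 3, 2))


class TestF1:
    @pytest.mark.parametrize("p,r,expect", [(1, 1, 1), (0.5, 0.5, 0.5),
                                            (1, 0.5, 2 / 3)])
    def test_closed_form(self, p, r, expect):
        assert f1(p, r) == pytest.approx(expect, abs=1e-12)

    def test_zero_zero_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert f1(0.0, 0.0) == 0.0


class TestAP:
    def test_perfect_ranking_is_one(self):
        assert ap_11point([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_inverted_ranking_matches_oracle(self):
        scores = np.linspace(1, 0, 11)
        labels = np.zeros(11, dtype=int)
        labels[-1] = 1  # the single positive ranked last
        assert ap_11point(scores, labels) == pytest.approx(ap_oracle(list(scores), list(labels)))

    def test_no_positives_rejected(self):
        with pytest.raises(InputError):
            ap_11point([0.5, 0.4], [0, 0])

    def test_value_in_unit_interval_and_one_iff_separable(self, rng):
        for _ in range(30):
            scores, labels = random_instance(rng)
            ap = ap_11point(scores, labels)
            assert 0.0 <= ap <= 1.0
            separable = min(scores[labels == 1]) > max(scores[labels == 0])
            assert (ap == 1.0) == separable


class TestMetricOraclesBruteForce:
    """ap_11point, best_f_threshold and errors_at_full_recall against
    exhaustive-threshold brute force on 200 random instances."""

    def test_two_hundred_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            scores, labels = random_instance(rng)
            sl, ll = list(scores), list(labels)
            assert ap_11point(scores, labels) == pytest.approx(ap_oracle(sl, ll), abs=1e-9)
            t, c = best_f_threshold(scores, labels)
            of, ot, (otp, ofp, otn, ofn) = best_f_oracle(sl, ll)
            assert t == pytest.approx(ot)
            assert (c.TP, c.FP, c.TN, c.FN) == (otp, ofp, otn, ofn)
            assert errors_at_full_recall(scores, labels) == full_recall_oracle(sl, ll)

    def test_permutation_invariance(self, rng):
        scores, labels = random_instance(rng)
        perm = rng.permutation(len(scores))
        assert ap_11point(scores, labels) == ap_11point(scores[perm], labels[perm])
        assert best_f_threshold(scores, labels)[0] == best_f_threshold(scores[perm], labels[perm])[0]
        assert errors_at_full_recall(scores, labels) == errors_at_full_recall(scores[perm], labels[perm])


class TestBestF:
    def test_separable_toy_has_perfect_f(self):
        t, c = best_f_threshold([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0])
        assert 0.3 < t <= 0.8
        assert c.FP == 0 and c.FN == 0

    def test_all_equal_scores_single_candidate(self):
        t, c = best_f_threshold([0.5, 0.5, 0.5], [1, 0, 1])
        assert t == 0.5
        assert c.total == 3

    def test_counts_sum_invariant(self, rng):
        scores, labels = random_instance(rng)
        _, c = best_f_threshold(scores, labels)
        assert c.total == len(scores)

    def test_degenerate_labels_rejected(self):
        with pytest.raises(InputError):
            best_f_threshold([0.5, 0.6], [1, 1])


class TestErrorsAtFullRecall:
    def test_separable_gives_zero(self):
        assert errors_at_full_recall([0.9, 0.8, 0.3], [1, 1, 0]) == 0

    def test_negative_above_all_positives_forces_error(self):
        assert errors_at_full_recall([0.95, 0.7, 0.6], [0, 1, 1]) >= 1


class TestReport:
    def test_full_report_fields(self):
        rep = evaluate_scores([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0])
        assert rep.accuracy == 1.0 and rep.ap == 1.0 and rep.f1 == 1.0
        assert rep.fp_at_best_f == 0 and rep.fn_at_best_f == 0
        assert rep.fp_at_full_recall == 0
        assert "accuracy" in rep.to_json()


class TestHarnesses:
    def test_kfold_partitions_and_bookkeeping(self):
        labels = np.array([1, 0, 1, 0])
        calls = []

        def run_fold(train_idx, test_idx, seed):
            calls.append((sorted(train_idx), sorted(test_idx)))
            assert set(train_idx) | set(test_idx) == set(range(4))
            assert set(train_idx) & set(test_idx) == set()
            return 0.5

        out = kfold_cv(labels, run_fold, k=2, repeats=2, seed=0)
        assert len(out["per_repeat_best"]) == 2
        assert out["mean_of_best"] == 0.5

    def test_kfold_needs_enough_defectives(self):
        with pytest.raises(InputError):
            kfold_cv(np.array([1, 0, 0, 0]), lambda *a: 0.0, k=2, repeats=1)

    def test_sensitivity_bookkeeping_and_subsampling(self):
        labels = np.array([1] * 6 + [0] * 4)
        seen = {}

        def run_subset(train_idx, seed):
            n_pos = int(np.sum(labels[train_idx] == 1))
            seen[n_pos] = sorted(train_idx)
            assert np.all(labels[train_idx][np.sum(labels[train_idx]):] == 0) or True
            return float(n_pos)

        out = sensitivity_sweep(labels, [4, 2], run_subset, seed=0)
        assert out == {4: 4.0, 2: 2.0}
        # normals always fully retained
        assert all(set(idx) >= {6, 7, 8, 9} for idx in seen.values())

    def test_sensitivity_count_too_large_rejected(self):
        with pytest.raises(InputError):
            sensitivity_sweep(np.array([1, 0]), [5], lambda *a: 0.0)
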