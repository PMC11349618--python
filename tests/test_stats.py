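"""Evaluation-statistics unit tests, each against an independent oracle
(brute-force counting, closed-form formulas, or a second library)."""

import numpy as np
import pytest
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from atrophy2d.stats import (bland_altman, confusion_counts, delong_test,
                             dice, group_compare, pearson_with_ci, percent_of,
                             roc_pr_metrics)


def brute_force_counts(pred, truth):
    tp = fp = fn = tn = 0
    for p, t in zip(pred.ravel(), truth.ravel()):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def auc_concordant_pairs(scores, labels):
    """Exhaustive concordant-pair counting with ties worth 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusionAndDice:
    def test_identity_and_complement(self):
        m = np.array([[1, 0], [1, 1]], dtype=bool)
        c = confusion_counts(m, m)
        assert (c.fp, c.fn) == (0, 0) and c.tp == 3
        c2 = confusion_counts(~m, m)
        assert (c2.tp, c2.tn) == (0, 0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            confusion_counts(np.ones((2, 2)), np.ones((3, 3)))

    def test_dice_printed_formula(self):
        # TP=2, FP=1, FN=1 -> 2*2/(2*2+1+1)
        pred = np.array([1, 1, 1, 0], dtype=bool)
        truth = np.array([1, 1, 0, 1], dtype=bool)
        assert dice(pred, truth) == pytest.approx(2 / 3)

    def test_dice_extremes(self):
        a = np.array([1, 1, 0], dtype=bool)
        assert dice(a, a) == 1.0
        assert dice(a, ~a) == 0.0

    def test_empty_vs_empty_warns_returns_one(self):
        z = np.zeros(5, dtype=bool)
        with pytest.warns(UserWarning, match="empty"):
            assert dice(z, z) == 1.0

    def test_oracle_equivalence_random_masks(self, rng):
        for _ in range(50):
            shape = tuple(rng.integers(2, 12, size=2))
            pred = rng.random(shape) > 0.6
            truth = rng.random(shape) > 0.6
            tp, fp, fn, tn = brute_force_counts(pred, truth)
            c = confusion_counts(pred, truth)
            assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)
            if 2 * tp + fp + fn > 0:
                assert dice(pred, truth) == pytest.approx(
                    2 * tp / (2 * tp + fp + fn), abs=1e-12)
                assert dice(pred, truth) == pytest.approx(
                    dice(truth, pred), abs=1e-12)


class TestRocPr:
    def test_known_auc(self):
        m = roc_pr_metrics(np.array([0.1, 0.4, 0.35, 0.8]),
                           np.array([0, 0, 1, 1]))
        assert m["auc"] == pytest.approx(0.75)

    def test_perfect_and_tied(self):
        m = roc_pr_metrics(np.array([1, 2, 3, 4.0]), np.array([0, 0, 1, 1]))
        assert m["auc"] == 1.0 and m["auprc"] == 1.0
        tied = roc_pr_metrics(np.ones(6), np.array([0, 1, 0, 1, 0, 1]))
        assert tied["auc"] == pytest.approx(0.5)

    def test_sensitivity_specificity_at_threshold(self):
        scores = np.array([0.1, 0.2, 0.6, 0.9])
        labels = np.array([0, 1, 0, 1])
        m = roc_pr_metrics(scores, labels, threshold=0.5)
        assert m["sensitivity"] == 0.5 and m["specificity"] == 0.5

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            roc_pr_metrics(np.array([0.2, 0.4]), np.array([1, 1]))

    def test_midrank_oracle_and_sklearn(self, rng):
        for _ in range(40):
            n = int(rng.integers(6, 50))
            scores = np.round(rng.random(n), 1)  # force ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            auc = roc_pr_metrics(scores, labels)["auc"]
            assert auc == pytest.approx(auc_concordant_pairs(scores, labels),
                                        abs=1e-12)
            assert auc == pytest.approx(roc_auc_score(labels, scores),
                                        abs=1e-12)

    def test_negated_score_symmetry(self, rng):
        scores = rng.random(30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        a1 = roc_pr_metrics(scores, labels)["auc"]
        a2 = roc_pr_metrics(-scores, labels)["auc"]
        assert a1 + a2 == pytest.approx(1.0)


class TestDeLong:
    def test_self_comparison_p_is_one(self, rng):
        scores = rng.random(60)
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        out = delong_test(scores, scores, labels)
        assert out["z"] == 0.0 and out["p"] == 1.0

    def test_auc_consistency(self, rng):
        a = rng.random(80)
        b = rng.random(80)
        labels = rng.integers(0, 2, size=80)
        labels[:2] = [0, 1]
        out = delong_test(a, b, labels)
        assert out["auc_a"] == pytest.approx(roc_pr_metrics(a, labels)["auc"])
        assert out["auc_b"] == pytest.approx(roc_pr_metrics(b, labels)["auc"])

    def test_detects_large_difference(self):
        rng = np.random.default_rng(5)
        labels = np.repeat([0, 1], 100)
        informative = labels + rng.normal(0, 0.5, 200)
        noise = rng.normal(0, 1, 200)
        out = delong_test(informative, noise, labels)
        assert out["p"] < 1e-4

    def test_unpaired_error(self):
        with pytest.raises(ValueError, match="paired"):
            delong_test(np.ones(3), np.ones(4), np.array([0, 1, 0, 1]))


class TestPearsonCI:
    def test_identity_and_anti_identity(self, rng):
        x = rng.normal(size=50)
        assert pearson_with_ci(x, x)["r"] == pytest.approx(1.0)
        assert pearson_with_ci(x, -x)["r"] == pytest.approx(-1.0)

    def test_fisher_ci_frozen_value(self):
        # construct a sample with r exactly 0.5 by orthogonalization
        rng = np.random.default_rng(11)
        n, r = 100, 0.5
        x = rng.normal(size=n)
        e = rng.normal(size=n)
        x = (x - x.mean()) / x.std()
        e = e - e.mean()
        e -= x * (e @ x) / (x @ x)
        e /= e.std()
        y = r * x + np.sqrt(1 - r**2) * e
        out = pearson_with_ci(x, y)
        assert out["r"] == pytest.approx(0.5, abs=1e-12)
        # independent Fisher-formula oracle: tanh(atanh(r) +/- 1.96/sqrt(97))
        assert out["lo"] == pytest.approx(0.3366, abs=1e-3)
        assert out["hi"] == pytest.approx(0.6333, abs=1e-3)

    def test_ci_shrinks_with_n(self, rng):
        x = rng.normal(size=400)
        y = 0.5 * x + rng.normal(size=400)
        big = pearson_with_ci(x, y)
        small = pearson_with_ci(x[:100], y[:100])
        assert big["hi"] - big["lo"] < small["hi"] - small["lo"]

    def test_zero_variance_error(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_with_ci(np.ones(10), np.arange(10.0))

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.normal(size=60)
        y = x + rng.normal(size=60)
        out = pearson_with_ci(x, y)
        ref = pingouin.corr(x, y)
        assert out["r"] == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        lo, hi = ref["CI95"].iloc[0] if "CI95" in ref else ref["CI95%"].iloc[0]
        assert out["lo"] == pytest.approx(lo, abs=5e-3)
        assert out["hi"] == pytest.approx(hi, abs=5e-3)


class TestBlandAltman:
    def test_identity(self):
        x = np.arange(5.0)
        out = bland_altman(x, x)
        assert out["bias"] == 0 and out["loa_low"] == 0 and out["loa_high"] == 0

    def test_constant_offset(self):
        x = np.arange(5.0)
        out = bland_altman(x, x + 3)
        assert out["bias"] == pytest.approx(-3)
        assert out["loa_low"] == pytest.approx(-3)
        assert out["loa_high"] == pytest.approx(-3)

    def test_formula_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            out = bland_altman(x, y)
            d = x - y
            assert out["bias"] == pytest.approx(d.mean())
            assert out["loa_high"] == pytest.approx(
                d.mean() + 1.96 * d.std(ddof=1))


class TestGroupCompare:
    def test_identical_proportions_chi2_p_one(self):
        import pandas as pd
        table = pd.DataFrame({
            "group": ["a"] * 100 + ["b"] * 100,
            "female": [1] * 59 + [0] * 41 + [1] * 59 + [0] * 41,
        })
        out = group_compare(table, "female", "group", categorical=True)
        assert out["test"] == "chi-square"
        assert out["p"] == pytest.approx(1.0)

    def test_large_effect_selects_ttest(self, rng):
        import pandas as pd
        table = pd.DataFrame({
            "group": ["a"] * 200 + ["b"] * 200,
            "v": np.concatenate([rng.normal(0, 1, 200),
                                 rng.normal(2, 1, 200)]),
        })
        out = group_compare(table, "v", "group")
        assert out["test"] == "t-test"
        assert out["p"] < 1e-10 and out["significant"]

    def test_skewed_variable_selects_mannwhitney(self, rng):
        import pandas as pd
        table = pd.DataFrame({
            "group": ["a"] * 80 + ["b"] * 80,
            "v": np.concatenate([rng.exponential(1, 80),
                                 rng.exponential(2, 80)]),
        })
        out = group_compare(table, "v", "group")
        assert out["test"] == "mann-whitney"

    def test_three_groups_error(self):
        import pandas as pd
        table = pd.DataFrame({"group": ["a", "b", "c"], "v": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            group_compare(table, "v", "group")


def test_percent_of_worked_demographics():
    """542 female of 924 development subjects prints as 58.7%."""
    assert percent_of(542, 924) == 58.7
    assert percent_of(282, 478) == 59.0
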