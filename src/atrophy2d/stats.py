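"""Evaluation statistics: Dice overlap, ROC/PR metrics, DeLong's paired AUC
test, Pearson correlation with a Fisher-transform CI, Bland-Altman agreement,
and two-group cohort comparisons."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import average_precision_score

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "dice",
    "roc_pr_metrics",
    "auc_rank",
    "delong_test",
    "pearson_with_ci",
    "bland_altman",
    "group_compare",
    "percent_of",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Elementwise TP/FP/FN/TN between two binary masks of identical shape."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return ConfusionCounts(tp, fp, fn, tn)


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice similarity coefficient, DSC = 2 TP / (2 TP + FP + FN).

    Both masks empty is a 0/0 case: returns 1 with a warning (two empty
    regions agree perfectly), a convention chosen because ROI absence in
    sparse slices is routine.
    """
    c = confusion_counts(pred, truth)
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        warnings.warn("Dice of two empty masks is undefined (0/0); returning 1",
                      stacklevel=2)
        return 1.0
    return 2.0 * c.tp / denom


def auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the rank statistic with midrank tie handling (equals the
    normalized Mann-Whitney U)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1))


def roc_pr_metrics(scores: np.ndarray, labels: np.ndarray,
                   threshold: float | None = None) -> dict:
    """AUC (midrank convention), AUPRC (step-wise non-interpolated
    integration), and sensitivity/specificity at the supplied threshold
    (predicted positive iff score >= threshold)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    out = {"auc": auc_rank(scores, labels),
           "auprc": float(average_precision_score(labels, scores))}
    if threshold is not None:
        pred = scores >= threshold
        pos, neg = labels == 1, labels == 0
        out["sensitivity"] = float(np.count_nonzero(pred & pos) / pos.sum())
        out["specificity"] = float(np.count_nonzero(~pred & neg) / neg.sum())
    return out


def _placements(pos: np.ndarray, neg: np.ndarray):
    """Midrank placement values V10 (per positive) and V01 (per negative)."""
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    ranks = sps.rankdata(allv)
    rank_pos = sps.rankdata(pos)
    rank_neg = sps.rankdata(neg)
    v10 = (ranks[:m] - rank_pos) / n
    v01 = 1.0 - (ranks[m:] - rank_neg) / m
    return v10, v01


def delong_test(scores_a: np.ndarray, scores_b: np.ndarray,
                labels: np.ndarray) -> dict:
    """DeLong's test for two correlated (paired) AUCs.

    Scores must be paired on the same subjects. Returns both AUCs, the z
    statistic, and the two-sided normal p-value. Identical score vectors are
    a zero-variance comparison and return z = 0, p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=np.float64)
    scores_b = np.asarray(scores_b, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise ValueError("scores_a, scores_b and labels must be paired "
                         f"(got lengths {len(scores_a)}, {len(scores_b)}, "
                         f"{len(labels)})")
    pos, neg = labels == 1, labels == 0
    if pos.sum() == 0 or neg.sum() == 0:
        raise ValueError("both classes must be present")
    aucs, v10s, v01s = [], [], []
    for s in (scores_a, scores_b):
        v10, v01 = _placements(s[pos], s[neg])
        v10s.append(v10)
        v01s.append(v01)
        aucs.append(v10.mean())
    m, n = pos.sum(), neg.sum()
    s10 = np.cov(np.stack(v10s)) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack(v01s)) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = aucs[0] - aucs[1]
    if var <= 0 or np.isclose(diff, 0.0, atol=1e-15):
        z = 0.0 if np.isclose(diff, 0.0, atol=1e-15) else np.inf * np.sign(diff)
    else:
        z = diff / np.sqrt(var)
    p = 1.0 if z == 0.0 else float(2.0 * sps.norm.sf(abs(z)))
    return {"auc_a": float(aucs[0]), "auc_b": float(aucs[1]),
            "z": float(z), "p": p}


def pearson_with_ci(x: np.ndarray, y: np.ndarray, level: float = 0.95) -> dict:
    """Sample Pearson r with a Fisher z-transform confidence interval."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = len(x)
    if n < 4:
        raise ValueError(f"need n >= 4 for a Fisher CI, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y")
    r = float(sps.pearsonr(x, y).statistic)
    if abs(r) >= 1.0:
        return {"r": r, "lo": r, "hi": r, "n": n}
    zcrit = sps.norm.ppf(0.5 + level / 2.0)
    zr = np.arctanh(r)
    half = zcrit / np.sqrt(n - 3)
    return {"r": r, "lo": float(np.tanh(zr - half)),
            "hi": float(np.tanh(zr + half)), "n": n}


def bland_altman(x: np.ndarray, y: np.ndarray) -> dict:
    """Bland-Altman agreement: bias = mean(x - y), limits of agreement
    bias +/- 1.96 * SD(x - y) with the sample SD (n - 1)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return {"bias": bias, "loa_low": bias - 1.96 * sd,
            "loa_high": bias + 1.96 * sd, "n": len(x)}


def group_compare(table, variable: str, group_col: str,
                  categorical: bool | None = None, alpha: float = 0.05) -> dict:
    """Two-group comparison following the usual clinical-table conventions.

    Continuous variables: Shapiro-Wilk normality screen on each group at
    alpha = 0.05 chooses Student's t (both normal) vs Mann-Whitney U.
    Categorical variables: chi-square on the contingency table. Significance
    is read at p < 0.05.
    """
    groups = table[group_col].unique()
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, found {len(groups)}")
    a = table.loc[table[group_col] == groups[0], variable]
    b = table.loc[table[group_col] == groups[1], variable]
    if categorical is None:
        categorical = (a.dtype == object or a.nunique() <= 2)
    if categorical:
        import pandas as pd
        ct = pd.crosstab(table[group_col], table[variable])
        stat, p, _, _ = sps.chi2_contingency(ct)
        test = "chi-square"
    else:
        normal = all(sps.shapiro(g).pvalue > alpha for g in (a, b))
        if normal:
            stat, p = sps.ttest_ind(a, b)
            test = "t-test"
        else:
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
            test = "mann-whitney"
    return {"test": test, "statistic": float(stat), "p": float(p),
            "significant": bool(p < 0.05)}


def percent_of(count: int, total: int, decimals: int = 1) -> float:
    """Percentage of a printed count pair, e.g. 542 of 924 -> 58.7."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, decimals)
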