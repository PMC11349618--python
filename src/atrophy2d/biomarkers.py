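"""AD biomarkers from the seven CSF-volume features.

* DAT-vs-CU classifier whose continuous sigmoid output in [0, 1] is the
  "AD-specific atrophy similarity"; the decision threshold maximizes
  Youden's J on development data.
* W-score normative model: per ROI, OLS of CSF volume on age and sex fitted
  on a cognitively-unimpaired reference cohort;
  W = (V - E_CU(age, sex)) / sigma_CU with sigma_CU the residual standard
  error (denominator n - 3 by default). Positive W means more CSF (more
  atrophy) than expected for age and sex.
* Brain-age MLP mapping (7 CSF volumes, age, sex) -> brain age; the Brain
  Age Index is BAI = predicted brain age - chronological age in years.
  Chronological age is deliberately both a model input and the BAI
  reference, following the upstream feature definition; the leakage this
  invites is discussed in the methods note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nn import MLP
from .phantom import CSF_ROIS, ROI_NAMES
from .pipeline import kfold_splits
from .quantify import desk_mlp_grid
from .stats import roc_pr_metrics

log = logging.getLogger(__name__)

__all__ = [
    "CSF_FEATURES",
    "DatClassifier",
    "WScoreModel",
    "BrainAgeModel",
    "train_dat_classifier",
    "score_subject",
    "select_threshold",
    "fit_wscore_model",
    "compute_wscore",
    "train_brainage_model",
    "compute_bai",
]

CSF_FEATURES = [ROI_NAMES[c] for c in CSF_ROIS]


def _feature_matrix(table: pd.DataFrame, cols: list[str]) -> np.ndarray:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    return table[cols].to_numpy(dtype=np.float64)


# ---------------------------------------------------------------------------
# DAT / CU classifier and atrophy similarity
# ---------------------------------------------------------------------------

@dataclass
class DatClassifier:
    model: MLP
    feature_cols: list[str]
    threshold: float
    chosen: dict
    cv_auc: float
    cv_auprc: float

    @property
    def fitted(self) -> bool:
        return self.model is not None and self.model.fitted


def select_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Score threshold maximizing Youden's J = sens + spec - 1.

    Candidates are midpoints between consecutive distinct scores (plus one
    below the minimum and one above the maximum); the prediction rule is
    positive iff score >= threshold, ties in J break toward the lower
    threshold.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n1 = labels.sum()
    n0 = len(labels) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    best_j, best_t = -np.inf, candidates[0]
    for t in candidates:
        pred = scores >= t
        sens = np.count_nonzero(pred & (labels == 1)) / n1
        spec = np.count_nonzero(~pred & (labels == 0)) / n0
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)


def train_dat_classifier(
    table: pd.DataFrame,
    feature_cols: list[str] | None = None,
    label_col: str = "dx",
    grid: list[dict] | None = None,
    cv: tuple[int, int] = (10, 10),
    seed: int = 0,
    epochs: int = 200,
) -> DatClassifier:
    """Sigmoid-output MLP on {CU: 0, DAT: 1}; the grid point with the highest
    mean CV AUC is refit on the full development table; the stored decision
    threshold is the Youden optimum on development scores."""
    feature_cols = feature_cols or CSF_FEATURES + ["age", "sex"]
    grid = grid if grid is not None else desk_mlp_grid()
    y = table[label_col].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("development data contain a single class")
    X = _feature_matrix(table, feature_cols)
    reps, folds = cv
    ids = list(table["id"]) if "id" in table.columns else list(range(len(table)))
    splits = kfold_splits(ids, k=folds, repeats=reps, seed=seed)
    id_pos = {s: i for i, s in enumerate(ids)}
    results = []
    for hp in grid:
        aucs, auprcs = [], []
        for rep in splits:
            for train_ids, val_ids in rep:
                tr = [id_pos[i] for i in train_ids]
                va = [id_pos[i] for i in val_ids]
                if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
                    continue  # degenerate fold at small n
                mlp = MLP(task="binary", epochs=epochs, seed=seed, **hp)
                mlp.fit(X[tr], y[tr])
                s = mlp.predict(X[va])
                m = roc_pr_metrics(s, y[va])
                aucs.append(m["auc"])
                auprcs.append(m["auprc"])
        results.append((float(np.mean(aucs)), float(np.mean(auprcs))))
        log.info("classifier grid %s: AUC %.3f", hp, results[-1][0])
    best_i = int(np.argmax([r[0] for r in results]))
    chosen = grid[best_i]
    final = MLP(task="binary", epochs=epochs, seed=seed, **chosen)
    final.fit(X, y)
    dev_scores = final.predict(X)
    threshold = select_threshold(dev_scores, y)
    return DatClassifier(model=final, feature_cols=feature_cols,
                         threshold=threshold, chosen=chosen,
                         cv_auc=results[best_i][0], cv_auprc=results[best_i][1])


def score_subject(clf: DatClassifier, features: np.ndarray):
    """(similarity in [0, 1], predicted label). A score exactly at the
    threshold is labeled DAT (boundary assigned to the positive class)."""
    if not clf.fitted:
        raise RuntimeError("classifier is not trained")
    features = np.atleast_2d(np.asarray(features, dtype=np.float64))
    sim = clf.model.predict(features)
    return sim, (sim >= clf.threshold).astype(int)


# ---------------------------------------------------------------------------
# W-scores
# ---------------------------------------------------------------------------

@dataclass
class WScoreModel:
    """Per-ROI normative model: coefficients (intercept, age, sex) of
    E_CU(A, S) and the residual SD sigma_CU, fitted on CU reference data."""

    coef: dict[str, np.ndarray]   # roi -> (b0, b_age, b_sex)
    sigma: dict[str, float]       # roi -> sigma_CU
    n_reference: int
    sigma_denominator: str = "n-3"


def fit_wscore_model(reference: pd.DataFrame,
                     rois: list[str] | None = None,
                     sigma_denominator: str = "n-3") -> WScoreModel:
    """OLS of each CSF ROI volume on (1, age, sex) over a CU reference.

    sigma_CU is the residual standard error with denominator n - 3 (the
    residual degrees of freedom); pass sigma_denominator="n-1" for the plain
    residual SD. A near-zero sigma (< 1e-8 x mean reference volume) marks a
    degenerate normative model and raises.
    """
    rois = rois or CSF_FEATURES
    n = len(reference)
    if n <= 3:
        raise ValueError(f"reference cohort too small (n={n}, need > 3)")
    if "dx" in reference.columns and reference["dx"].any():
        raise ValueError("reference cohort must be all CU (dx == 0)")
    age = reference["age"].to_numpy(dtype=np.float64)
    sex = reference["sex"].to_numpy(dtype=np.float64)
    if age.std() == 0 and sex.std() == 0:
        raise ValueError("collinear reference design: single age and single sex")
    design = np.column_stack([np.ones(n), age, sex])
    ddof = 3 if sigma_denominator == "n-3" else 1
    coef, sigma = {}, {}
    for roi in rois:
        v = reference[roi].to_numpy(dtype=np.float64)
        beta, *_ = np.linalg.lstsq(design, v, rcond=None)
        resid = v - design @ beta
        s = float(np.sqrt((resid**2).sum() / (n - ddof)))
        if s < 1e-8 * max(abs(v.mean()), 1e-300):
            raise ValueError(f"degenerate sigma_CU for ROI '{roi}' "
                             f"({s:.3g}): reference volumes are (near) exactly "
                             "linear in age and sex")
        coef[roi] = beta
        sigma[roi] = s
    return WScoreModel(coef=coef, sigma=sigma, n_reference=n,
                       sigma_denominator=sigma_denominator)


def compute_wscore(model: WScoreModel, roi: str, volume, age, sex):
    """W = (V - E_CU(A, S)) / sigma_CU; larger CSF volume => larger W."""
    if roi not in model.coef:
        raise KeyError(f"no fitted W-score model for ROI '{roi}'")
    b0, b_age, b_sex = model.coef[roi]
    expected = b0 + b_age * np.asarray(age, dtype=np.float64) \
        + b_sex * np.asarray(sex, dtype=np.float64)
    return (np.asarray(volume, dtype=np.float64) - expected) / model.sigma[roi]


# ---------------------------------------------------------------------------
# Brain age and BAI
# ---------------------------------------------------------------------------

@dataclass
class BrainAgeModel:
    model: MLP
    feature_cols: list[str]
    chosen: dict
    cv_rmse: float

    @property
    def fitted(self) -> bool:
        return self.model is not None and self.model.fitted


def train_brainage_model(
    table: pd.DataFrame,
    truth_col: str = "brain_age",
    feature_cols: list[str] | None = None,
    grid: list[dict] | None = None,
    cv: tuple[int, int] = (10, 10),
    seed: int = 0,
    epochs: int = 200,
) -> BrainAgeModel:
    """MLP regression of true brain age on (7 CSF volumes, age, sex); grid
    point with minimum mean CV RMSE selected and refit on the full table."""
    feature_cols = feature_cols or CSF_FEATURES + ["age", "sex"]
    grid = grid if grid is not None else desk_mlp_grid()
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    y = table[truth_col].to_numpy(dtype=np.float64)
    if np.any(~np.isfinite(y)):
        raise ValueError("non-finite brain-age truth")
    X = _feature_matrix(table, feature_cols)
    reps, folds = cv
    ids = list(table["id"]) if "id" in table.columns else list(range(len(table)))
    splits = kfold_splits(ids, k=folds, repeats=reps, seed=seed)
    id_pos = {s: i for i, s in enumerate(ids)}
    rmses = []
    for hp in grid:
        vals = []
        for rep in splits:
            for train_ids, val_ids in rep:
                tr = [id_pos[i] for i in train_ids]
                va = [id_pos[i] for i in val_ids]
                mlp = MLP(task="regression", epochs=epochs, seed=seed, **hp)
                mlp.fit(X[tr], y[tr])
                resid = mlp.predict(X[va]) - y[va]
                vals.append(float(np.sqrt(np.mean(resid**2))))
        rmses.append(float(np.mean(vals)))
    best_i = int(np.argmin(rmses))
    chosen = grid[best_i]
    final = MLP(task="regression", epochs=epochs, seed=seed, **chosen)
    final.fit(X, y)
    return BrainAgeModel(model=final, feature_cols=feature_cols,
                         chosen=chosen, cv_rmse=rmses[best_i])


def compute_bai(model: BrainAgeModel, features: np.ndarray,
                chronological_age) -> np.ndarray:
    """BAI (years) = predicted brain age - chronological age."""
    if not model.fitted:
        raise RuntimeError("brain-age model is not trained")
    features = np.atleast_2d(np.asarray(features, dtype=np.float64))
    pred = model.model.predict(features)
    return pred - np.asarray(chronological_age, dtype=np.float64)
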