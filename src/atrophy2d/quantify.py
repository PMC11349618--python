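"""From predicted label stacks to scalar measures.

Each subject's segmented-pixel count per ROI (summed over the slice stack)
plus age and sex feeds an independent two-hidden-layer MLP regressor per ROI
whose target is the 3D-derived ground truth (CSF volume in mm^3 or lobar
cortical thickness in mm). Hyperparameters are selected by repeated k-fold
cross-validation (default 10 x 10-fold) on minimum mean RMSE, then the
winning configuration is refit on the full table.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import SliceStack
from .nn import MLP
from .phantom import ROI_NAMES
from .pipeline import kfold_splits

log = logging.getLogger(__name__)

__all__ = [
    "roi_pixel_sum",
    "build_feature_table",
    "RoiRegressor",
    "train_roi_regressor",
    "predict_measure",
    "full_mlp_grid",
    "desk_mlp_grid",
]

FEATURE_COLS = ["id", "age", "sex", "dx"]


def roi_pixel_sum(stack: SliceStack, roi: int) -> int:
    """Total segmented-pixel count for one ROI across the stack (exact int)."""
    if stack.labels is None:
        raise ValueError("stack carries no label slices")
    if len(stack) == 0:
        raise ValueError("empty stack")
    if roi not in ROI_NAMES:
        raise ValueError(f"unknown ROI code {roi}; valid codes: "
                         f"{sorted(ROI_NAMES)}")
    return int(np.count_nonzero(stack.labels == roi))


def build_feature_table(stacks: list[SliceStack],
                        covariates: pd.DataFrame) -> pd.DataFrame:
    """One row per subject: id, age, sex, dx, then the 11 ROI pixel sums
    (columns named after the ROI with a `_px` suffix, in label-code order).
    Join on id is exact; a stack without covariates is an error."""
    cov = covariates.set_index("id")
    rows = []
    for stack in stacks:
        if stack.subject_id not in cov.index:
            raise KeyError(f"no covariate row for subject {stack.subject_id}")
        row = {"id": stack.subject_id}
        for c in ("age", "sex", "dx"):
            if c in cov.columns:
                row[c] = cov.loc[stack.subject_id, c]
        for code, name in ROI_NAMES.items():
            row[f"{name}_px"] = roi_pixel_sum(stack, code)
        rows.append(row)
    return pd.DataFrame(rows)


# The printed MLP hyperparameter grid (1200 combinations).
FULL_MLP_GRID = {
    "batch_size": (16, 48, 64, 68, 96),
    "dropout": (0.3, 0.4, 0.5),
    "lr": (3e-4, 3e-3),
    "weight_decay": (1e-4, 1e-3),
    "hidden1": (16, 32, 64, 128),
    "hidden2": (4, 8, 16, 32, 64),
}


def _expand(grid: dict) -> list[dict]:
    keys = list(grid)
    return [dict(zip(keys, combo))
            for combo in itertools.product(*(grid[k] for k in keys))]


def full_mlp_grid() -> list[dict]:
    """All Cartesian-product combinations of the full grid."""
    return _expand(FULL_MLP_GRID)


def desk_mlp_grid() -> list[dict]:
    """A small default grid for CPU-scale runs."""
    return [
        {"hidden1": 32, "hidden2": 16, "dropout": 0.3, "lr": 3e-3,
         "weight_decay": 1e-4, "batch_size": 64},
        {"hidden1": 16, "hidden2": 8, "dropout": 0.3, "lr": 3e-3,
         "weight_decay": 1e-4, "batch_size": 64},
    ]


@dataclass
class RoiRegressor:
    """Per-ROI regressor: selected MLP + its repeated-CV RMSE summary."""

    roi: str
    model: MLP
    chosen: dict
    cv_rmse: float
    cv_table: pd.DataFrame = field(repr=False, default=None)

    def predict(self, features: np.ndarray) -> np.ndarray:
        return predict_measure(self, features)


def _cv_rmse(X: np.ndarray, y: np.ndarray, ids: list, hp: dict,
             splits, epochs: int, seed: int) -> float:
    """Mean of fold-level RMSEs over all repeats x folds."""
    id_pos = {s: i for i, s in enumerate(ids)}
    rmses = []
    for rep in splits:
        for train_ids, val_ids in rep:
            tr = [id_pos[i] for i in train_ids]
            va = [id_pos[i] for i in val_ids]
            mlp = MLP(task="regression", epochs=epochs, seed=seed, **hp)
            mlp.fit(X[tr], y[tr])
            resid = mlp.predict(X[va]) - y[va]
            rmses.append(float(np.sqrt(np.mean(resid**2))))
    return float(np.mean(rmses))


def train_roi_regressor(
    table: pd.DataFrame,
    roi: str,
    truth_col: str | None = None,
    grid: list[dict] | None = None,
    cv: tuple[int, int] = (10, 10),
    seed: int = 0,
    epochs: int = 200,
) -> RoiRegressor:
    """Select hyperparameters by repeated-CV minimum mean RMSE, refit on the
    full table.

    `roi` is an ROI name (see phantom.ROI_NAMES); features are the ROI pixel
    sum, age, and sex; the truth column defaults to the ROI name itself.
    CV assignments are subject-level, seeded, and shared across grid points.
    """
    grid = grid if grid is not None else desk_mlp_grid()
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    truth_col = truth_col or roi
    if truth_col not in table.columns:
        raise ValueError(f"truth column '{truth_col}' missing from table")
    y = table[truth_col].to_numpy(dtype=np.float64)
    if np.any(~np.isfinite(y)):
        raise ValueError(f"non-finite truth values in '{truth_col}'")
    X = table[[f"{roi}_px", "age", "sex"]].to_numpy(dtype=np.float64)
    reps, folds = cv
    if len(table) < folds:
        raise ValueError(f"need at least {folds} subjects for {folds}-fold CV")
    ids = list(table["id"])
    splits = kfold_splits(ids, k=folds, repeats=reps, seed=seed)
    records = []
    for gi, hp in enumerate(grid):
        rmse = _cv_rmse(X, y, ids, hp, splits, epochs, seed)
        records.append({**hp, "cv_rmse": rmse})
        log.info("%s grid %d/%d: RMSE %.4f", roi, gi + 1, len(grid), rmse)
    cv_table = pd.DataFrame(records)
    best_i = int(cv_table["cv_rmse"].idxmin())
    chosen = grid[best_i]
    final = MLP(task="regression", epochs=epochs, seed=seed, **chosen)
    final.fit(X, y)
    return RoiRegressor(roi=roi, model=final, chosen=chosen,
                        cv_rmse=float(cv_table.loc[best_i, "cv_rmse"]),
                        cv_table=cv_table)


def predict_measure(reg: RoiRegressor, features: np.ndarray) -> np.ndarray:
    """Predict the ROI measure (mm^3 or mm) for (pixel sum, age, sex) rows."""
    features = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if np.any(features[:, 0] < 0):
        raise ValueError("pixel sums cannot be negative")
    return reg.model.predict(features)
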