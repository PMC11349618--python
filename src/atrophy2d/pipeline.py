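"""Orchestration: seeded cross-validation splits shared by every stage, and
the end-to-end run from phantom generation to biomarker report.

The pipeline executes simulate -> preprocess -> segment -> quantify ->
biomarkers -> stats on a single global seed, holds out a test subject set
that no fit ever sees, and writes a manifest with per-output SHA-256
checksums so a rerun with the same config can be verified bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["kfold_splits", "RunConfig", "PipelineResult", "run_pipeline"]


def kfold_splits(ids, k: int, repeats: int = 1, seed: int = 0):
    """Repeated k-fold subject splits.

    Returns a list with one entry per repeat; each entry is a list of
    (train_ids, validation_ids) tuples. Within a repeat the folds are
    disjoint, exhaust the ids, and differ in size by at most one; repeats
    use fresh shuffles of the same seeded stream.
    """
    ids = list(ids)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if len(ids) < k:
        raise ValueError(f"need at least {k} ids for {k} folds, got {len(ids)}")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(repeats):
        order = rng.permutation(len(ids))
        folds = np.array_split(order, k)
        rep = []
        for f in folds:
            val = [ids[i] for i in f]
            val_set = set(val)
            train = [s for s in ids if s not in val_set]
            rep.append((train, val))
        out.append(rep)
    return out


@dataclass(frozen=True)
class RunConfig:
    """End-to-end run configuration (desk preset by default)."""

    n_cu: int = 60
    n_dat: int = 60
    preset: str = "desk"
    seed: int = 1
    out_dir: str = "runs/desk"
    atrophy_effect: bool = True      # False: c_dx = 0 and no DAT horn gain
    stride: int = 5
    test_fraction: float = 1.0 / 3.0
    seg_train_subjects: int = 12     # development subjects used to fit the FCN
    seg_slice_step: int = 2          # take every k-th stack slice for training
    seg_epochs: int = 30
    seg_batch_size: int = 4
    cv_reps: int = 2                 # pipeline-internal repeated-CV budget
    cv_folds: int = 5
    mlp_epochs: int = 200
    ref_n_cu: int = 40               # isolated CU reference for the W-scores
    stages: tuple[str, ...] = ("simulate", "preprocess", "segment",
                               "quantify", "biomarkers", "stats")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    config: RunConfig
    truth_table: pd.DataFrame
    feature_table: pd.DataFrame | None = None
    volume_table: pd.DataFrame | None = None
    biomarker_table: pd.DataFrame | None = None
    dsc: dict | None = None                 # roi name -> per-test-subject DSC
    volume_r: dict | None = None            # roi name -> pearson report
    classifier_metrics: dict | None = None
    bai_summary: dict | None = None
    seg_model: object | None = None
    regressors: dict | None = None
    classifier: object | None = None
    wscore_model: object | None = None
    brainage_model: object | None = None
    test_ids: list = field(default_factory=list)
    dev_ids: list = field(default_factory=list)
    manifest: dict | None = None
    manifest_path: Path | None = None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, index=False, float_format="%.10g")
    return _sha256(path)


def run_pipeline(config: RunConfig, pretrained: PipelineResult | None = None
                 ) -> PipelineResult:
    """Run the full study on a phantom cohort.

    `pretrained` reuses a previous run's segmentation model and ROI
    regressors (the measurement machinery) on a freshly generated cohort —
    e.g. to score a null cohort without re-fitting the imaging stages. The
    classifier, W-score and brain-age models are always fitted on the new
    cohort's development split.
    """
    from . import biomarkers as bm
    from . import phantom, quantify, segnet, stats
    from .imaging import extract_slices
    from .phantom import CSF_ROIS, ROI_NAMES

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    # --- simulate ---------------------------------------------------------
    params_kw = {} if config.atrophy_effect else {"c_dx": 0.0, "hipp_dx_gain": 0.0}
    params = (phantom.desk_params(**params_kw) if config.preset == "desk"
              else phantom.clinical_params(**params_kw))
    log.info("simulating cohort: %d CU + %d DAT (%s preset)",
             config.n_cu, config.n_dat, config.preset)
    cohort = phantom.generate_cohort(config.n_cu, config.n_dat, params,
                                     seed=config.seed)
    truth = cohort.truth_table

    # --- preprocess -------------------------------------------------------
    stacks = []
    for vol, lab, t in zip(cohort.volumes, cohort.label_volumes, cohort.truths):
        stacks.append(extract_slices(vol, labels=lab, stride=config.stride,
                                     subject_id=t.subject_id))
    by_id = {s.subject_id: s for s in stacks}

    # development / held-out test split, stratified by diagnosis
    ids = list(truth["id"])
    dx = truth.set_index("id")["dx"]
    test_ids: list[str] = []
    for g in (0, 1):
        g_ids = [i for i in ids if dx[i] == g]
        n_test = int(round(len(g_ids) * config.test_fraction))
        pick = rng.choice(len(g_ids), size=n_test, replace=False)
        test_ids.extend(g_ids[i] for i in sorted(pick))
    test_set = set(test_ids)
    dev_ids = [i for i in ids if i not in test_set]

    result = PipelineResult(config=config, truth_table=truth,
                            test_ids=test_ids, dev_ids=dev_ids)

    # --- segment ----------------------------------------------------------
    if "segment" in config.stages:
        seg_ids = dev_ids[: config.seg_train_subjects]
        step = config.seg_slice_step
        images = np.concatenate([by_id[i].images[::step] for i in seg_ids])
        labels = np.concatenate([by_id[i].labels[::step] for i in seg_ids])
        zs = np.concatenate([segnet.stack_zs(by_id[i])[::step]
                             for i in seg_ids])
        seg_cfg = segnet.SegConfig(epochs=config.seg_epochs,
                                   batch_size=config.seg_batch_size,
                                   seed=config.seed)
        log.info("training segmentation on %d slices from %d subjects",
                 len(images), len(seg_ids))
        result.seg_model = segnet.train_segmentation(images, labels, seg_cfg,
                                                     zs=zs)
    elif pretrained is not None:
        result.seg_model = pretrained.seg_model
    else:
        raise ValueError("segment stage disabled and no pretrained model given")

    pred_stacks = {i: segnet.predict_segmentation(result.seg_model, by_id[i])
                   for i in ids}

    # held-out Dice, pooled counts per subject
    roi_codes = tuple(range(1, 12))
    dsc = {ROI_NAMES[c]: [] for c in roi_codes}
    for i in test_ids:
        for c in roi_codes:
            dsc[ROI_NAMES[c]].append(
                stats.dice(pred_stacks[i].labels == c, by_id[i].labels == c))
    result.dsc = {k: np.asarray(v) for k, v in dsc.items()}

    # --- quantify ---------------------------------------------------------
    feats = quantify.build_feature_table(list(pred_stacks.values()),
                                         truth[["id", "age", "sex", "dx"]])
    feats = feats.merge(truth.drop(columns=["age", "sex", "dx"]), on="id")
    result.feature_table = feats
    dev_mask = feats["id"].isin(dev_ids)
    if "quantify" in config.stages:
        regs = {}
        for code in roi_codes:
            name = ROI_NAMES[code]
            regs[name] = quantify.train_roi_regressor(
                feats[dev_mask], name, cv=(config.cv_reps, config.cv_folds),
                seed=config.seed, epochs=config.mlp_epochs)
        result.regressors = regs
    elif pretrained is not None:
        result.regressors = pretrained.regressors
    else:
        raise ValueError("quantify stage disabled and no pretrained "
                         "regressors given")

    vol_tab = feats[["id", "age", "sex", "dx"]].copy()
    for code in roi_codes:
        name = ROI_NAMES[code]
        X = feats[[f"{name}_px", "age", "sex"]].to_numpy(dtype=np.float64)
        vol_tab[name] = quantify.predict_measure(result.regressors[name], X)
    result.volume_table = vol_tab

    test_mask = vol_tab["id"].isin(test_ids)
    result.volume_r = {}
    for code in roi_codes:
        name = ROI_NAMES[code]
        result.volume_r[name] = stats.pearson_with_ci(
            vol_tab.loc[test_mask, name], feats.loc[test_mask, name])

    # --- biomarkers -------------------------------------------------------
    if "biomarkers" in config.stages:
        dev_vol = vol_tab[vol_tab["id"].isin(dev_ids)]
        test_vol = vol_tab[test_mask]
        clf = bm.train_dat_classifier(dev_vol, cv=(config.cv_reps,
                                                   config.cv_folds),
                                      seed=config.seed,
                                      epochs=config.mlp_epochs)
        Xt = test_vol[clf.feature_cols].to_numpy(dtype=np.float64)
        sim, labels_hat = bm.score_subject(clf, Xt)
        y_test = test_vol["dx"].to_numpy(dtype=int)
        metrics = stats.roc_pr_metrics(sim, y_test, threshold=clf.threshold)
        result.classifier = clf
        result.classifier_metrics = metrics

        # isolated CU reference cohort for the normative model, measured with
        # the same segmentation + regression machinery
        ref = phantom.generate_cohort(config.ref_n_cu, 0, params,
                                      seed=config.seed + 10_000)
        ref_stacks = [extract_slices(v, labels=l, stride=config.stride,
                                     subject_id=t.subject_id)
                      for v, l, t in zip(ref.volumes, ref.label_volumes,
                                         ref.truths)]
        ref_feats = quantify.build_feature_table(
            [segnet.predict_segmentation(result.seg_model, s)
             for s in ref_stacks],
            ref.truth_table[["id", "age", "sex", "dx"]])
        ref_vol = ref_feats[["id", "age", "sex", "dx"]].copy()
        for code in CSF_ROIS:
            name = ROI_NAMES[code]
            X = ref_feats[[f"{name}_px", "age", "sex"]].to_numpy(np.float64)
            ref_vol[name] = quantify.predict_measure(result.regressors[name], X)
        wmodel = bm.fit_wscore_model(ref_vol)
        result.wscore_model = wmodel

        dev_cu = dev_vol[dev_vol["dx"] == 0].merge(
            truth[["id", "brain_age"]], on="id")
        bam = bm.train_brainage_model(dev_cu, cv=(config.cv_reps,
                                                  config.cv_folds),
                                      seed=config.seed,
                                      epochs=config.mlp_epochs)
        result.brainage_model = bam
        Xb = test_vol[bam.feature_cols].to_numpy(dtype=np.float64)
        bai = bm.compute_bai(bam, Xb, test_vol["age"].to_numpy())

        bio = test_vol[["id", "age", "sex", "dx"]].copy()
        bio["similarity"] = sim
        bio["predicted_label"] = labels_hat
        for code in CSF_ROIS:
            name = ROI_NAMES[code]
            bio[f"w_{name}"] = bm.compute_wscore(
                wmodel, name, test_vol[name].to_numpy(),
                test_vol["age"].to_numpy(), test_vol["sex"].to_numpy())
        bio["bai"] = bai
        result.biomarker_table = bio
        result.bai_summary = {
            "mean_bai_cu": float(bio.loc[bio.dx == 0, "bai"].mean()),
            "mean_bai_dat": float(bio.loc[bio.dx == 1, "bai"].mean()),
        }

    # --- report / manifest ------------------------------------------------
    checksums = {}
    checksums["truth.csv"] = _write_csv(truth, out_dir / "truth.csv")
    checksums["features.csv"] = _write_csv(feats, out_dir / "features.csv")
    checksums["volumes.csv"] = _write_csv(vol_tab, out_dir / "volumes.csv")
    if result.biomarker_table is not None:
        checksums["biomarkers.csv"] = _write_csv(result.biomarker_table,
                                                 out_dir / "biomarkers.csv")
    dsc_tab = pd.DataFrame({k: v for k, v in result.dsc.items()})
    dsc_tab.insert(0, "id", test_ids)
    checksums["dsc.csv"] = _write_csv(dsc_tab, out_dir / "dsc.csv")
    manifest = {
        "config": config.to_dict(),
        "stages": list(config.stages),
        "dev_ids": dev_ids,
        "test_ids": test_ids,
        "checksums": checksums,
    }
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    result.manifest = manifest
    result.manifest_path = mpath
    log.info("pipeline complete; manifest at %s", mpath)
    return result
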