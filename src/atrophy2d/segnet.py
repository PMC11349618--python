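"""Encoder-decoder fully-convolutional segmentation of the 12-class axial
label problem (background + 11 ROIs).

The network is a U-style FCN: an encoder of convolution + batch-norm + ReLU
stages with 2x max-pooling, a mirrored decoder of nearest-neighbour
upsampling + convolution stages, and skip connections feeding each of the
last three encoder stages into its corresponding decoder stage. Training
minimizes sparse softmax cross-entropy (unweighted) plus an L2 weight
penalty with Adam; augmentation randomly flips image+label horizontally and
shifts the raw-intensity brightness in U[-50, 50] before per-slice Z-score
normalization.

Because lobar ROIs are defined by their position in the head, the network
internally appends fixed normalized coordinate channels to its input: two
in-plane coordinate maps plus one constant slice-position channel (the
axial index normalized across the head extent, which any acquisition knows
for each slice). The public contract is still one image channel in, 12
class maps out. Without these a small desk-scale encoder cannot tell, say,
frontal from occipital eCSF (identical intensity, mirrored position) or
parietal from temporal eCSF (distinguished only by slice height).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .imaging import SliceStack, znormalize
from .stats import dice

log = logging.getLogger(__name__)

__all__ = [
    "SegConfig",
    "SegModel",
    "build_model",
    "augment_sample",
    "train_segmentation",
    "predict_segmentation",
    "stack_zs",
    "crossval_segmentation",
    "evaluate_dsc",
]

N_CLASSES = 12


@dataclass(frozen=True)
class SegConfig:
    """Segmentation hyperparameters.

    The "full" preset carries the selected clinical-scale values (batch 4,
    dropout 0.5, lr 1e-4, weight decay 1e-5, wide inception-style stages);
    the "desk" preset is a width-reduced three-stage variant for CPU-scale
    phantoms.
    """

    preset: str = "desk"
    n_classes: int = N_CLASSES
    batch_size: int = 4
    dropout: float = 0.5
    learning_rate: float = 1e-2
    weight_decay: float = 1e-4
    epochs: int = 30
    flip_prob: float = 0.5
    brightness_range: float = 50.0
    base_channels: int = 8
    n_stages: int = 3
    seed: int = 0
    grid: tuple = ()   # optional tuple of SegConfig variants for grid search

    def __post_init__(self):
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


def full_config(**overrides) -> SegConfig:
    defaults = dict(preset="full", batch_size=4, dropout=0.5,
                    learning_rate=1e-4, weight_decay=1e-5, base_channels=32,
                    n_stages=4)
    defaults.update(overrides)
    return SegConfig(**defaults)


# printed hyperparameter grid for the segmentation stage
SEG_GRID = {
    "batch_size": (2, 4),
    "dropout": (0.4, 0.5, 0.6),
    "learning_rate": (1e-3, 1e-4, 1e-5),
    "weight_decay": (1e-4, 1e-3),
}


def seg_grid_configs(base: SegConfig | None = None) -> list[SegConfig]:
    """All Cartesian-product combinations of the segmentation grid."""
    base = base or SegConfig()
    keys = list(SEG_GRID)
    return [replace(base, **dict(zip(keys, combo)))
            for combo in itertools.product(*(SEG_GRID[k] for k in keys))]


class SegModel:
    """U-style FCN with explicit forward/backward wiring."""

    def __init__(self, config: SegConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config.base_channels
        self.stage_channels = [c * (2**i) for i in range(config.n_stages)]
        in_ch = 4  # image + 2 in-plane coordinate channels + slice position
        self.enc_convs, self.enc_bns = [], []
        for ch in self.stage_channels:
            self.enc_convs.append(nn.Conv2d(in_ch, ch, 3, rng))
            self.enc_bns.append(nn.BatchNorm2d(ch))
            in_ch = ch
        self.pool = nn.MaxPool2d()
        self.up = nn.UpsampleNearest2d()
        self.bott_conv = nn.Conv2d(in_ch, in_ch, 3, rng)
        self.bott_bn = nn.BatchNorm2d(in_ch)
        self.dec_convs, self.dec_bns = [], []
        self.n_skips = min(3, config.n_stages)  # last three encoder stages skip
        prev = in_ch
        for i, ch in enumerate(reversed(self.stage_channels)):
            cin = prev + (ch if i < self.n_skips else 0)
            self.dec_convs.append(nn.Conv2d(cin, ch, 3, rng))
            self.dec_bns.append(nn.BatchNorm2d(ch))
            prev = ch
        self.head = nn.Conv2d(prev, config.n_classes, 1, rng)
        self.relu = nn.ReLU
        self.dropout = nn.Dropout(config.dropout, rng)
        self.loss_history: list[float] = []
        self.trained = False

    # ------------------------------------------------------------------
    def params(self) -> list[nn.Param]:
        layers = (self.enc_convs + self.enc_bns + [self.bott_conv, self.bott_bn]
                  + self.dec_convs + self.dec_bns + [self.head])
        return [p for layer in layers for p in layer.params()]

    @property
    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    @staticmethod
    def _pad_to_multiple(x: np.ndarray, mult: int):
        h, w = x.shape[1:3]
        ph, pw = (-h) % mult, (-w) % mult
        if ph or pw:
            log.info("padding %dx%d input by (%d, %d) to match the "
                     "downsampling factor %d", h, w, ph, pw, mult)
            x = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)))
        return x, (h, w)

    def forward(self, images: np.ndarray, train: bool = False,
                zs: np.ndarray | None = None) -> np.ndarray:
        """images: (N, H, W) normalized slices -> (N, H, W, n_classes).

        zs: optional per-slice axial position in [-1, 1]; defaults to 0.
        """
        images = np.asarray(images, dtype=np.float32)
        n, h0, w0 = images.shape
        yy, xx = np.meshgrid(np.linspace(-1, 1, h0, dtype=np.float32),
                             np.linspace(-1, 1, w0, dtype=np.float32),
                             indexing="ij")
        coords = np.broadcast_to(np.stack([yy, xx], axis=-1), (n, h0, w0, 2))
        if zs is None:
            zmap = np.zeros((n, h0, w0, 1), dtype=np.float32)
        else:
            zmap = np.broadcast_to(
                np.asarray(zs, dtype=np.float32)[:, None, None, None],
                (n, h0, w0, 1))
        x = np.concatenate([images[..., None], coords, zmap], axis=-1)
        x, self._orig_hw = self._pad_to_multiple(x, 2**self.config.n_stages)

        self._acts = []
        skips = []
        self._relus = []
        for conv, bn in zip(self.enc_convs, self.enc_bns):
            r = self.relu()
            x = r.forward(bn.forward(conv.forward(x, train), train), train)
            self._relus.append(r)
            skips.append(x)
            x = self.pool.forward(x, train)
            self._acts.append(("pool", self.pool))
            # each pool layer must keep its own cache: clone state
            self._acts[-1] = ("pool", _snap_pool(self.pool))
        rb = self.relu()
        x = rb.forward(self.bott_bn.forward(self.bott_conv.forward(x, train),
                                            train), train)
        self._relus.append(rb)
        x = self.dropout.forward(x, train)
        self._skip_shapes = []
        ups = []
        n_dec = len(self.dec_convs)
        for i, (conv, bn) in enumerate(zip(self.dec_convs, self.dec_bns)):
            up = _FreshUpsample()
            x = up.forward(x, train)
            ups.append(up)
            skip = skips[-(i + 1)]
            if i < self.n_skips:
                self._skip_shapes.append(skip.shape[-1])
                x = np.concatenate([x, skip], axis=-1)
            else:
                self._skip_shapes.append(0)
            r = self.relu()
            x = r.forward(bn.forward(conv.forward(x, train), train), train)
            self._relus.append(r)
        self._ups = ups
        logits = self.head.forward(x, train)
        h, w = self._orig_hw
        return logits[:, :h, :w, :]

    def backward(self, grad_logits: np.ndarray) -> None:
        mult = 2**self.config.n_stages
        n, h, w, k = grad_logits.shape
        ph, pw = (-h) % mult, (-w) % mult
        g = np.pad(grad_logits, ((0, 0), (0, ph), (0, pw), (0, 0)))
        g = self.head.backward(g)
        relus = list(self._relus)
        n_dec = len(self.dec_convs)
        skip_grads: dict[int, np.ndarray] = {}
        for i in reversed(range(n_dec)):
            g = relus.pop().backward(g)
            g = self.dec_bns[i].backward(g)
            g = self.dec_convs[i].backward(g)
            sk = self._skip_shapes[i]
            if sk:
                skip_grads[len(self.enc_convs) - 1 - i] = g[..., -sk:]
                g = g[..., :-sk]
            g = self._ups[i].backward(g)
        g = self.dropout.backward(g)
        g = relus.pop().backward(g)
        g = self.bott_bn.backward(g)
        g = self.bott_conv.backward(g)
        for i in reversed(range(len(self.enc_convs))):
            g = self._acts[i][1].backward(g)
            if i in skip_grads:
                g = g + skip_grads[i]
            g = relus.pop().backward(g)
            g = self.enc_bns[i].backward(g)
            g = self.enc_convs[i].backward(g)

    def predict(self, images: np.ndarray,
                zs: np.ndarray | None = None) -> np.ndarray:
        """Argmax class map for a batch of *normalized* (N, H, W) slices."""
        logits = self.forward(images, train=False, zs=zs)
        return logits.argmax(axis=-1).astype(np.int16)


class _FreshUpsample(nn.UpsampleNearest2d):
    pass


def _snap_pool(pool: nn.MaxPool2d) -> nn.MaxPool2d:
    snap = nn.MaxPool2d()
    snap._argmax = pool._argmax
    snap._xshape = pool._xshape
    return snap


def build_model(config: SegConfig) -> SegModel:
    """Construct an untrained model; same seed gives identical parameters."""
    model = SegModel(config)
    log.info("segmentation model built: %d stages, %d parameters",
             config.n_stages, model.n_params)
    return model


def augment_sample(image: np.ndarray, label: np.ndarray,
                   rng: np.random.Generator, flip_prob: float = 0.5,
                   brightness_range: float = 50.0):
    """Random horizontal flip of image+label together and a brightness offset
    drawn U[-range, range] added to the raw image only."""
    if image.shape != label.shape:
        raise ValueError("image and label must share a shape")
    if rng.random() < flip_prob:
        # first in-plane axis is left-right in the axial slice layout
        image = image[::-1, :].copy()
        label = label[::-1, :].copy()
    offset = rng.uniform(-brightness_range, brightness_range)
    return image + offset, label


def _validate_labels(labels: np.ndarray, n_classes: int) -> None:
    lo, hi = int(labels.min()), int(labels.max())
    if lo < 0 or hi >= n_classes:
        raise ValueError(f"label values must lie in [0, {n_classes - 1}], "
                         f"found range [{lo}, {hi}]")


def stack_zs(stack: SliceStack) -> np.ndarray:
    """Per-slice axial position normalized to [-1, 1] over the stack's own
    head extent; the constant-position channel fed to the network."""
    idx = stack.indices.astype(np.float64)
    span = idx.max() - idx.min()
    if span == 0:
        return np.zeros(len(idx), dtype=np.float32)
    return (2.0 * (idx - idx.min()) / span - 1.0).astype(np.float32)


def train_segmentation(images: np.ndarray, labels: np.ndarray,
                       config: SegConfig,
                       zs: np.ndarray | None = None) -> SegModel:
    """Train on raw (N, H, W) slices + integer label slices.

    Augmentation runs on raw intensities; Z-score normalization is applied
    per slice afterwards, matching the inference-time normalization. `zs`
    optionally carries each slice's normalized axial position (see
    stack_zs); it defaults to zero for position-free training.
    """
    images = np.asarray(images, dtype=np.float64)
    labels = np.asarray(labels)
    if len(images) < 1:
        raise ValueError("at least one training slice is required")
    _validate_labels(labels, config.n_classes)
    if zs is None:
        zs = np.zeros(len(images), dtype=np.float32)
    model = build_model(config)
    # initialize the classification bias at the empirical log class priors:
    # rare structures (ventricles) otherwise spend many updates just
    # overcoming the background-dominated output distribution
    counts = np.bincount(labels.reshape(-1).astype(np.int64),
                         minlength=config.n_classes).astype(np.float64)
    priors = (counts + 1.0) / (counts.sum() + config.n_classes)
    model.head.b.value[...] = np.log(priors).astype(np.float32)
    rng = np.random.default_rng(config.seed + 1)
    opt = nn.Adam(model.params(), lr=config.learning_rate,
                  weight_decay=config.weight_decay)
    n = len(images)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch_x, batch_y = [], []
            for i in idx:
                img, lab = augment_sample(images[i], labels[i], rng,
                                          config.flip_prob,
                                          config.brightness_range)
                batch_x.append(znormalize(img))
                batch_y.append(lab)
            bx = np.stack(batch_x)
            by = np.stack(batch_y)
            logits = model.forward(bx, train=True, zs=zs[idx])
            loss, grad = nn.softmax_cross_entropy(logits, by)
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            epoch_loss += loss * len(idx)
        model.loss_history.append(epoch_loss / n)
        log.info("epoch %d/%d loss %.4f", epoch + 1, config.epochs,
                 model.loss_history[-1])
    model.trained = True
    return model


def predict_segmentation(model: SegModel, stack: SliceStack) -> SliceStack:
    """Predict per-pixel labels for a stack; output aligned to input indices."""
    norm = np.stack([znormalize(img) for img in stack.images])
    zs = stack_zs(stack)
    preds = []
    for start in range(0, len(norm), 16):  # bounded memory
        preds.append(model.predict(norm[start : start + 16],
                                   zs=zs[start : start + 16]))
    pred = np.concatenate(preds)
    return SliceStack(subject_id=stack.subject_id, images=stack.images,
                      indices=stack.indices, labels=pred)


def evaluate_dsc(model: SegModel, stacks: list[SliceStack],
                 rois: tuple[int, ...] = tuple(range(1, N_CLASSES))):
    """Per-subject DSC (counts pooled over the full stack), per ROI.

    Returns {roi: array of per-subject DSC}.
    """
    out = {roi: [] for roi in rois}
    for stack in stacks:
        if stack.labels is None:
            raise ValueError(f"stack {stack.subject_id} has no reference labels")
        pred = predict_segmentation(model, stack)
        for roi in rois:
            out[roi].append(dice(pred.labels == roi, stack.labels == roi))
    return {roi: np.asarray(v) for roi, v in out.items()}


def crossval_segmentation(stacks: list[SliceStack], config: SegConfig,
                          k: int = 5, seed: int = 0) -> dict:
    """Subject-level k-fold cross-validation; never splits by slice.

    Returns per-ROI mean DSC with a normal-approximation 95% CI across
    held-out subjects.
    """
    from .pipeline import kfold_splits

    if len(stacks) < k:
        raise ValueError(f"need at least {k} subjects for {k}-fold CV, "
                         f"got {len(stacks)}")
    ids = [s.subject_id for s in stacks]
    by_id = {s.subject_id: s for s in stacks}
    rois = tuple(range(1, config.n_classes))
    per_subject = {roi: {} for roi in rois}
    for train_ids, val_ids in kfold_splits(ids, k=k, repeats=1, seed=seed)[0]:
        tr = [by_id[i] for i in train_ids]
        images = np.concatenate([s.images for s in tr])
        labels = np.concatenate([s.labels for s in tr])
        zs = np.concatenate([stack_zs(s) for s in tr])
        model = train_segmentation(images, labels, config, zs=zs)
        scores = evaluate_dsc(model, [by_id[i] for i in val_ids], rois)
        for roi in rois:
            for sid, d in zip(val_ids, scores[roi]):
                per_subject[roi][sid] = d
    report = {}
    for roi in rois:
        vals = np.asarray([per_subject[roi][i] for i in ids])
        mean = vals.mean()
        half = 1.959963984540054 * vals.std(ddof=1) / np.sqrt(len(vals)) \
            if len(vals) > 1 else 0.0
        report[roi] = {"dsc_mean": float(mean), "ci_low": float(mean - half),
                       "ci_high": float(mean + half),
                       "per_subject": vals}
    return report
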