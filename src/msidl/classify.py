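"""1-D CNN spectrum classifier with stratified k-fold cross-validation.

Each pixel spectrum is treated as an independent, singly-labeled sample.
The architecture is the study design: ``n_conv_blocks`` blocks of
[same-padding conv -> leaky ReLU -> max pool] followed by one fully
connected layer producing raw class scores; training minimizes softmax
cross-entropy with Adam. Cross-validation is pixel-stratified: within each
class, pixels are randomly permuted (seeded) and dealt round-robin into k
folds, so per-class fold sizes differ by at most one. Note that pixels of
one core may then span training and test folds; ``split_by='core'`` gives a
leakage-safe alternative that stratifies whole cores instead.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .io import MSIDataset
from .nn import (Adam, Conv1d, Dense, Flatten, LeakyReLU, MaxPool1d,
                 Sequential, cross_entropy, softmax)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ArchConfig:
    """Architecture hyperparameters. Only depth and layer types are part of
    the study design; channel/kernel/pool sizes are exposed here with
    defaults sized for desk-scale axes of a few thousand bins."""

    n_conv_blocks: int = 6
    channels: tuple[int, ...] = (8, 16, 32, 64, 128, 128)
    kernel_size: int = 9
    pool_size: int = 4
    activation_slope: float = 0.01
    n_classes: int = 8

    def validate(self) -> None:
        if self.n_conv_blocks < 1:
            raise ValueError("need at least one conv block")
        if len(self.channels) != self.n_conv_blocks:
            raise ValueError(
                f"{len(self.channels)} channel counts for {self.n_conv_blocks} blocks")
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise ValueError("kernel_size must be odd and positive")
        if self.pool_size < 1 or self.n_classes < 2:
            raise ValueError("pool_size >= 1 and n_classes >= 2 required")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    epochs: int = 30
    batch_size: int = 64
    seed: int = 7
    k_folds: int = 5
    split_by: str = "pixel"        # "pixel" (study protocol) or "core"

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.split_by not in ("pixel", "core"):
            raise ValueError("split_by must be 'pixel' or 'core'")


@dataclass
class TrainedModel:
    """Architecture descriptor + weights (opaque) + fixed class order."""

    arch: ArchConfig
    net: Sequential
    class_order: list[str]
    n_bins: int

    def forward(self, spectra: np.ndarray, batch: int = 256) -> np.ndarray:
        """Raw class scores for (n, n_bins) spectra."""
        spectra = np.atleast_2d(np.asarray(spectra, dtype=np.float32))
        if spectra.shape[1] != self.n_bins:
            raise ValueError(f"expected {self.n_bins} bins, got {spectra.shape[1]}")
        out = []
        for lo in range(0, len(spectra), batch):
            x = spectra[lo:lo + batch, None, :]
            out.append(self.net.forward(x))
        return np.concatenate(out, axis=0) if out else np.empty((0, self.arch.n_classes))

    def predict(self, spectra: np.ndarray) -> np.ndarray:
        scores = self.forward(spectra)
        return np.array([self.class_order[i] for i in scores.argmax(axis=1)],
                        dtype=object)


def build_model(arch: ArchConfig, n_bins: int, class_order: list[str] | None = None,
                seed: int = 0) -> TrainedModel:
    """Initialize the CNN for an ``n_bins``-long input axis.

    Raises a configuration error, naming the offending block, if pooling
    collapses the sequence length to zero before the dense layer.
    """
    arch.validate()
    rng = np.random.default_rng(seed)
    layers: list = []
    c_prev, length = 1, n_bins
    for b in range(arch.n_conv_blocks):
        layers.append(Conv1d(c_prev, arch.channels[b], arch.kernel_size, rng))
        layers.append(LeakyReLU(arch.activation_slope))
        length = length // arch.pool_size
        if length < 1:
            raise ValueError(
                f"conv block {b}: pooling by {arch.pool_size} collapses the "
                f"sequence to length 0 (n_bins={n_bins})")
        layers.append(MaxPool1d(arch.pool_size))
        c_prev = arch.channels[b]
    layers.append(Flatten())
    layers.append(Dense(c_prev * length, arch.n_classes, rng))
    order = class_order if class_order is not None else [
        f"class_{i}" for i in range(arch.n_classes)]
    if len(order) != arch.n_classes:
        raise ValueError("class_order length must equal n_classes")
    return TrainedModel(arch=arch, net=Sequential(layers),
                        class_order=list(order), n_bins=n_bins)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldAssignment:
    """Fold index in 0..k-1 for every pixel; per class, fold sizes differ by
    at most one (ratio preservation)."""

    folds: np.ndarray
    k: int

    def validate(self, labels: np.ndarray) -> None:
        for cls in np.unique(labels):
            counts = np.bincount(self.folds[labels == cls], minlength=self.k)
            if counts.max() - counts.min() > 1:
                raise AssertionError(f"class {cls!r} folds unbalanced: {counts}")


def stratified_folds(dataset: MSIDataset, k: int, seed: int = 0,
                     split_by: str = "pixel") -> FoldAssignment:
    """Deal pixels (or whole cores) of each class round-robin into k folds
    after a seeded within-class shuffle."""
    rng = np.random.default_rng(seed)
    labels = dataset.labels
    folds = np.full(dataset.n_pixels, -1, dtype=np.int64)
    if split_by == "core":
        cores = np.asarray(dataset.core_ids)
        amap = {a.core_id: a.label for a in dataset.annotations}
        by_class: dict[str, list[str]] = {}
        for cid in dict.fromkeys(cores.tolist()):        # stable order
            by_class.setdefault(amap[cid], []).append(cid)
        for cls, cids in by_class.items():
            if len(cids) < k:
                raise ValueError(f"class {cls!r} has {len(cids)} cores < k={k}")
            perm = rng.permutation(len(cids))
            for j, pi in enumerate(perm):
                folds[cores == cids[pi]] = j % k
    else:
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            if len(idx) < k:
                raise ValueError(f"class {cls!r} has {len(idx)} pixels < k={k}")
            perm = rng.permutation(len(idx))
            folds[idx[perm]] = np.arange(len(idx)) % k
    assert (folds >= 0).all()
    fa = FoldAssignment(folds=folds, k=k)
    if split_by == "pixel":
        fa.validate(labels)
    return fa


@dataclass
class PredictionSet:
    """Held-out predictions: one record per evaluated pixel."""

    true_labels: np.ndarray        # object (class names)
    pred_labels: np.ndarray
    scores: np.ndarray             # (n, n_classes) raw scores
    fold: np.ndarray               # fold each pixel was held out in
    core_ids: np.ndarray
    coords: np.ndarray             # (n, 2)
    class_order: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.true_labels)

    @property
    def correct(self) -> np.ndarray:
        return self.true_labels == self.pred_labels

    def overall_accuracy(self) -> float:
        """Held-out per-pixel accuracy in percent."""
        return 100.0 * float(self.correct.mean())


def train_cv(dataset: MSIDataset, arch: ArchConfig, cfg: TrainConfig,
             ) -> tuple[list[TrainedModel], PredictionSet]:
    """Stratified k-fold cross-validation of the CNN.

    For each fold f, a freshly initialized model is trained on the other
    folds and evaluated on fold f, so every pixel is predicted exactly once
    by a model that never saw it. Fully seeded; reproducible run-to-run on
    one platform.
    """
    arch.validate()
    cfg.validate()
    labels = dataset.labels
    class_to_idx = {c: i for i, c in enumerate(dataset.class_order)}
    y = np.array([class_to_idx[c] for c in labels], dtype=np.int64)
    X = dataset.intensities.astype(np.float32)
    fa = stratified_folds(dataset, cfg.k_folds, seed=cfg.seed, split_by=cfg.split_by)

    models: list[TrainedModel] = []
    pred_idx = np.zeros(dataset.n_pixels, dtype=np.int64)
    scores_all = np.zeros((dataset.n_pixels, arch.n_classes), dtype=np.float64)
    rng = np.random.default_rng(cfg.seed + 104729)       # batch-order stream
    for f in range(cfg.k_folds):
        test = np.flatnonzero(fa.folds == f)
        train = np.flatnonzero(fa.folds != f)
        model = build_model(arch, dataset.n_bins, dataset.class_order,
                            seed=cfg.seed * 1013 + f)
        opt = Adam(model.net.params(), lr=cfg.learning_rate)
        for epoch in range(cfg.epochs):
            perm = train[rng.permutation(len(train))]
            for lo in range(0, len(perm), cfg.batch_size):
                sel = perm[lo:lo + cfg.batch_size]
                xb = X[sel][:, None, :]
                logits = model.net.forward(xb, keep=True)
                loss, dz = cross_entropy(logits, y[sel])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at fold {f}, epoch {epoch}: "
                        f"loss={loss}, |logits|max={np.abs(logits).max()}")
                model.net.backward(dz)
                opt.step(model.net.grads())
        sc = model.forward(X[test])
        scores_all[test] = sc
        pred_idx[test] = sc.argmax(axis=1)
        models.append(model)
        log.info("fold %d: held-out accuracy %.1f%%", f,
                 100.0 * (pred_idx[test] == y[test]).mean())

    preds = PredictionSet(
        true_labels=labels,
        pred_labels=np.array([dataset.class_order[i] for i in pred_idx], dtype=object),
        scores=scores_all,
        fold=fa.folds.copy(),
        core_ids=np.asarray(dataset.core_ids).copy(),
        coords=np.asarray(dataset.coords).copy(),
        class_order=list(dataset.class_order),
    )
    return models, preds


def per_class_accuracy(preds: PredictionSet) -> dict[str, float | None]:
    """Per-class held-out accuracy in percent, computed per fold and averaged
    over folds (a class absent from the predictions maps to None)."""
    if len(preds) == 0:
        raise ValueError("empty prediction set")
    out: dict[str, float | None] = {}
    for cls in preds.class_order:
        vals = []
        for f in np.unique(preds.fold):
            sel = (preds.fold == f) & (preds.true_labels == cls)
            if sel.any():
                vals.append(100.0 * float(preds.correct[sel].mean()))
        out[cls] = float(np.mean(vals)) if vals else None
    return out


# ---------------------------------------------------------------------------
# checkpoints and prediction TSV
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path: str) -> None:
    """Self-describing single-file checkpoint (npz with embedded metadata)."""
    meta = {
        "arch": {
            "n_conv_blocks": model.arch.n_conv_blocks,
            "channels": list(model.arch.channels),
            "kernel_size": model.arch.kernel_size,
            "pool_size": model.arch.pool_size,
            "activation_slope": model.arch.activation_slope,
            "n_classes": model.arch.n_classes,
        },
        "class_order": model.class_order,
        "n_bins": model.n_bins,
    }
    arrays = {f"param_{i}": p for i, p in enumerate(model.net.params())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path: str) -> TrainedModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        arch = ArchConfig(
            n_conv_blocks=meta["arch"]["n_conv_blocks"],
            channels=tuple(meta["arch"]["channels"]),
            kernel_size=meta["arch"]["kernel_size"],
            pool_size=meta["arch"]["pool_size"],
            activation_slope=meta["arch"]["activation_slope"],
            n_classes=meta["arch"]["n_classes"],
        )
        model = build_model(arch, meta["n_bins"], meta["class_order"], seed=0)
        for i, p in enumerate(model.net.params()):
            p[...] = data[f"param_{i}"]
    return model


def save_predictions(preds: PredictionSet, path: str) -> None:
    cols = "\t".join(f"score_{c}" for c in preds.class_order)
    with open(path, "w") as fh:
        fh.write(f"x\ty\tcore_id\ttrue\tpred\tfold\t{cols}\n")
        for i in range(len(preds)):
            sc = "\t".join(f"{v:.6g}" for v in preds.scores[i])
            fh.write(f"{preds.coords[i, 0]}\t{preds.coords[i, 1]}\t"
                     f"{preds.core_ids[i]}\t{preds.true_labels[i]}\t"
                     f"{preds.pred_labels[i]}\t{preds.fold[i]}\t{sc}\n")


def load_predictions(path: str) -> PredictionSet:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        class_order = [h[len("score_"):] for h in header if h.startswith("score_")]
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    n = len(rows)
    coords = np.array([[int(r[0]), int(r[1])] for r in rows], dtype=np.int64)
    return PredictionSet(
        true_labels=np.array([r[3] for r in rows], dtype=object),
        pred_labels=np.array([r[4] for r in rows], dtype=object),
        scores=np.array([[float(v) for v in r[6:6 + len(class_order)]]
                         for r in rows], dtype=np.float64).reshape(n, len(class_order)),
        fold=np.array([int(r[5]) for r in rows], dtype=np.int64),
        core_ids=np.array([r[2] for r in rows], dtype=object),
        coords=coords,
        class_order=class_order,
    )
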