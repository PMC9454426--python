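"""DeepLift attribution (rescale rule) for the 1-D CNN.

Contribution scores are computed by backward multiplier propagation from a
target class score to the input bins, relative to a reference spectrum:

* linear layers (conv, dense) propagate multipliers through their weights,
  exactly like gradients — the bias cancels in the difference-from-reference;
* leaky ReLU uses the rescale rule ``m_in = m_out * (dy/dx)`` where
  dy and dx are differences from the reference activation, falling back to
  the pointwise derivative where ``|dx|`` is below a small epsilon;
* max pooling routes the multiplier to the argmax position of the *actual*
  input, scaled by the rescale ratio of pooled output to routed input.

This construction satisfies summation-to-delta: the input contributions sum
to ``score(x) - score(reference)`` for the target class (up to the epsilon
fallback and float round-off). All attribution arithmetic runs in float64.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .classify import PredictionSet, TrainedModel
from .io import MSIDataset
from .nn import Conv1d, Dense, Flatten, LeakyReLU, MaxPool1d

log = logging.getLogger(__name__)

#: |delta input| below which the rescale rule falls back to the derivative.
RESCALE_EPS = 1e-7


def _forward_trace(model: TrainedModel, x: np.ndarray) -> list[np.ndarray]:
    """Per-layer activations in float64: [input, after layer 0, ...]."""
    trace = [x.astype(np.float64)]
    a = trace[0]
    for layer in model.net.layers:
        a = layer.forward(a, keep=False)
        trace.append(a)
    return trace


def deeplift_batch(model: TrainedModel, spectra: np.ndarray, target_class: int,
                   reference: np.ndarray) -> np.ndarray:
    """DeepLift contributions for a batch of spectra toward one class.

    Parameters
    ----------
    spectra : ndarray, shape (n, n_bins)
    target_class : int
        Index into the model's class order.
    reference : ndarray, shape (n_bins,)
        Baseline spectrum the contributions are measured against.

    Returns
    -------
    ndarray, shape (n, n_bins) of signed contribution scores.
    """
    spectra = np.atleast_2d(np.asarray(spectra, dtype=np.float64))
    reference = np.asarray(reference, dtype=np.float64).reshape(-1)
    if spectra.shape[1] != model.n_bins or reference.size != model.n_bins:
        raise ValueError(
            f"spectrum/reference length must be {model.n_bins}, got "
            f"{spectra.shape[1]}/{reference.size}")
    n = spectra.shape[0]
    xa = spectra[:, None, :]
    xr = reference[None, None, :]
    trace_a = _forward_trace(model, xa)
    trace_r = _forward_trace(model, xr)

    m = np.zeros((n, model.arch.n_classes), dtype=np.float64)
    m[:, target_class] = 1.0
    for i in range(len(model.net.layers) - 1, -1, -1):
        layer = model.net.layers[i]
        x_a, x_r = trace_a[i], trace_r[i]
        y_a, y_r = trace_a[i + 1], trace_r[i + 1]
        if isinstance(layer, Dense):
            m = m @ layer.W.astype(np.float64)
        elif isinstance(layer, Flatten):
            m = m.reshape((n,) + x_a.shape[1:])
        elif isinstance(layer, Conv1d):
            m = layer.input_backward(m)
        elif isinstance(layer, LeakyReLU):
            dx = x_a - x_r
            dy = y_a - y_r
            small = np.abs(dx) < RESCALE_EPS
            ratio = np.where(small, layer.derivative(x_a),
                             dy / np.where(small, 1.0, dx))
            m = m * ratio
        elif isinstance(layer, MaxPool1d):
            p = layer.p
            _, c, lp = m.shape
            xr_a = x_a[:, :, :lp * p].reshape(n, c, lp, p)
            xr_rf = np.broadcast_to(x_r[:, :, :lp * p].reshape(1, c, lp, p),
                                    (n, c, lp, p))
            amax = xr_a.argmax(axis=3)
            xa_max = np.take_along_axis(xr_a, amax[..., None], axis=3)[..., 0]
            xr_max = np.take_along_axis(xr_rf, amax[..., None], axis=3)[..., 0]
            dy = y_a - y_r
            dxa = xa_max - xr_max
            # degenerate routing target (delta ~ 0 at the actual argmax):
            # fall back to the window position with the largest |delta|
            small = np.abs(dxa) < RESCALE_EPS
            alt = np.abs(xr_a - xr_rf).argmax(axis=3)
            route = np.where(small, alt, amax)
            dxa = (np.take_along_axis(xr_a, route[..., None], axis=3)
                   - np.take_along_axis(xr_rf, route[..., None], axis=3))[..., 0]
            flat = np.abs(dxa) < RESCALE_EPS        # whole window at the reference
            ratio = np.where(flat, 1.0, dy / np.where(flat, 1.0, dxa))
            routed = np.zeros((n, c, lp, p), dtype=np.float64)
            np.put_along_axis(routed, route[..., None], (m * ratio)[..., None], axis=3)
            routed = routed.reshape(n, c, lp * p)
            if x_a.shape[2] > lp * p:                   # truncated tail: zero multiplier
                routed = np.pad(routed, ((0, 0), (0, 0), (0, x_a.shape[2] - lp * p)))
            m = routed
        else:                                           # pragma: no cover
            raise TypeError(f"unsupported layer {type(layer).__name__}")
    contrib = (m * (xa - xr)).sum(axis=1)               # collapse channel dim
    if not np.all(np.isfinite(contrib)):
        raise FloatingPointError("non-finite DeepLift contribution")
    return contrib


def deeplift_attribute(model: TrainedModel, spectrum: np.ndarray, target_class: int,
                       reference: np.ndarray) -> np.ndarray:
    """Contribution vector of one spectrum toward ``target_class``."""
    return deeplift_batch(model, spectrum[None, :], target_class, reference)[0]


def summation_check(model: TrainedModel, spectra: np.ndarray, target_class: int,
                    reference: np.ndarray) -> float:
    """Max relative deviation of sum(contributions) from score(x)-score(ref)."""
    spectra = np.atleast_2d(np.asarray(spectra, dtype=np.float64))
    contrib = deeplift_batch(model, spectra, target_class, reference)
    sa = _forward_trace(model, spectra[:, None, :])[-1][:, target_class]
    sr = _forward_trace(model, reference[None, None, :])[-1][0, target_class]
    delta = sa - float(sr)
    scale = np.maximum(np.abs(delta), 1.0)
    return float(np.max(np.abs(contrib.sum(axis=1) - delta) / scale))


# ---------------------------------------------------------------------------
# class-level pooling and top-k masses
# ---------------------------------------------------------------------------

@dataclass
class AttributionResult:
    """Per-class mean DeepLift contribution vectors over bins.

    ``vectors[class]`` is None when the class had no correctly classified
    held-out pixel. ``aggregation`` documents how pixel scores were pooled.
    """

    vectors: dict[str, np.ndarray | None]
    reference: np.ndarray
    aggregation: str
    bin_centers: np.ndarray


def class_attribution(models: list[TrainedModel], dataset: MSIDataset,
                      preds: PredictionSet, batch: int = 256) -> AttributionResult:
    """Average DeepLift contributions per class over its correctly classified
    held-out pixels, each pixel attributed through the model of its own fold,
    against an all-zero reference spectrum."""
    if len(preds) != dataset.n_pixels:
        raise ValueError("predictions do not cover the dataset")
    reference = np.zeros(dataset.n_bins, dtype=np.float64)
    class_order = preds.class_order
    vectors: dict[str, np.ndarray | None] = {}
    X = dataset.intensities
    for ci, cls in enumerate(class_order):
        sel = np.flatnonzero((preds.true_labels == cls) & preds.correct)
        if sel.size == 0:
            log.warning("class %s: no correctly classified pixel, empty attribution", cls)
            vectors[cls] = None
            continue
        total = np.zeros(dataset.n_bins, dtype=np.float64)
        for f in np.unique(preds.fold[sel]):
            idx = sel[preds.fold[sel] == f]
            for lo in range(0, len(idx), batch):
                chunk = idx[lo:lo + batch]
                total += deeplift_batch(models[int(f)], X[chunk], ci,
                                        reference).sum(axis=0)
        vectors[cls] = total / sel.size
    return AttributionResult(
        vectors=vectors,
        reference=reference,
        aggregation="mean over correctly classified held-out pixels, "
                    "per-fold models, zero reference",
        bin_centers=dataset.scheme.bin_centers,
    )


@dataclass
class TopKMasses:
    """Per class, the masses (bin centers) with the largest positive
    contribution, in descending score order."""

    masses: dict[str, list[tuple[float, float]]]   # class -> [(mz, score), ...]
    k: int

    def pooled(self) -> list[tuple[str, float, float]]:
        """All (class, mz, score) entries across classes."""
        return [(cls, mz, sc) for cls, lst in self.masses.items()
                for mz, sc in lst]


def top_k_masses(attr: AttributionResult, k: int = 10) -> TopKMasses:
    """The k bins of largest positive contribution per class, as bin-center
    m/z, descending by score with ties broken toward lower m/z; classes with
    fewer than k positive bins yield shorter lists."""
    if k < 1:
        raise ValueError("k must be >= 1")
    out: dict[str, list[tuple[float, float]]] = {}
    for cls, vec in attr.vectors.items():
        if vec is None:
            out[cls] = []
            continue
        pos = np.flatnonzero(vec > 0)
        order = pos[np.lexsort((attr.bin_centers[pos], -vec[pos]))]
        out[cls] = [(float(attr.bin_centers[i]), float(vec[i])) for i in order[:k]]
    return TopKMasses(masses=out, k=k)


def save_top_k(topk: TopKMasses, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("class\trank\tmz\tscore\n")
        for cls, lst in topk.masses.items():
            for rank, (mz, sc) in enumerate(lst, start=1):
                fh.write(f"{cls}\t{rank}\t{mz:.5f}\t{sc:.6g}\n")
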