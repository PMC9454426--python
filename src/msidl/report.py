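"""Spatial and core-level reporting: correctness maps, core majority votes,
and narrow-window ion images."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .classify import PredictionSet
from .io import CoreAnnotation, MSIDataset

log = logging.getLogger(__name__)


def classification_map(preds: PredictionSet, dataset: MSIDataset) -> np.ndarray:
    """RGB raster of the pixel grid: green = correctly classified spectrum,
    red = misclassification, black = unimaged background."""
    if len(preds) == 0:
        return np.zeros((1, 1, 3), dtype=np.uint8)
    w = int(preds.coords[:, 0].max()) + 1
    h = int(preds.coords[:, 1].max()) + 1
    img = np.zeros((h, w, 3), dtype=np.uint8)
    ok = preds.correct
    xs, ys = preds.coords[:, 0], preds.coords[:, 1]
    img[ys[ok], xs[ok]] = (0, 255, 0)
    img[ys[~ok], xs[~ok]] = (255, 0, 0)
    return img


def save_png(img: np.ndarray, path: str, upscale: int = 4) -> None:
    """Write an RGB or grayscale raster as PNG (nearest-neighbor upscaled)."""
    from PIL import Image

    arr = np.repeat(np.repeat(img, upscale, axis=0), upscale, axis=1)
    Image.fromarray(arr).save(path)


@dataclass
class CoreVoteResult:
    """Per-core majority label, its vote fraction, and correctness."""

    votes: dict[str, tuple[str, float, bool]]    # core -> (label, fraction, correct)

    @property
    def fraction_correct(self) -> float:
        if not self.votes:
            return float("nan")
        return float(np.mean([ok for _, _, ok in self.votes.values()]))

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("core_id\tmajority_label\tvote_fraction\tcorrect\n")
            for cid, (lab, frac, ok) in sorted(self.votes.items()):
                fh.write(f"{cid}\t{lab}\t{frac:.4f}\t{int(ok)}\n")


def core_majority_vote(preds: PredictionSet,
                       annotations: list[CoreAnnotation]) -> CoreVoteResult:
    """Assign every core the modal predicted label over its pixels.

    Ties are broken by the higher mean raw score for the tied class, then by
    lexicographic class order. A core without predicted pixels is excluded
    with a warning. ``correct`` compares the majority label with the core's
    annotation.
    """
    truth = {a.core_id: a.label for a in annotations}
    votes: dict[str, tuple[str, float, bool]] = {}
    class_idx = {c: i for i, c in enumerate(preds.class_order)}
    for a in annotations:
        sel = np.flatnonzero(preds.core_ids == a.core_id)
        if sel.size == 0:
            log.warning("core %s has no predicted pixels; excluded from vote", a.core_id)
            continue
        labs, counts = np.unique(preds.pred_labels[sel].astype(str), return_counts=True)
        top = counts.max()
        tied = [str(l) for l, n in zip(labs, counts) if n == top]
        if len(tied) > 1:
            mean_scores = {l: float(preds.scores[sel, class_idx[l]].mean())
                           for l in tied}
            best = max(mean_scores.values())
            tied = sorted(l for l, s in mean_scores.items() if s == best)
        winner = tied[0]
        votes[a.core_id] = (winner, float(top / sel.size),
                            winner == truth[a.core_id])
    return CoreVoteResult(votes=votes)


@dataclass
class IonImage:
    """Narrow-window ion intensity on the pixel grid.

    ``values`` holds the raw per-pixel window sums (export for quantitative
    use); ``grid_raw``/``grid_rel`` are rasters with NaN off-grid, the
    relative one scaled by the per-image maximum.
    """

    mz: float
    window: float
    values: np.ndarray
    grid_raw: np.ndarray
    grid_rel: np.ndarray

    def save(self, path: str, upscale: int = 4) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.cm as cm

        g = np.nan_to_num(self.grid_rel, nan=0.0)
        rgba = (cm.viridis(g) * 255).astype(np.uint8)
        rgba[np.isnan(self.grid_rel)] = (0, 0, 0, 255)
        save_png(rgba[..., :3], path, upscale=upscale)


def ion_image(dataset: MSIDataset, mz: float, window: float = 0.003) -> IonImage:
    """Sum each pixel's intensity over the bins intersecting
    ``[mz - window, mz + window]`` and raster it on the grid with a relative
    (per-image maximum) scale."""
    bins = dataset.scheme.mz_window_bins(mz, window)
    if bins.size == 0:
        raise ValueError(
            f"window [{mz - window:.5f}, {mz + window:.5f}] does not intersect "
            f"the axis [{dataset.scheme.lo_mz}, {dataset.scheme.hi_mz})")
    values = dataset.intensities[:, bins].sum(axis=1).astype(np.float64)
    w = int(dataset.coords[:, 0].max()) + 1 if dataset.n_pixels else 1
    h = int(dataset.coords[:, 1].max()) + 1 if dataset.n_pixels else 1
    grid = np.full((h, w), np.nan)
    grid[dataset.coords[:, 1], dataset.coords[:, 0]] = values
    peak = np.nanmax(grid) if dataset.n_pixels else np.nan
    rel = grid / peak if peak and np.isfinite(peak) and peak > 0 else grid * 0.0
    return IonImage(mz=float(mz), window=float(window), values=values,
                    grid_raw=grid, grid_rel=rel)
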