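"""Spectral preprocessing: re-binning, off-tissue exclusion, matrix-peak
correlation filtering, and per-pixel min-max normalization.

The pipeline order is rebin -> mask_off_tissue -> matrix_filter ->
normalize_minmax, so the classifier always receives [0, 1] inputs and the
matrix filter sees raw (co-varying) intensities. No baseline removal or
global normalization is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import (BinningScheme, CoreAnnotation, MSIDataset, RawSpectra,
                 ValidationError)

log = logging.getLogger(__name__)


def rebin(raw: RawSpectra, scheme: BinningScheme,
          annotations: list[CoreAnnotation] | None = None,
          class_order: Sequence[str] | None = None) -> MSIDataset:
    """Re-bin raw spectra onto the equidistant axis of ``scheme``.

    Each raw point's intensity is added to the bin whose half-open interval
    contains its m/z; points outside ``[lo_mz, hi_mz)`` are dropped, so the
    total in-range intensity is conserved exactly.
    """
    if scheme.n_bins < 1:
        raise ValueError("empty binning scheme")
    n = len(raw)
    out = np.zeros((n, scheme.n_bins), dtype=np.float64)
    for i, (mz, inten) in enumerate(zip(raw.mzs, raw.intensities)):
        if mz.size == 0:
            continue
        idx = scheme.bin_index(mz)
        keep = idx >= 0
        np.add.at(out[i], idx[keep], np.asarray(inten, dtype=np.float64)[keep])
    core_ids = np.array([c if c else f"px_{x}_{y}"
                         for c, (x, y) in zip(raw.core_ids, raw.coords)], dtype=object)
    if annotations is None:
        annotations = [CoreAnnotation(str(c), "unlabeled",
                                      frozenset({(int(x), int(y))}))
                       for c, (x, y) in zip(core_ids, raw.coords)]
        class_order = ["unlabeled"]
    # keep float64: conservation of total intensity is part of the contract
    ds = MSIDataset(scheme, out, raw.coords, core_ids,
                    annotations, list(class_order or []))
    ds.validate()
    return ds


def normalize_minmax(dataset: MSIDataset) -> MSIDataset:
    """Scale every pixel spectrum to [0, 1] by its own min and max.

    Constant spectra (max == min) map to all-zeros rather than NaN, keeping
    downstream tensors finite. Idempotent.
    """
    out = dataset.copy()
    x = out.intensities.astype(np.float32)
    mn = x.min(axis=1, keepdims=True)
    mx = x.max(axis=1, keepdims=True)
    span = mx - mn
    flat = span[:, 0] == 0
    span[flat] = 1.0
    x = (x - mn) / span
    x[flat] = 0.0
    out.intensities = x
    return out


def mask_off_tissue(dataset: MSIDataset, matrix_class: str = "Matrix") -> MSIDataset:
    """Drop in-core pixels that carry no tissue.

    Pixels outside their core's tissue mask are removed — except pixels of
    cores annotated with the dedicated matrix class, which by definition
    contain no tissue and are retained wholesale. A tissue core whose mask
    removes every pixel is kept in the annotations but logged as a warning.
    """
    tissue = dataset.tissue
    labels = dataset.labels
    keep = tissue | (labels == matrix_class)
    kept_cores = set(dataset.core_ids[keep])
    for a in dataset.annotations:
        if a.label != matrix_class and a.core_id not in kept_cores:
            log.warning("core %s (%s): empty tissue mask, all pixels removed",
                        a.core_id, a.label)
    return dataset.subset(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# matrix-peak correlation filter
# ---------------------------------------------------------------------------

@dataclass
class MatrixFilterReport:
    """What the matrix filter removed and why.

    ``selected_peaks`` holds (m/z, Pearson correlation with the reference
    peak) sorted by descending correlation; ``zeroed_intervals`` the
    corresponding [mz - w, mz + w] windows clipped to the axis.
    """

    reference_mz: float
    selected_peaks: list[tuple[float, float]]
    zeroed_intervals: list[tuple[float, float]]

    def to_dict(self) -> dict:
        return {
            "reference_mz": self.reference_mz,
            "selected_peaks": [[mz, r] for mz, r in self.selected_peaks],
            "zeroed_intervals": [[lo, hi] for lo, hi in self.zeroed_intervals],
        }


def detect_peaks(dataset: MSIDataset) -> np.ndarray:
    """Peak apex bins: strict local maxima of the dataset-mean spectrum that
    exceed median + 3*MAD of that mean spectrum."""
    mean = dataset.intensities.mean(axis=0, dtype=np.float64)
    med = np.median(mean)
    mad = np.median(np.abs(mean - med))
    thr = med + 3.0 * mad
    interior = np.arange(1, len(mean) - 1)
    is_max = (mean[interior] > mean[interior - 1]) & (mean[interior] > mean[interior + 1])
    apex = interior[is_max & (mean[interior] > thr)]
    return apex


def matrix_filter(dataset: MSIDataset, n_filter: int = 500, window: float = 0.02,
                  matrix_class: str = "Matrix") -> tuple[MSIDataset, MatrixFilterReport]:
    """Zero out the ``n_filter`` peaks best correlated with the matrix peak.

    Procedure: (1) detect peaks as local maxima of the mean spectrum above a
    noise floor; (2) take as reference the detected peak of highest mean
    intensity over matrix-class pixels (falling back to the globally highest
    mean peak when no matrix-class pixel exists); (3) Pearson-correlate every
    peak's apex-bin intensity with the reference's across pixels; (4) select
    the top ``n_filter`` peaks by correlation, the reference always included;
    (5) set all bins within ± ``window`` Da of each selected apex to zero in
    every pixel.

    Correlations are computed on pre-normalization intensities; run this
    before :func:`normalize_minmax`.
    """
    if dataset.n_pixels < 2:
        raise ValidationError("matrix_filter needs at least 2 pixels")
    sch = dataset.scheme
    apex = detect_peaks(dataset)
    if apex.size == 0:
        return dataset.copy(), MatrixFilterReport(float("nan"), [], [])

    labels = dataset.labels
    matrix_pix = np.flatnonzero(labels == matrix_class)
    ref_basis = dataset.intensities[matrix_pix] if matrix_pix.size else dataset.intensities
    ref_apex = apex[int(np.argmax(ref_basis[:, apex].mean(axis=0)))]

    ref_col = dataset.intensities[:, ref_apex].astype(np.float64)
    if np.ptp(ref_col) == 0:
        raise ValidationError("degenerate correlation: reference bin is constant")
    X = dataset.intensities[:, apex].astype(np.float64)
    Xc = X - X.mean(axis=0)
    rc = ref_col - ref_col.mean()
    denom = np.sqrt((Xc ** 2).sum(axis=0)) * np.sqrt((rc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Xc * rc[:, None]).sum(axis=0) / denom
    corr[~np.isfinite(corr)] = -np.inf      # constant peak columns: never selected

    order = np.argsort(-corr, kind="stable")
    n_sel = min(n_filter, apex.size)
    sel = set(order[:n_sel].tolist())
    ref_pos = int(np.flatnonzero(apex == ref_apex)[0])
    if ref_pos not in sel:                   # reference always included
        sel.discard(order[n_sel - 1])
        sel.add(ref_pos)
    sel_idx = sorted(sel, key=lambda j: (-corr[j], apex[j]))

    centers = sch.bin_centers
    out = dataset.copy()
    selected_peaks, intervals = [], []
    for j in sel_idx:
        mz = float(centers[apex[j]])
        bins = sch.mz_window_bins(mz, window)
        out.intensities[:, bins] = 0.0
        selected_peaks.append((mz, float(corr[j])))
        intervals.append((max(mz - window, sch.lo_mz), min(mz + window, sch.hi_mz)))
    return out, MatrixFilterReport(float(centers[ref_apex]), selected_peaks, intervals)


def preprocess(dataset: MSIDataset, n_filter: int = 500, window: float = 0.02,
               matrix_class: str = "Matrix") -> tuple[MSIDataset, MatrixFilterReport]:
    """Full preprocessing chain for an already-binned dataset:
    mask_off_tissue -> matrix_filter -> normalize_minmax."""
    ds = mask_off_tissue(dataset, matrix_class=matrix_class)
    ds, report = matrix_filter(ds, n_filter=n_filter, window=window,
                               matrix_class=matrix_class)
    return normalize_minmax(ds), report
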