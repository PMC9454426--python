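"""Data model and I/O for MALDI mass-spectrometry-imaging (MSI) datasets.

The central container is :class:`MSIDataset`: pixel spectra on a shared
equidistant m/z axis (:class:`BinningScheme`) together with grid coordinates,
tissue-microarray (TMA) core membership and core-level class annotations.
Interchange format is imzML 1.1 (continuous mode, via :mod:`pyimzml`); a
single-file HDF5 container is provided for fast local round trips, and core
annotations travel as plain TSV.

Conventions
-----------
* Grid coordinates are 0-based internally (``x`` = column, ``y`` = row);
  imzML's 1-based coordinates are shifted on read/write.
* Bins are half-open, lower-inclusive: bin ``i`` covers
  ``[lo_mz + i*w, lo_mz + (i+1)*w)`` and its center is ``lo_mz + (i+0.5)*w``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import h5py
import numpy as np


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class ValidationError(ValueError):
    """Raised when data violate an MSIDataset invariant."""


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinningScheme:
    """Equidistant m/z axis shared by every stage of the pipeline.

    Parameters
    ----------
    lo_mz, hi_mz : float
        Mass range in Da. The axis covers ``[lo_mz, hi_mz)``.
    bin_width : float
        Bin width in Da.
    """

    lo_mz: float
    hi_mz: float
    bin_width: float

    def __post_init__(self) -> None:
        if not (self.lo_mz < self.hi_mz):
            raise ValueError(f"lo_mz ({self.lo_mz}) must be < hi_mz ({self.hi_mz})")
        if not (self.bin_width > 0):
            raise ValueError(f"bin_width must be positive, got {self.bin_width}")
        if self.n_bins < 1:
            raise ValueError("scheme yields zero bins")

    @property
    def n_bins(self) -> int:
        return int(np.floor((self.hi_mz - self.lo_mz) / self.bin_width))

    @property
    def bin_centers(self) -> np.ndarray:
        """Bin centers ``lo_mz + (i + 0.5) * bin_width`` as a float64 array."""
        return self.lo_mz + (np.arange(self.n_bins) + 0.5) * self.bin_width

    def bin_index(self, mz: np.ndarray | float) -> np.ndarray:
        """Bin index for each m/z; -1 where outside ``[lo_mz, hi_mz)``.

        The interval convention is half-open, lower-inclusive, so a point at
        exactly ``lo_mz`` lands in bin 0 and a point at exactly ``hi_mz`` is
        outside.
        """
        scalar = np.isscalar(mz) or np.ndim(mz) == 0
        mz = np.atleast_1d(np.asarray(mz, dtype=np.float64))
        idx = np.floor((mz - self.lo_mz) / self.bin_width).astype(np.int64)
        out = (mz < self.lo_mz) | (mz >= self.hi_mz) | (idx >= self.n_bins)
        idx[out] = -1
        return int(idx[0]) if scalar else idx

    def mz_window_bins(self, mz: float, window: float) -> np.ndarray:
        """Indices of bins whose interval intersects ``[mz - window, mz + window]``."""
        lo = int(np.floor((mz - window - self.lo_mz) / self.bin_width))
        hi = int(np.floor((mz + window - self.lo_mz) / self.bin_width))
        lo = max(lo, 0)
        hi = min(hi, self.n_bins - 1)
        if hi < lo:
            return np.empty(0, dtype=np.int64)
        return np.arange(lo, hi + 1, dtype=np.int64)


# ---------------------------------------------------------------------------
# annotations and pixels
# ---------------------------------------------------------------------------

@dataclass
class CoreAnnotation:
    """One TMA core: identifier, class label and the set of tissue pixels.

    ``tissue_mask`` holds the (x, y) pixels of the core flagged as containing
    tissue; core pixels absent from the mask are off-tissue (matrix only).
    """

    core_id: str
    label: str
    tissue_mask: frozenset[tuple[int, int]] = field(default_factory=frozenset)


@dataclass
class PixelSpectrum:
    """View of one pixel: grid position, core membership and binned intensities."""

    x: int
    y: int
    core_id: str
    intensities: np.ndarray


@dataclass
class RawSpectra:
    """Unbinned spectra as parallel (m/z array, intensity array) lists.

    Produced by :func:`read_imzml_raw`; consumed by ``preprocess.rebin``.
    """

    mzs: list[np.ndarray]
    intensities: list[np.ndarray]
    coords: np.ndarray          # (n, 2) int, 0-based (x, y)
    core_ids: list[str]

    def __len__(self) -> int:
        return len(self.mzs)


@dataclass
class MSIDataset:
    """Pixel spectra on a common binned axis plus core-level annotations.

    Attributes
    ----------
    scheme : BinningScheme
        The shared m/z axis.
    intensities : ndarray, shape (n_pixels, n_bins)
        Non-negative binned intensities, float32.
    coords : ndarray, shape (n_pixels, 2)
        0-based (x, y) grid positions, unique per pixel.
    core_ids : ndarray of str, shape (n_pixels,)
        Core membership of each pixel.
    annotations : list of CoreAnnotation
        One entry per core; every pixel's core must appear here.
    class_order : list of str
        Fixed, duplicate-free class ordering used by the classifier.
    """

    scheme: BinningScheme
    intensities: np.ndarray
    coords: np.ndarray
    core_ids: np.ndarray
    annotations: list[CoreAnnotation]
    class_order: list[str]

    # -- derived views ------------------------------------------------------

    @property
    def n_pixels(self) -> int:
        return int(self.intensities.shape[0])

    @property
    def n_bins(self) -> int:
        return int(self.intensities.shape[1])

    def annotation_map(self) -> dict[str, CoreAnnotation]:
        return {a.core_id: a for a in self.annotations}

    @property
    def labels(self) -> np.ndarray:
        """Per-pixel class label inherited from the pixel's core."""
        amap = {a.core_id: a.label for a in self.annotations}
        return np.array([amap[c] for c in self.core_ids], dtype=object)

    @property
    def tissue(self) -> np.ndarray:
        """Per-pixel boolean: is the pixel inside its core's tissue mask."""
        masks = {a.core_id: a.tissue_mask for a in self.annotations}
        return np.array(
            [(int(x), int(y)) in masks[c]
             for (x, y), c in zip(self.coords, self.core_ids)],
            dtype=bool,
        )

    def pixel(self, i: int) -> PixelSpectrum:
        return PixelSpectrum(
            x=int(self.coords[i, 0]),
            y=int(self.coords[i, 1]),
            core_id=str(self.core_ids[i]),
            intensities=self.intensities[i],
        )

    def __iter__(self) -> Iterator[PixelSpectrum]:
        return (self.pixel(i) for i in range(self.n_pixels))

    def subset(self, index: np.ndarray) -> "MSIDataset":
        """New dataset restricted to the given pixel index (annotations kept)."""
        index = np.asarray(index)
        return MSIDataset(
            scheme=self.scheme,
            intensities=self.intensities[index].copy(),
            coords=self.coords[index].copy(),
            core_ids=self.core_ids[index].copy(),
            annotations=list(self.annotations),
            class_order=list(self.class_order),
        )

    def copy(self) -> "MSIDataset":
        return self.subset(np.arange(self.n_pixels))

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        """Enforce the dataset invariants; raise ValidationError on violation."""
        if self.intensities.ndim != 2:
            raise ValidationError("intensities must be 2-D (pixels x bins)")
        if self.intensities.shape[1] != self.scheme.n_bins:
            raise ValidationError(
                f"spectra have {self.intensities.shape[1]} bins, "
                f"scheme defines {self.scheme.n_bins}"
            )
        if self.n_pixels and not np.all(np.isfinite(self.intensities)):
            raise ValidationError("non-finite intensity encountered")
        if self.n_pixels and self.intensities.min() < 0:
            raise ValidationError("negative intensity encountered")
        if len(self.coords) != self.n_pixels or len(self.core_ids) != self.n_pixels:
            raise ValidationError("coords/core_ids length mismatch")
        seen = set(map(tuple, np.asarray(self.coords).tolist()))
        if len(seen) != self.n_pixels:
            raise ValidationError("duplicate (x, y) coordinate")
        known = {a.core_id for a in self.annotations}
        missing = set(map(str, self.core_ids)) - known
        if missing:
            raise ValidationError(f"pixels reference unannotated cores: {sorted(missing)}")
        if len(set(self.class_order)) != len(self.class_order):
            raise ValidationError("class_order contains duplicates")
        labels = {a.label for a in self.annotations}
        unknown = labels - set(self.class_order)
        if unknown:
            raise ValidationError(f"labels outside class_order: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# annotations TSV
# ---------------------------------------------------------------------------

def write_annotations(annotations: Sequence[CoreAnnotation], path: str,
                      mask_path: str | None = None) -> None:
    """Write core labels as TSV (``core_id\\tlabel``) and, optionally, the
    per-pixel tissue mask as TSV (``x\\ty\\tcore_id\\ttissue``)."""
    with open(path, "w") as fh:
        fh.write("core_id\tlabel\n")
        for a in annotations:
            fh.write(f"{a.core_id}\t{a.label}\n")
    if mask_path is not None:
        with open(mask_path, "w") as fh:
            fh.write("x\ty\tcore_id\ttissue\n")
            for a in annotations:
                for (x, y) in sorted(a.tissue_mask):
                    fh.write(f"{x}\t{y}\t{a.core_id}\t1\n")


def read_annotations(path: str, mask_path: str | None = None,
                     class_order: Sequence[str] | None = None) -> list[CoreAnnotation]:
    """Read core annotations from TSV.

    Parameters
    ----------
    path : str
        TSV with header ``core_id\\tlabel``, one row per core.
    mask_path : str, optional
        TSV with header ``x\\ty\\tcore_id\\ttissue``; rows with tissue=1 form
        each core's tissue mask. A pixel claimed by two cores is rejected.
    class_order : sequence of str, optional
        If given, labels outside this set are rejected.

    Raises
    ------
    ValidationError
        On duplicate cores with conflicting labels, unknown labels, or a
        pixel referenced by two cores.
    """
    labels: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["core_id", "label"]:
            raise FormatError(f"unexpected annotation header {header!r} in {path}")
        for line in fh:
            if not line.strip():
                continue
            core_id, label = line.rstrip("\n").split("\t")[:2]
            if core_id in labels and labels[core_id] != label:
                raise ValidationError(
                    f"core {core_id!r} annotated with conflicting labels "
                    f"{labels[core_id]!r} and {label!r}"
                )
            labels[core_id] = label
    if class_order is not None:
        bad = sorted(set(labels.values()) - set(class_order))
        if bad:
            raise ValidationError(f"unknown class labels {bad}; expected {list(class_order)}")

    masks: dict[str, set[tuple[int, int]]] = {c: set() for c in labels}
    if mask_path is not None:
        owner: dict[tuple[int, int], str] = {}
        with open(mask_path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:4] != ["x", "y", "core_id", "tissue"]:
                raise FormatError(f"unexpected mask header {header!r} in {mask_path}")
            for line in fh:
                if not line.strip():
                    continue
                xs, ys, core_id, tis = line.rstrip("\n").split("\t")[:4]
                pix = (int(xs), int(ys))
                if pix in owner and owner[pix] != core_id:
                    raise ValidationError(
                        f"pixel {pix} referenced by cores {owner[pix]!r} and {core_id!r}"
                    )
                owner[pix] = core_id
                if core_id not in masks:
                    raise ValidationError(f"mask references unannotated core {core_id!r}")
                if int(tis):
                    masks[core_id].add(pix)
    return [CoreAnnotation(c, labels[c], frozenset(masks[c])) for c in labels]


# ---------------------------------------------------------------------------
# imzML
# ---------------------------------------------------------------------------

def _sidecar_paths(path: str) -> tuple[str, str]:
    stem = path[:-6] if path.lower().endswith(".imzml") else path
    return stem + ".annotations.tsv", stem + ".mask.tsv"


def write_imzml(dataset: MSIDataset, path: str,
                write_sidecars: bool = True) -> None:
    """Write a dataset as continuous-mode imzML 1.1 (+ .ibd).

    The shared bin-center axis is written once (continuous mode). Core labels
    and tissue masks do not fit in imzML; they are written to sidecar TSVs
    (``<stem>.annotations.tsv`` / ``<stem>.mask.tsv``) unless disabled.
    Internal 0-based coordinates are shifted to imzML's 1-based convention.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    dataset.validate()
    centers = dataset.scheme.bin_centers
    # core membership is encoded in the sidecar mask TSV (tissue=0 rows included)
    with ImzMLWriter(path, mode="continuous", spec_type="profile") as w:
        for i in range(dataset.n_pixels):
            x, y = dataset.coords[i]
            w.addSpectrum(centers, dataset.intensities[i].astype(np.float64),
                          (int(x) + 1, int(y) + 1, 1))
    if write_sidecars:
        ann_path, mask_path = _sidecar_paths(path)
        write_annotations(dataset.annotations, ann_path)
        # record every pixel (incl. off-tissue) so core membership round-trips
        with open(mask_path, "w") as fh:
            fh.write("x\ty\tcore_id\ttissue\n")
            tissue = dataset.tissue
            for i in range(dataset.n_pixels):
                x, y = dataset.coords[i]
                fh.write(f"{int(x)}\t{int(y)}\t{dataset.core_ids[i]}\t{int(tissue[i])}\n")


def read_imzml_raw(path: str) -> RawSpectra:
    """Read an imzML file pair into raw (unbinned) spectra.

    Works for continuous and processed mode. Coordinates are shifted to the
    internal 0-based convention. Raises FormatError for non-monotone m/z
    arrays and the underlying I/O error when the .ibd file is missing.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    try:
        parser = ImzMLParser(path)
    except IndexError:
        # pyimzml cannot represent a spectrum-free run; treat as empty dataset
        with open(path, "rb") as fh:
            if b"<spectrum " not in fh.read():
                return RawSpectra([], [], np.empty((0, 2), dtype=np.int64), [])
        raise
    mzs, intens, coords = [], [], []
    for i, (x, y, _z) in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(i)
        mz = np.asarray(mz, dtype=np.float64)
        if mz.size > 1 and np.any(np.diff(mz) < 0):
            raise FormatError(f"non-monotone m/z array in spectrum {i}")
        mzs.append(mz)
        intens.append(np.asarray(inten, dtype=np.float64))
        coords.append((int(x) - 1, int(y) - 1))
    coords_arr = (np.asarray(coords, dtype=np.int64).reshape(-1, 2)
                  if coords else np.empty((0, 2), dtype=np.int64))
    return RawSpectra(mzs=mzs, intensities=intens, coords=coords_arr,
                      core_ids=[""] * len(mzs))


def read_imzml(path: str, scheme: BinningScheme | None = None,
               class_order: Sequence[str] | None = None) -> MSIDataset:
    """Read a continuous-mode imzML file pair written on a shared binned axis.

    If ``scheme`` is omitted it is inferred from the (equidistant) bin-center
    axis stored in the file. Sidecar annotation/mask TSVs written by
    :func:`write_imzml` are loaded when present; otherwise each pixel becomes
    its own unlabeled core.
    """
    raw = read_imzml_raw(path)
    if len(raw) == 0:
        scheme = scheme or BinningScheme(0.0, 1.0, 1.0)
        return MSIDataset(scheme, np.empty((0, scheme.n_bins), np.float32),
                          raw.coords, np.empty(0, dtype=object), [], [])
    axis = raw.mzs[0]
    for m in raw.mzs[1:]:
        if m.shape != axis.shape or not np.allclose(m, axis):
            raise FormatError("spectra do not share one axis; use read_imzml_raw + rebin")
    if scheme is None:
        if axis.size < 2:
            raise FormatError("cannot infer binning from a single-point axis")
        widths = np.diff(axis)
        if not np.allclose(widths, widths[0], rtol=1e-6):
            raise FormatError("axis is not equidistant; pass a BinningScheme")
        w = float(np.mean(widths))
        lo = float(axis[0]) - w / 2
        # half-bin headroom so float round-off cannot drop the last bin
        scheme = BinningScheme(lo, lo + w * (axis.size + 0.5), w)
    if scheme.n_bins != axis.size:
        raise FormatError(f"axis has {axis.size} points, scheme defines {scheme.n_bins} bins")

    intensities = np.stack(raw.intensities).astype(np.float32)
    ann_path, mask_path = _sidecar_paths(path)
    if os.path.exists(ann_path):
        annotations = read_annotations(
            ann_path, mask_path if os.path.exists(mask_path) else None, class_order)
        owner: dict[tuple[int, int], str] = {}
        if os.path.exists(mask_path):
            with open(mask_path) as fh:
                fh.readline()
                for line in fh:
                    if line.strip():
                        xs, ys, cid, _ = line.rstrip("\n").split("\t")[:4]
                        owner[(int(xs), int(ys))] = cid
        core_ids = np.array(
            [owner.get((int(x), int(y)), "") for x, y in raw.coords], dtype=object)
        classes = (list(class_order) if class_order is not None
                   else sorted({a.label for a in annotations}))
    else:
        core_ids = np.array([f"px_{x}_{y}" for x, y in raw.coords], dtype=object)
        annotations = [CoreAnnotation(str(c), "unlabeled",
                                      frozenset({(int(x), int(y))}))
                       for c, (x, y) in zip(core_ids, raw.coords)]
        classes = ["unlabeled"]
    ds = MSIDataset(scheme, intensities, raw.coords, core_ids, annotations, classes)
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def save_dataset(dataset: MSIDataset, path: str) -> None:
    """Save a dataset to the single-file HDF5 container (fast local format)."""
    dataset.validate()
    str_dt = h5py.string_dtype()
    with h5py.File(path, "w") as f:
        f.attrs["lo_mz"] = dataset.scheme.lo_mz
        f.attrs["hi_mz"] = dataset.scheme.hi_mz
        f.attrs["bin_width"] = dataset.scheme.bin_width
        f.create_dataset("intensities", data=dataset.intensities,
                         compression="gzip", compression_opts=1)
        f.create_dataset("coords", data=np.asarray(dataset.coords, dtype=np.int64))
        f.create_dataset("core_ids",
                         data=np.asarray(dataset.core_ids, dtype=object), dtype=str_dt)
        f.create_dataset("class_order",
                         data=np.asarray(dataset.class_order, dtype=object), dtype=str_dt)
        ann = f.create_group("annotations")
        for a in dataset.annotations:
            g = ann.create_group(a.core_id)
            g.attrs["label"] = a.label
            mask = np.asarray(sorted(a.tissue_mask), dtype=np.int64).reshape(-1, 2)
            g.create_dataset("tissue_mask", data=mask)


def load_dataset(path: str) -> MSIDataset:
    """Load a dataset saved by :func:`save_dataset`."""
    with h5py.File(path, "r") as f:
        scheme = BinningScheme(float(f.attrs["lo_mz"]), float(f.attrs["hi_mz"]),
                               float(f.attrs["bin_width"]))
        intensities = f["intensities"][...].astype(np.float32)
        coords = f["coords"][...].astype(np.int64)
        core_ids = np.array([c.decode() if isinstance(c, bytes) else str(c)
                             for c in f["core_ids"][...]], dtype=object)
        class_order = [c.decode() if isinstance(c, bytes) else str(c)
                       for c in f["class_order"][...]]
        annotations = []
        for cid, g in f["annotations"].items():
            mask = frozenset(map(tuple, g["tissue_mask"][...].tolist()))
            annotations.append(CoreAnnotation(cid, str(g.attrs["label"]), mask))
    ds = MSIDataset(scheme, intensities, coords, core_ids, annotations, class_order)
    ds.validate()
    return ds
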