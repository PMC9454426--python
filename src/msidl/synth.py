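"""Synthetic tissue-microarray (TMA) generator for MALDI-imaging pipelines.

Emulates the statistical structure the downstream analysis assumes: an
8-class TMA (six tumor subtypes, a control tissue class, and matrix-only
spots) of disk-shaped cores on a regular pixel grid, where every pixel
spectrum is a sum of Gaussian peaks on the shared binned axis:

* class markers  — peaks unique to one class (the discriminative masses the
  attribution stage must recover),
* background     — peaks shared by all tissue classes,
* matrix peaks   — one dominant reference peak plus satellites whose
  per-pixel heights co-vary with it (the target of the correlation filter),
* additive non-negative noise, per-pixel lognormal amplitude jitter, and a
  fraction of off-tissue pixels carrying matrix-only signal.

All planted m/z values are separated by more than twice the matrix-filter
window so the planted structure is unambiguous; the generator returns them
as :class:`MarkerGroundTruth`, the oracle for feature-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .io import BinningScheme, CoreAnnotation, MSIDataset

#: Class set of the salivary-gland-carcinoma TMA (alphabetical order):
#: Acin (acinic cell), AdCy (adenoid cystic), Anos (adenocarcinoma NOS),
#: Control (healthy tonsil/appendix tissue), Matrix (matrix-only spot),
#: MuEp (mucoepidermoid), SaDu (salivary duct), Sec (secretory).
DEFAULT_CLASSES = ("Acin", "AdCy", "Anos", "Control", "Matrix", "MuEp", "SaDu", "Sec")

#: Core counts patterned on the study TMA (Acin 20, AdCy 24, Anos 8,
#: Control 6, MuEp 16, SaDu 4, Sec 3) plus six matrix-only spots.
DEFAULT_CORES_PER_CLASS = {
    "Acin": 20, "AdCy": 24, "Anos": 8, "Control": 6,
    "Matrix": 6, "MuEp": 16, "SaDu": 4, "Sec": 3,
}


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic TMA.

    The defaults are the package's desk-scale reference conditions: a
    590–631 Da axis at 10 mDa bins (4100 bins — six conv+pool blocks of the
    classifier still leave one position before the dense layer), Table-style
    core counts, five markers per class, and noise levels at which the
    planted classes are well separated but not trivially noise-free.
    """

    scheme: BinningScheme = BinningScheme(590.0, 631.0, 0.010)
    cores_per_class: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CORES_PER_CLASS))
    matrix_class: str = "Matrix"
    core_radius: int = 1              # disk radius in pixels (5 px per core)
    markers_per_class: int = 5
    marker_intensity: float = 0.5     # mean marker height rel. to matrix reference 3.0
    marker_jitter: float = 0.3        # lognormal sigma of per-pixel amplitudes
    n_background_peaks: int = 30
    n_matrix_peaks: int = 500         # total matrix peaks incl. the reference
    matrix_corr: float = 0.9          # target Pearson corr of satellites vs reference
    reference_intensity: float = 3.0  # the globally most intense peak by construction
    peak_sigma: float = 0.0025        # Gaussian peak width in Da
    noise_sigma: float = 0.02         # scale of additive half-normal noise
    off_tissue_fraction: float = 0.1  # in-core pixels carrying matrix-only signal
    matrix_window: float = 0.02       # separation rule: peaks > 2*window apart
    shared_marker_pairs: int = 0      # extra masses planted into two classes' lists
    grid_shape: tuple[int, int] | None = None   # (rows, cols) of core slots
    seed: int = 7

    @property
    def n_classes(self) -> int:
        return len(self.cores_per_class)

    @property
    def class_names(self) -> list[str]:
        return sorted(self.cores_per_class)

    def validate(self) -> None:
        if any(v < 0 for v in self.cores_per_class.values()):
            raise ConfigurationError("negative core count")
        if not (0 <= self.off_tissue_fraction < 1):
            raise ConfigurationError("off_tissue_fraction must be in [0, 1)")
        if not (0 < self.matrix_corr <= 1):
            raise ConfigurationError("matrix_corr must be in (0, 1]")
        if min(self.markers_per_class, self.n_background_peaks,
               self.n_matrix_peaks, self.shared_marker_pairs) < 0:
            raise ConfigurationError("peak counts must be >= 0")
        if self.core_radius < 0:
            raise ConfigurationError("core_radius must be >= 0")


@dataclass(frozen=True)
class MarkerGroundTruth:
    """Planted m/z values — the oracle for recovery tests (synthetic data only)."""

    class_markers: dict[str, list[float]]
    matrix_mzs: list[float]
    background_mzs: list[float]
    reference_mz: float

    def all_marker_mzs(self) -> list[float]:
        return [m for v in self.class_markers.values() for m in v]


def _disk_offsets(radius: int) -> list[tuple[int, int]]:
    return [(dx, dy)
            for dy in range(-radius, radius + 1)
            for dx in range(-radius, radius + 1)
            if dx * dx + dy * dy <= radius * radius]


def _place_peaks(cfg: SyntheticConfig, rng: np.random.Generator):
    """Choose mutually separated m/z positions and assign them to roles.

    Positions sit on a jittered regular grid inside the axis (0.5 Da margin)
    so that consecutive peaks are > 2 * matrix_window apart; class-marker
    positions are then nudged toward the center of their bin so each marker
    occupies one clearly dominant bin.
    """
    sch = cfg.scheme
    classes = cfg.class_names
    n_markers = cfg.n_classes * cfg.markers_per_class + cfg.shared_marker_pairs
    n_total = n_markers + cfg.n_background_peaks + cfg.n_matrix_peaks
    margin = min(0.5, 0.05 * (sch.hi_mz - sch.lo_mz))
    span = sch.hi_mz - sch.lo_mz - 2 * margin
    spacing = span / n_total
    if spacing <= 2 * cfg.matrix_window + 2 * sch.bin_width:
        raise ConfigurationError(
            f"{n_total} peaks do not fit the axis under the separation rule "
            f"(spacing {spacing:.4f} Da, need > {2 * cfg.matrix_window + 2 * sch.bin_width:.4f})")
    jitter = 0.25 * (spacing - 2 * cfg.matrix_window - 2 * sch.bin_width)
    pos = (sch.lo_mz + margin + (np.arange(n_total) + 0.5) * spacing
           + rng.uniform(-jitter, jitter, size=n_total))
    # keep each apex away from bin edges so its bin is a strict local maximum
    frac = (pos - sch.lo_mz) / sch.bin_width
    frac = np.floor(frac) + np.clip(frac - np.floor(frac), 0.3, 0.7)
    pos = sch.lo_mz + frac * sch.bin_width

    order = rng.permutation(n_total)
    marker_pos = np.sort(pos[order[:n_markers]])
    rest = order[n_markers:]
    background = np.sort(pos[rest[:cfg.n_background_peaks]])
    matrix = np.sort(pos[rest[cfg.n_background_peaks:]])

    # markers snap to exact bin centers (one dominant bin per marker)
    idx = sch.bin_index(marker_pos)
    marker_pos = sch.lo_mz + (idx + 0.5) * sch.bin_width

    class_markers: dict[str, list[float]] = {}
    k = cfg.markers_per_class
    assign = rng.permutation(n_markers)
    for i, cls in enumerate(classes):
        class_markers[cls] = sorted(float(marker_pos[j]) for j in assign[i * k:(i + 1) * k])
    # shared masses: planted into two consecutive classes' lists (dedup oracle)
    for s in range(cfg.shared_marker_pairs):
        mz = float(marker_pos[assign[cfg.n_classes * k + s]])
        a, b = classes[s % cfg.n_classes], classes[(s + 1) % cfg.n_classes]
        class_markers[a] = sorted(class_markers[a] + [mz])
        class_markers[b] = sorted(class_markers[b] + [mz])

    if len(matrix):
        ref = float(matrix[rng.integers(len(matrix))])
    else:
        ref = float("nan")
    return class_markers, [float(m) for m in matrix], [float(b) for b in background], ref


def _peak_template(sch: BinningScheme, mzs: np.ndarray, sigma: float) -> np.ndarray:
    """Dense (n_peaks, n_bins) matrix of unit-height Gaussian bin profiles.

    Row p holds the fraction of peak p's mass falling in each bin
    (Gaussian of width ``sigma`` integrated over the half-open bin
    intervals), so a fully contained peak of height h contributes h to its
    apex bin.
    """
    mzs = np.asarray(mzs, dtype=np.float64)
    T = np.zeros((len(mzs), sch.n_bins), dtype=np.float32)
    edges = sch.lo_mz + np.arange(sch.n_bins + 1) * sch.bin_width
    for p, mu in enumerate(mzs):
        lo = max(0, int((mu - 5 * sigma - sch.lo_mz) / sch.bin_width) - 1)
        hi = min(sch.n_bins, int((mu + 5 * sigma - sch.lo_mz) / sch.bin_width) + 2)
        if hi <= lo:
            continue
        cdf = norm.cdf(edges[lo:hi + 1], loc=mu, scale=sigma)
        T[p, lo:hi] = np.diff(cdf)
    return T


def _lognormal_mean1(rng: np.random.Generator, sigma: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal jitter; exactly 1 when sigma == 0."""
    if sigma == 0:
        return np.ones(size)
    return np.exp(rng.normal(0.0, sigma, size=size) - sigma * sigma / 2.0)


def generate_tma(cfg: SyntheticConfig) -> tuple[MSIDataset, MarkerGroundTruth]:
    """Generate a synthetic TMA dataset plus its planted-peak ground truth.

    Layout: cores are placed on a regular grid of non-overlapping slots
    (row-major, one slot per core). Tissue-class pixels carry background +
    class-marker + matrix signal; a fraction ``off_tissue_fraction`` of each
    tissue core's pixels is flagged tissue=0 and carries matrix-only signal;
    matrix-class cores are entirely tissue-free and carry matrix signal plus
    the matrix class's own characteristic (uncorrelated) peaks.

    Deterministic: the same config (including seed) yields an identical
    dataset.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    sch = cfg.scheme
    classes = cfg.class_names

    class_markers, matrix_mzs, background_mzs, ref_mz = _place_peaks(cfg, rng)
    truth = MarkerGroundTruth(class_markers=class_markers, matrix_mzs=matrix_mzs,
                              background_mzs=background_mzs, reference_mz=ref_mz)

    # ---- core layout ------------------------------------------------------
    core_list: list[tuple[str, str]] = []       # (core_id, label)
    for cls in classes:
        for k in range(cfg.cores_per_class[cls]):
            core_list.append((f"{cls}_{k + 1:02d}", cls))
    n_cores = len(core_list)
    if cfg.grid_shape is not None:
        rows, cols = cfg.grid_shape
        if rows * cols < n_cores:
            raise ConfigurationError(
                f"{n_cores} cores do not fit a {rows}x{cols} grid")
    else:
        cols = max(1, math.ceil(math.sqrt(n_cores)))
    cell = 2 * cfg.core_radius + 3
    offsets = _disk_offsets(cfg.core_radius)

    coords, core_ids, roles = [], [], []        # role: "tissue" | "off" | "matrix"
    annotations: list[CoreAnnotation] = []
    for idx, (core_id, label) in enumerate(core_list):
        cx = (idx % cols) * cell + cfg.core_radius + 1
        cy = (idx // cols) * cell + cfg.core_radius + 1
        pix = [(cx + dx, cy + dy) for dx, dy in offsets]
        if label == cfg.matrix_class:
            tissue_idx: set[int] = set()
        else:
            off = set(np.flatnonzero(
                rng.random(len(pix)) < cfg.off_tissue_fraction).tolist())
            tissue_idx = set(range(len(pix))) - off
        mask = frozenset(pix[i] for i in tissue_idx)
        annotations.append(CoreAnnotation(core_id, label, mask))
        for i, (x, y) in enumerate(pix):
            coords.append((x, y))
            core_ids.append(core_id)
            if label == cfg.matrix_class:
                roles.append("matrix")
            else:
                roles.append("tissue" if i in tissue_idx else "off")

    n_pix = len(coords)
    labels = np.array([dict(core_list)[c] for c in core_ids], dtype=object)

    # ---- per-pixel peak heights ------------------------------------------
    all_mzs = (truth.all_marker_mzs() + background_mzs + matrix_mzs)
    # deduplicate shared markers (planted once, listed twice)
    all_mzs = sorted(set(all_mzs))
    mz_col = {mz: j for j, mz in enumerate(all_mzs)}
    P = len(all_mzs)
    H = np.zeros((n_pix, P), dtype=np.float64)

    sj = cfg.marker_jitter
    base_marker = cfg.marker_intensity * rng.uniform(0.8, 1.2, size=P)
    base_bg = rng.uniform(0.2, 0.7, size=P)
    base_sat = rng.uniform(0.3, 0.8, size=P)

    A = _lognormal_mean1(rng, sj, n_pix)        # matrix reference amplitude factor
    c = cfg.matrix_corr
    delta = math.sqrt(1.0 / (c * c) - 1.0)      # satellite decorrelation mix

    roles_arr = np.array(roles)
    has_tissue_sig = roles_arr == "tissue"
    is_matrix_core = roles_arr == "matrix"

    for cls in classes:
        in_cls = (labels == cls) & (has_tissue_sig | is_matrix_core)
        cols_cls = [mz_col[m] for m in class_markers[cls]]
        if in_cls.any() and cols_cls:
            jit = _lognormal_mean1(rng, sj, (int(in_cls.sum()), len(cols_cls)))
            H[np.ix_(in_cls, cols_cls)] += base_marker[cols_cls] * jit

    bg_cols = [mz_col[m] for m in background_mzs]
    if bg_cols:
        jit = _lognormal_mean1(rng, sj, (int(has_tissue_sig.sum()), len(bg_cols)))
        H[np.ix_(has_tissue_sig, bg_cols)] = base_bg[bg_cols] * jit

    sat_mzs = [m for m in matrix_mzs if m != ref_mz]
    sat_cols = [mz_col[m] for m in sat_mzs]
    if matrix_mzs:
        H[:, mz_col[ref_mz]] = cfg.reference_intensity * A
        if sat_cols:
            eta = _lognormal_mean1(rng, sj, (n_pix, len(sat_cols)))
            mix = (A[:, None] + delta * eta) / (1.0 + delta)
            H[:, sat_cols] = base_sat[sat_cols] * mix

    T = _peak_template(sch, np.array(all_mzs), cfg.peak_sigma)
    X = H.astype(np.float32) @ T
    if cfg.noise_sigma > 0:
        X += np.abs(rng.normal(0.0, cfg.noise_sigma, size=X.shape)).astype(np.float32)

    ds = MSIDataset(
        scheme=sch,
        intensities=np.ascontiguousarray(X, dtype=np.float32),
        coords=np.asarray(coords, dtype=np.int64),
        core_ids=np.asarray(core_ids, dtype=object),
        annotations=annotations,
        class_order=classes,
    )
    ds.validate()
    return ds, truth


def plant_label_noise(dataset: MSIDataset, truth: MarkerGroundTruth,
                      core_id: str, fraction: float, seed: int = 0,
                      window: float = 0.02) -> MSIDataset:
    """Strip the class-marker signal from a fraction of one core's pixels.

    Emulates a mixed core whose healthy portion is (incorrectly) labeled with
    the core's tumor class: the chosen pixels keep their label and tissue
    flag but lose all bins within ``window`` Da of the core's planted class
    markers, leaving background-plus-matrix signal only.
    """
    if not (0 <= fraction <= 1):
        raise ValueError("fraction must be in [0, 1]")
    amap = dataset.annotation_map()
    if core_id not in amap:
        raise KeyError(f"unknown core {core_id!r}")
    label = amap[core_id].label
    markers = truth.class_markers.get(label, [])
    out = dataset.copy()
    idx = np.flatnonzero(dataset.core_ids == core_id)
    n_mod = int(round(fraction * len(idx)))
    if n_mod == 0 or not markers:
        return out
    rng = np.random.default_rng(seed)
    chosen = rng.choice(idx, size=n_mod, replace=False)
    for mz in markers:
        bins = dataset.scheme.mz_window_bins(mz, window)
        out.intensities[np.ix_(chosen, bins)] = 0.0
    return out


def pixels_per_core(cfg: SyntheticConfig) -> int:
    return len(_disk_offsets(cfg.core_radius))
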