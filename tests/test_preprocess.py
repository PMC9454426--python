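"""Re-binning, normalization, off-tissue masking and the matrix filter."""

import numpy as np
import pytest
from dataclasses import replace

from msidl import BinningScheme, CoreAnnotation, MSIDataset
from msidl.io import RawSpectra, ValidationError
from msidl.preprocess import (mask_off_tissue, matrix_filter, normalize_minmax,
                              preprocess, rebin)

from conftest import make_flat_dataset


def _raw(mzs_list, intens_list):
    n = len(mzs_list)
    return RawSpectra(
        mzs=[np.asarray(m, dtype=np.float64) for m in mzs_list],
        intensities=[np.asarray(v, dtype=np.float64) for v in intens_list],
        coords=np.column_stack([np.arange(n), np.zeros(n, dtype=int)]).astype(np.int64),
        core_ids=[""] * n,
    )


class TestRebin:
    def test_two_points_one_bin_hand_oracle(self):
        # floor((600.0001-590)/0.0003) = 33333 for both points -> bin sum 8
        sch = BinningScheme(590.0, 2000.0, 0.0003)
        ds = rebin(_raw([[600.0001, 600.0002]], [[5.0, 3.0]]), sch)
        assert ds.intensities[0, 33333] == pytest.approx(8.0)
        assert ds.intensities.sum() == pytest.approx(8.0)

    def test_half_open_edges(self):
        sch = BinningScheme(590.0, 600.0, 0.5)
        ds = rebin(_raw([[590.0, 600.0]], [[1.0, 1.0]]), sch)
        assert ds.intensities[0, 0] == 1.0          # lo_mz -> bin 0
        assert ds.intensities.sum() == 1.0          # hi_mz dropped

    def test_conservation_random_spectra(self):
        rng = np.random.default_rng(0)
        sch = BinningScheme(590.0, 650.0, 0.07)
        mzs = [np.sort(rng.uniform(580, 660, size=50)) for _ in range(1000)]
        vals = [rng.random(50) for _ in range(1000)]
        ds = rebin(_raw(mzs, vals), sch)
        for i in range(1000):
            in_range = (mzs[i] >= 590.0) & (mzs[i] < 590.0 + sch.n_bins * 0.07)
            assert ds.intensities[i].sum() == pytest.approx(
                vals[i][in_range].sum(), rel=1e-6)

    def test_brute_force_equivalence(self):
        rng = np.random.default_rng(1)
        sch = BinningScheme(100.0, 110.0, 0.25)
        mz = np.sort(rng.uniform(99, 111, size=200))
        val = rng.random(200)
        ds = rebin(_raw([mz], [val]), sch)
        brute = np.zeros(sch.n_bins)
        for m, v in zip(mz, val):                    # independent per-point loop
            i = int(np.floor((m - 100.0) / 0.25))
            if 0 <= i < sch.n_bins and m >= 100.0:
                brute[i] += v
        assert np.allclose(ds.intensities[0], brute, rtol=1e-6)


class TestNormalizeMinmax:
    def test_affine_map(self):
        ds = make_flat_dataset({"A": 1}, n_bins=3)
        ds.intensities[0] = [2.0, 4.0, 6.0]
        out = normalize_minmax(ds)
        assert np.allclose(out.intensities[0], [0.0, 0.5, 1.0])

    def test_constant_spectrum_maps_to_zeros(self):
        ds = make_flat_dataset({"A": 1}, n_bins=3)
        ds.intensities[0] = [5.0, 5.0, 5.0]
        out = normalize_minmax(ds)
        assert np.all(out.intensities == 0.0)

    def test_postcondition_and_idempotence(self, small_tma):
        ds, _ = small_tma
        out = normalize_minmax(ds)
        mn, mx = out.intensities.min(axis=1), out.intensities.max(axis=1)
        assert np.all(mn == 0.0)
        assert np.all((mx == 1.0) | (mx == 0.0))
        again = normalize_minmax(out)
        assert np.allclose(again.intensities, out.intensities)


class TestMaskOffTissue:
    def _core(self, n, n_tissue, label, y=0):
        pix = [(x, y) for x in range(n)]
        return pix, CoreAnnotation(f"{label}_{y}", label, frozenset(pix[:n_tissue]))

    def test_counts(self):
        pix, ann = self._core(10, 7, "A")
        ds = make_flat_dataset({"A": 10})
        ds.annotations = [ann]
        ds.core_ids[:] = ann.core_id
        out = mask_off_tissue(ds)
        assert out.n_pixels == 7

    def test_matrix_core_fully_retained(self):
        ds = make_flat_dataset({"Matrix": 5})
        ds.annotations = [CoreAnnotation("Matrix_core", "Matrix", frozenset())]
        out = mask_off_tissue(ds)
        assert out.n_pixels == 5

    def test_empty_mask_warns_and_drops(self, caplog):
        ds = make_flat_dataset({"A": 4})
        ds.annotations = [CoreAnnotation("A_core", "A", frozenset())]
        with caplog.at_level("WARNING"):
            out = mask_off_tissue(ds)
        assert out.n_pixels == 0
        assert any("empty tissue mask" in r.message for r in caplog.records)


class TestMatrixFilter:
    def _toy(self):
        """10 pixels, 3 isolated peaks: A (reference, most intense),
        B highly correlated with A, C independent."""
        rng = np.random.default_rng(42)
        ds = make_flat_dataset({"T": 10}, n_bins=30)
        ds.intensities[:] = 0.0
        a = rng.uniform(5.0, 10.0, size=10)
        b = 0.5 * a + rng.normal(0, 0.05, size=10)
        c = rng.uniform(1.0, 2.0, size=10)
        ds.intensities[:, 5] = a
        ds.intensities[:, 15] = b
        ds.intensities[:, 25] = c
        return ds, a, b, c

    def test_toy_selection_matches_brute_force_pearson(self):
        from scipy.stats import pearsonr

        ds, a, b, c = self._toy()
        out, report = matrix_filter(ds, n_filter=2, window=0.4)
        sel_bins = {ds.scheme.bin_index(mz) for mz, _ in report.selected_peaks}
        assert sel_bins == {5, 15}
        assert np.all(out.intensities[:, 5] == 0.0)
        assert np.all(out.intensities[:, 15] == 0.0)
        assert np.array_equal(out.intensities[:, 25], ds.intensities[:, 25])
        by_mz = dict(report.selected_peaks)
        centers = ds.scheme.bin_centers
        assert by_mz[centers[5]] == pytest.approx(1.0)
        # dataset intensities are float32; the oracle correlates the float64 originals
        assert by_mz[centers[15]] == pytest.approx(pearsonr(a, b).statistic, abs=1e-6)
        assert report.reference_mz == centers[5]

    def test_saturation_zeroes_all_peaks(self):
        ds, *_ = self._toy()
        out, report = matrix_filter(ds, n_filter=99, window=0.4)
        assert len(report.selected_peaks) == 3
        assert np.all(out.intensities[:, [5, 15, 25]] == 0.0)

    def test_reference_from_matrix_class_pixels(self, small_tma):
        ds, truth = small_tma
        _, report = matrix_filter(ds, n_filter=5)
        assert report.reference_mz == pytest.approx(truth.reference_mz, abs=0.006)

    def test_planted_matrix_zeroed_markers_intact(self, small_tma):
        ds, truth = small_tma
        filtered, report = matrix_filter(ds, n_filter=len(truth.matrix_mzs))
        sel = np.array([mz for mz, _ in report.selected_peaks])
        for mz in truth.matrix_mzs:
            assert np.min(np.abs(sel - mz)) <= 0.01
        for mz in [m for v in truth.class_markers.values() for m in v]:
            assert all(not (lo <= mz <= hi) for lo, hi in report.zeroed_intervals)
            b = ds.scheme.bin_index(mz)
            assert np.array_equal(filtered.intensities[:, b], ds.intensities[:, b])

    def test_idempotent_with_same_report(self, small_tma):
        ds, truth = small_tma
        filtered, report = matrix_filter(ds, n_filter=len(truth.matrix_mzs))
        again = filtered.copy()
        for lo, hi in report.zeroed_intervals:       # re-apply the report
            b0 = ds.scheme.bin_index(lo) if lo > ds.scheme.lo_mz else 0
            bins = ds.scheme.mz_window_bins((lo + hi) / 2, (hi - lo) / 2)
            again.intensities[:, bins] = 0.0
        assert np.array_equal(again.intensities, filtered.intensities)

    def test_degenerate_reference_rejected(self):
        ds = make_flat_dataset({"T": 5}, n_bins=10)
        ds.intensities[:] = 0.0
        ds.intensities[:, 4] = 7.0                   # constant peak
        with pytest.raises(ValidationError, match="degenerate|constant"):
            matrix_filter(ds, n_filter=1)

    def test_needs_two_pixels(self):
        ds = make_flat_dataset({"T": 1}, n_bins=10)
        with pytest.raises(ValidationError):
            matrix_filter(ds)


class TestFullChain:
    def test_output_in_unit_range_and_masked(self, small_cfg, small_tma):
        ds, truth = small_tma
        proc, report = preprocess(ds, n_filter=len(truth.matrix_mzs))
        assert proc.intensities.min() >= 0.0 and proc.intensities.max() <= 1.0
        labels = proc.labels
        assert (labels == "Matrix").sum() == small_cfg.cores_per_class["Matrix"] * 13
        assert proc.tissue[labels != "Matrix"].all()
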