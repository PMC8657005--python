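"""Alignment, normalization, noise, peak picking, binning, prevalence."""

import numpy as np
import pandas as pd
import pytest

from msihet.containers import FeatureMatrix, MSIDataset, PeakList
from msihet.preprocessing import (
    align_spectra,
    bin_features,
    estimate_noise,
    local_maxima,
    pick_peaks,
    prevalence_filter,
    preprocess,
    rms_normalize,
)


def _meta(n):
    return pd.DataFrame(
        {
            "spectrum_index": np.arange(n),
            "x": np.arange(n) + 1,
            "y": np.ones(n, int),
            "patient_id": ["P1"] * n,
            "roi_id": ["R1"] * n,
            "roi_class": ["WD"] * n,
        }
    )


def _peaky_spectrum(mz, centers, heights, sigma=0.01):
    spec = np.zeros_like(mz)
    for c, h in zip(centers, heights):
        spec += h * np.exp(-0.5 * ((mz - c) / sigma) ** 2)
    return spec


class TestRmsNormalize:
    def test_worked_example(self):
        out = rms_normalize(np.array([3.0, 4.0]))
        assert np.sqrt(np.mean(np.array([3.0, 4.0]) ** 2)) == pytest.approx(3.53553, abs=1e-5)
        assert out == pytest.approx([0.84853, 1.13137], abs=1e-5)

    def test_unit_rms_and_idempotence(self, rng):
        x = rng.exponential(2.0, 1000)
        out = rms_normalize(x)
        assert np.sqrt(np.mean(out**2)) == pytest.approx(1.0, abs=1e-10)
        assert rms_normalize(out) == pytest.approx(out, abs=1e-12)

    def test_scale_invariance(self, rng):
        x = rng.exponential(1.0, 500)
        assert rms_normalize(17.3 * x) == pytest.approx(rms_normalize(x))

    def test_rowwise_on_block(self, rng):
        block = rng.exponential(1.0, (5, 200)).astype(np.float32)
        out = rms_normalize(block)
        rms = np.sqrt(np.mean(np.asarray(out, dtype=float) ** 2, axis=1))
        assert rms == pytest.approx(np.ones(5), abs=1e-6)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            rms_normalize(np.zeros(10))


class TestEstimateNoise:
    def test_gaussian_noise_scale(self, rng):
        x = rng.normal(0.0, 1.0, 100_000)
        assert estimate_noise(x) == pytest.approx(1.0, rel=0.10)

    def test_all_zero(self):
        assert estimate_noise(np.zeros(100)) == 0.0

    def test_robust_to_tall_peaks(self, rng):
        x = rng.normal(0.0, 1.0, 100_000)
        base = estimate_noise(x)
        y = x.copy()
        y[::1000] += 500.0  # 100 tall peaks
        assert estimate_noise(y) == pytest.approx(base, rel=0.15)


class TestPickPeaks:
    def test_flat_zero_spectrum(self):
        mz = np.linspace(600, 610, 1000)
        peaks = pick_peaks(np.zeros(1000), mz=mz)
        assert len(peaks) == 0

    def test_snr_threshold_boundary(self):
        """A peak at 10x the noise level survives S/N=7; at 5x it does not
        (oracle: direct threshold count on the constructed spectrum)."""
        mz = np.arange(600, 650, 0.01)
        for factor, expected in ((10.0, 1), (5.0, 0)):
            spec = _peaky_spectrum(mz, [625.0], [factor], 0.05)
            oracle = int(np.sum((spec >= 7.0) & (spec > np.roll(spec, 1))
                                & (spec >= np.roll(spec, -1))))
            peaks = pick_peaks(spec, snr_threshold=7.0, mz=mz, noise=1.0)
            assert len(peaks) == expected == oracle

    def test_matches_brute_force_local_max_oracle(self, rng):
        """Retained apexes equal every local maximum above k*noise."""
        mz = np.arange(600, 620, 0.01)
        for _ in range(10):
            spec = rng.exponential(1.0, mz.size)
            spec += _peaky_spectrum(mz, rng.uniform(602, 618, 8), rng.uniform(5, 40, 8))
            noise = estimate_noise(spec)
            oracle = [
                i for i in range(1, mz.size - 1)
                if spec[i] > spec[i - 1] and spec[i] >= spec[i + 1]
                and spec[i] >= 7.0 * noise
            ]
            got = local_maxima(spec)
            got = got[spec[got] >= 7.0 * noise]
            assert got.tolist() == oracle

    def test_centroid_refinement_beats_grid(self):
        mz = np.arange(600, 602, 0.01)
        true_center = 601.0037  # deliberately off-grid
        spec = _peaky_spectrum(mz, [true_center], [100.0], 0.02)
        peaks = pick_peaks(spec, mz=mz, noise=1.0)
        assert len(peaks) == 1
        assert abs(peaks.centroids[0] - true_center) < 0.004


class TestAlignment:
    def _dataset(self, shifts_ppm, rng=None, noise=0.0):
        mz = np.arange(600, 1000, 0.01)
        centers = np.linspace(620, 980, 25)
        heights = np.linspace(30, 80, 25)
        rows = []
        for s in shifts_ppm:
            spec = _peaky_spectrum(mz, centers * (1 + s * 1e-6), heights)
            if noise and rng is not None:
                spec += rng.exponential(noise, mz.size)
            rows.append(spec)
        return MSIDataset(mz_axis=mz, intensities=np.array(rows),
                          meta=_meta(len(shifts_ppm)))

    def test_identical_spectra_zero_shift(self):
        ds = self._dataset([0.0, 0.0])
        _, shifts = align_spectra(ds)
        assert np.abs(shifts) == pytest.approx(0.0, abs=0.5)

    def test_recovers_rigid_20ppm_shift(self):
        ds = self._dataset([0.0, 20.0])
        aligned, shifts = align_spectra(ds)
        # residual relative offset between the two spectra after alignment
        residual = (shifts[1] + 20.0) - (shifts[0] + 0.0)
        assert abs(residual) <= 2.0

    def test_shift_bounded_by_max(self):
        ds = self._dataset([0.0, 100.0])
        _, shifts = align_spectra(ds, max_shift_ppm=50.0)
        assert np.all(np.abs(shifts) <= 50.0 + 1e-9)

    def test_residual_within_ten_percent_of_injected(self):
        injected = np.array([0.0, -30.0, 15.0, 40.0, -10.0, 25.0])
        ds = self._dataset(injected)
        _, shifts = align_spectra(ds)
        resid = shifts + injected
        resid -= resid.mean()  # alignment recovers relative, not absolute, shifts
        assert np.all(np.abs(resid) <= 0.1 * np.maximum(np.abs(injected), 10.0))

    def test_rejects_single_spectrum(self):
        ds = self._dataset([0.0])
        with pytest.raises(ValueError):
            align_spectra(ds)


class TestBinning:
    def _single_peak_lists(self, centers, height=10.0):
        return [
            PeakList(centroids=np.array([c]), heights=np.array([height]),
                     snr=np.array([20.0]))
            for c in centers
        ]

    def test_identical_peaks_one_feature(self):
        pls = self._single_peak_lists([700.0, 700.0, 700.0])
        mat = bin_features(pls, _meta(3), tolerance_scans=12, axis_spacing=0.01)
        assert mat.n_features == 1
        assert mat.prevalence == pytest.approx([1.0])

    def test_peaks_within_tolerance_merge(self):
        pls = self._single_peak_lists([700.00, 700.05])
        mat = bin_features(pls, _meta(2), tolerance_scans=12, axis_spacing=0.01)
        assert mat.n_features == 1

    def test_peaks_outside_tolerance_split(self):
        pls = self._single_peak_lists([700.00, 700.20])
        mat = bin_features(pls, _meta(2), tolerance_scans=12, axis_spacing=0.01)
        assert mat.n_features == 2

    def test_feature_mass_is_weighted_mean(self):
        pls = [
            PeakList(np.array([700.00]), np.array([30.0]), np.array([20.0])),
            PeakList(np.array([700.06]), np.array([10.0]), np.array([20.0])),
        ]
        mat = bin_features(pls, _meta(2), 12, 0.01)
        assert mat.feature_mz[0] == pytest.approx(700.015)

    def test_permutation_invariance(self, rng):
        centers = rng.uniform(600, 900, (6, 4))
        pls = [
            PeakList(np.sort(c), rng.uniform(5, 50, 4), np.full(4, 10.0))
            for c in centers
        ]
        mat1 = bin_features(pls, _meta(6), 12, 0.01)
        perm = [3, 1, 5, 0, 4, 2]
        mat2 = bin_features([pls[i] for i in perm], _meta(6), 12, 0.01)
        assert mat1.feature_mz == pytest.approx(mat2.feature_mz)
        assert np.allclose(mat1.intensities[perm], mat2.intensities)


class TestPrevalenceFilter:
    def _matrix(self, present_count, n=100):
        intens = np.zeros((n, 1))
        intens[:present_count, 0] = 5.0
        return FeatureMatrix(feature_mz=np.array([700.0]), intensities=intens,
                             meta=_meta(n))

    def test_below_threshold_removed(self):
        assert prevalence_filter(self._matrix(4)).n_features == 0

    def test_boundary_kept(self):
        # "fewer than 5%" is strict: exactly 5% survives
        assert prevalence_filter(self._matrix(5)).n_features == 1

    def test_zero_threshold_is_identity(self):
        assert prevalence_filter(self._matrix(1), min_fraction=0.0).n_features == 1


class TestEndToEnd:
    def test_noise_free_features_within_10ppm_of_theory(self, noisefree_dataset):
        ds, truth = noisefree_dataset
        matrix, _ = preprocess(ds)
        planted = truth.peptides["mh_plus"].to_numpy()
        for mh in planted:
            err_ppm = np.min(np.abs(matrix.feature_mz - mh)) / mh * 1e6
            assert err_ppm <= 10.0

    def test_alignment_corrects_generator_drift(self, small_dataset):
        ds, truth = small_dataset
        aligned, shifts = align_spectra(ds)
        resid = shifts + truth.drift_ppm
        resid -= np.median(resid)
        assert np.quantile(np.abs(resid), 0.95) <= 3.0
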