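"""Spectral preprocessing: alignment, normalization, peak picking, binning.

The stage order follows the acquisition-processing convention for FT-ICR
imaging data: rigid ppm alignment of all pixel spectra to a common
reference, RMS normalization, S/N-thresholded peak picking with parabolic
centroid refinement, tolerance binning of centroids across pixels into
consensus features, and a prevalence filter that removes features seen in
fewer than a given fraction of spectra.

A "scan" is one data point of the profile axis; the binning tolerance is
expressed in scans and converted to Da with the dataset's median axis
spacing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import FeatureMatrix, MSIDataset, PeakList, Spectrum

__all__ = [
    "align_spectra",
    "rms_normalize",
    "estimate_noise",
    "pick_peaks",
    "pick_peaks_dataset",
    "bin_features",
    "prevalence_filter",
    "preprocess",
]


# ---------------------------------------------------------------------------
# alignment

def align_spectra(
    dataset: MSIDataset,
    max_shift_ppm: float = 50.0,
    iterations: int = 3,
    oversampling: int = 2,
) -> tuple[MSIDataset, np.ndarray]:
    """Rigidly align all spectra to their mean spectrum.

    The shift model is multiplicative in m/z (a pure ppm miscalibration),
    which becomes a translation on a log-m/z axis. Each iteration
    cross-correlates every spectrum against the mean of the currently
    shifted spectra on a uniform log-m/z grid upsampled by ``oversampling``,
    refines the apex lag with 3-point parabolic interpolation, and
    accumulates the per-spectrum shift. For efficiency the correlation is
    evaluated only over signal-bearing grid columns (the top decile of the
    mean spectrum, dilated by the search width); with fewer than 2000 such
    columns the full grid is used. Applied shifts are clipped to
    ``+/- max_shift_ppm``; larger true offsets are corrected only up to the
    bound.

    Returns the aligned dataset (on the original axis) and the applied
    shift per spectrum in ppm. The sign convention: a spectrum whose peaks
    sit ``+s`` ppm above their true position gets an applied shift of
    ``-s`` ppm.
    """
    if dataset.n_spectra < 2:
        raise ValueError("alignment needs at least two spectra")
    if iterations < 1 or oversampling < 1:
        raise ValueError("iterations and oversampling must be >= 1")

    mz = dataset.mz_axis
    n = mz.size
    n_spec = dataset.n_spectra
    block = dataset.intensities

    # uniform log-m/z grid, upsampled by the oversampling factor
    n_log = n * oversampling
    lo, hi = np.log(mz[0]), np.log(mz[-1])
    dlog = (hi - lo) / (n_log - 1)
    ppm_per_lag = dlog * 1e6
    max_lag = int(np.ceil(max_shift_ppm / ppm_per_lag)) + 2
    lags = np.arange(-max_lag, max_lag + 1)

    # signal-bearing column selection from the unshifted mean spectrum:
    # clearly above the baseline fluctuation scale, with a fallback to the
    # top decile and finally the full grid for sparse/low-contrast data
    mean_native = block.mean(axis=0, dtype=np.float64)
    grid_mz = np.exp(lo + dlog * np.arange(n_log))
    native_of_col = np.clip(np.searchsorted(mz, grid_mz), 0, n - 1)
    med = np.median(mean_native)
    scale = 1.4826 * np.median(np.abs(mean_native - med))
    mask = mean_native >= med + 7.0 * scale
    if mask.sum() < max(200, n // 200):
        mask = mean_native >= np.quantile(mean_native, 0.90)
    width = max(3, -(-(max_lag + 2) // oversampling))
    mask = np.convolve(mask.astype(float), np.ones(2 * width + 1), mode="same") > 0
    sel = np.flatnonzero(mask[native_of_col])
    if sel.size < 2000:
        sel = np.arange(n_log)

    # fractional native-axis position of every (shifted) grid column
    uniform = np.allclose(np.diff(mz), mz[1] - mz[0], rtol=1e-6)
    dmz0 = mz[1] - mz[0]

    def positions(mz_values: np.ndarray) -> np.ndarray:
        if uniform:
            return np.clip((mz_values - mz[0]) / dmz0, 0.0, n - 1.000001)
        j = np.clip(np.searchsorted(mz, mz_values) - 1, 0, n - 2)
        return j + np.clip((mz_values - mz[j]) / (mz[j + 1] - mz[j]), 0.0, 1.0)

    # extended column set so ref covers sel shifted by every lag
    ext = np.unique(
        np.clip(sel[:, None] + np.arange(-max_lag - 1, max_lag + 2)[None, :],
                0, n_log - 1)
    )
    sel_in_ext = np.searchsorted(ext, sel)
    ext_mz = grid_mz[ext]
    ext_pos0 = positions(ext_mz)  # native positions at zero shift

    drift_ppm = np.zeros(n_spec)  # estimated miscalibration per spectrum
    ref_full = np.zeros(n_log + 2 * (max_lag + 2), dtype=np.float32)
    pad = max_lag + 2

    for _ in range(iterations):
        # reference = mean of currently-shifted spectra over ext columns:
        # a spectrum drifted +s ppm is corrected by sampling at mz*(1+s*1e-6)
        vals = np.empty((n_spec, ext.size), dtype=np.float32)
        for i in range(n_spec):
            fac = 1.0 + drift_ppm[i] * 1e-6
            if uniform:
                pos = ext_pos0 * fac + (mz[0] * (fac - 1.0)) / dmz0
                np.clip(pos, 0.0, n - 1.000001, out=pos)
            else:
                pos = positions(ext_mz * fac)
            i0 = pos.astype(np.int32)
            f = (pos - i0).astype(np.float32)
            row = block[i]
            vals[i] = row[i0] * (1.0 - f) + row[i0 + 1] * f
        acc = vals.sum(axis=0, dtype=np.float64)
        ref_full[:] = 0.0
        ref_full[pad + ext] = (acc / n_spec).astype(np.float32)
        # R[k, :] = ref at sel columns shifted by lags[k]
        R = np.stack([ref_full[pad + sel - k] for k in lags])
        corr = vals[:, sel_in_ext] @ R.T  # (S, n_lags)
        best = np.argmax(corr, axis=1)
        delta = np.zeros(n_spec)
        for i, b in enumerate(best):
            if 0 < b < len(lags) - 1:
                c0, c1, c2 = corr[i, b - 1], corr[i, b], corr[i, b + 1]
                denom = c0 - 2 * c1 + c2
                frac = 0.5 * (c0 - c2) / denom if denom != 0 else 0.0
                frac = float(np.clip(frac, -1.0, 1.0))
            else:
                frac = 0.0
            delta[i] = (lags[b] + frac) * ppm_per_lag
        # residual drift of +d ppm measured -> total drift estimate grows by d
        drift_ppm = np.clip(drift_ppm + delta, -max_shift_ppm, max_shift_ppm)

    # apply: corrected(mz) = original(mz * (1 + s*1e-6)), s = estimated drift
    aligned = np.empty_like(block)
    for i in range(dataset.n_spectra):
        target = mz * (1.0 + drift_ppm[i] * 1e-6)
        aligned[i] = np.interp(target, mz, block[i], left=0.0, right=0.0)
    out = MSIDataset(mz_axis=mz.copy(), intensities=aligned,
                     meta=dataset.meta.copy())
    # the applied correction is the negative of the estimated drift
    return out, -drift_ppm


# ---------------------------------------------------------------------------
# normalization & noise

def rms_normalize(spectrum):
    """Divide intensities by their root-mean-square, so RMS becomes 1.

    Accepts a ``Spectrum``, a 1-D array, or a 2-D block (normalized
    row-wise). All-zero input is degenerate and rejected.
    """
    if isinstance(spectrum, Spectrum):
        return Spectrum(
            mz=spectrum.mz,
            intensities=rms_normalize(spectrum.intensities),
            x=spectrum.x, y=spectrum.y,
            patient_id=spectrum.patient_id,
            roi_id=spectrum.roi_id,
            roi_class=spectrum.roi_class,
        )
    arr = np.asarray(spectrum)
    if arr.ndim == 1:
        arr = arr.astype(float)
        rms = np.sqrt(np.mean(arr**2))
        if rms == 0:
            raise ValueError("all-zero spectrum cannot be RMS-normalized")
        return arr / rms
    rms = np.sqrt(np.mean(arr * arr, axis=1, dtype=np.float64))
    if np.any(rms == 0):
        raise ValueError("all-zero spectrum cannot be RMS-normalized")
    return arr / rms[:, None].astype(arr.dtype)


def estimate_noise(intensities, lower_fraction: float = 0.9) -> float:
    """Robust baseline noise level of one spectrum.

    1.4826 x median absolute deviation, computed on the lower
    ``lower_fraction`` of the intensity order statistics so that sparse tall
    peaks do not inflate the estimate.
    """
    arr = np.asarray(
        intensities.intensities if isinstance(intensities, Spectrum) else intensities,
        dtype=float,
    )
    if arr.size == 0:
        raise ValueError("empty spectrum")
    k = max(1, int(np.ceil(arr.size * lower_fraction)))
    low = arr if k >= arr.size else np.partition(arr, k - 1)[:k]
    med = np.median(low)
    return float(1.4826 * np.median(np.abs(low - med)))


# ---------------------------------------------------------------------------
# peak picking

def _parabolic_centroids(mz, intens, apexes):
    """Vectorized 3-point parabolic refinement of local-maximum apexes."""
    mz = np.asarray(mz, dtype=float)
    interior = (apexes > 0) & (apexes < intens.size - 1)
    a = apexes
    y1 = intens[a].astype(float)
    centroids = mz[a].copy()
    heights = y1.copy()
    ai = a[interior]
    y0 = intens[ai - 1].astype(float)
    yc = intens[ai].astype(float)
    y2 = intens[ai + 1].astype(float)
    denom = y0 - 2 * yc + y2
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(denom != 0, 0.5 * (y0 - y2) / denom, 0.0)
    frac = np.clip(frac, -0.5, 0.5)
    step = np.where(frac >= 0, mz[np.minimum(ai + 1, mz.size - 1)] - mz[ai],
                    mz[ai] - mz[ai - 1])
    centroids[interior] = mz[ai] + frac * step
    heights[interior] = yc - 0.25 * (y0 - y2) * frac
    return centroids, heights


def local_maxima(intensities) -> np.ndarray:
    """Indices of strict-left / non-strict-right local maxima (plateau
    leftmost point wins); the brute-force definition used by peak picking."""
    arr = np.asarray(intensities, dtype=float)
    if arr.size < 3:
        return np.array([], dtype=int)
    mask = (arr[1:-1] > arr[:-2]) & (arr[1:-1] >= arr[2:])
    return np.flatnonzero(mask) + 1


def pick_peaks(spectrum, snr_threshold: float = 7.0, mz=None,
               noise: float | None = None) -> PeakList:
    """Pick local maxima with height >= snr_threshold x estimated noise.

    Centroids are refined by 3-point parabolic interpolation around the
    apex. When the noise estimate is zero (noise-free input), every positive
    local maximum is retained and its S/N reported as infinity.
    """
    if isinstance(spectrum, Spectrum):
        mz = spectrum.mz
        arr = np.asarray(spectrum.intensities, dtype=float)
    else:
        arr = np.asarray(spectrum, dtype=float)
        if mz is None:
            raise ValueError("mz axis required when passing a raw array")
        mz = np.asarray(mz, dtype=float)
    if snr_threshold <= 0:
        raise ValueError("snr_threshold must be positive")
    if noise is None:
        noise = estimate_noise(arr)
    apexes = local_maxima(arr)
    if noise > 0:
        apexes = apexes[arr[apexes] >= snr_threshold * noise]
    else:
        apexes = apexes[arr[apexes] > 0]
    centroids, heights = _parabolic_centroids(mz, arr, apexes)
    snr = heights / noise if noise > 0 else np.full(apexes.size, np.inf)
    order = np.argsort(centroids, kind="stable")
    return PeakList(centroids=centroids[order], heights=heights[order],
                    snr=snr[order])


def pick_peaks_dataset(dataset: MSIDataset, snr_threshold: float = 7.0
                       ) -> list[PeakList]:
    return [
        pick_peaks(dataset.intensities[i], snr_threshold, mz=dataset.mz_axis)
        for i in range(dataset.n_spectra)
    ]


# ---------------------------------------------------------------------------
# binning & prevalence

def bin_features(
    peaklists: list[PeakList],
    meta: pd.DataFrame,
    tolerance_scans: int = 12,
    axis_spacing: float = 0.01,
) -> FeatureMatrix:
    """Merge centroids across spectra into consensus m/z features.

    Centroids are pooled, sorted, and grouped left to right: a centroid
    joins the open bin while it lies within ``tolerance_scans x
    axis_spacing`` of the bin's running intensity-weighted consensus mass,
    otherwise it opens a new bin. The matrix entry is the picked peak height
    (the largest one, if a spectrum contributes several peaks to one bin)
    and 0 where a spectrum has no peak in the bin.
    """
    if tolerance_scans < 1:
        raise ValueError("tolerance_scans must be >= 1")
    tol = tolerance_scans * axis_spacing
    n_spectra = len(peaklists)
    cent = np.concatenate([p.centroids for p in peaklists]) if peaklists else np.array([])
    hgt = np.concatenate([p.heights for p in peaklists]) if peaklists else np.array([])
    spec = np.concatenate(
        [np.full(len(p), i) for i, p in enumerate(peaklists)]
    ) if peaklists else np.array([], dtype=int)
    if cent.size == 0:
        return FeatureMatrix(
            feature_mz=np.array([]),
            intensities=np.zeros((n_spectra, 0)),
            meta=meta.reset_index(drop=True),
        )
    order = np.argsort(cent, kind="stable")
    cent, hgt, spec = cent[order], hgt[order], spec[order].astype(int)

    bin_id = np.empty(cent.size, dtype=int)
    consensus_mass = 0.0
    consensus_weight = 0.0
    current = -1
    for i in range(cent.size):
        c, h = cent[i], hgt[i]
        if current < 0 or abs(c - consensus_mass) > tol:
            current += 1
            consensus_mass, consensus_weight = c, h
        else:
            consensus_weight += h
            consensus_mass += (c - consensus_mass) * (h / consensus_weight)
        bin_id[i] = current
    n_bins = current + 1

    weights = np.zeros(n_bins)
    sums = np.zeros(n_bins)
    np.add.at(weights, bin_id, hgt)
    np.add.at(sums, bin_id, hgt * cent)
    feature_mz = sums / weights

    matrix = np.zeros((n_spectra, n_bins), dtype=np.float32)
    np.maximum.at(matrix, (spec, bin_id), hgt.astype(np.float32))

    order = np.argsort(feature_mz, kind="stable")
    return FeatureMatrix(
        feature_mz=feature_mz[order],
        intensities=matrix[:, order],
        meta=meta.reset_index(drop=True),
    )


def prevalence_filter(matrix: FeatureMatrix, min_fraction: float = 0.05
                      ) -> FeatureMatrix:
    """Drop features present (nonzero) in fewer than ``min_fraction`` of
    spectra; the bound is strict ("less than"), so exactly 5% survives."""
    if matrix.n_spectra == 0:
        raise ValueError("empty matrix")
    keep = matrix.prevalence >= min_fraction
    return matrix.select_features(keep)


# ---------------------------------------------------------------------------
# convenience pipeline stage

def preprocess(
    dataset: MSIDataset,
    max_shift_ppm: float = 50.0,
    align_iterations: int = 3,
    align_oversampling: int = 2,
    snr_threshold: float = 7.0,
    tolerance_scans: int = 12,
    min_prevalence: float = 0.05,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Full preprocessing stage: align -> RMS-normalize -> pick -> bin ->
    prevalence-filter. Returns the feature matrix and applied shifts."""
    aligned, shifts = align_spectra(
        dataset, max_shift_ppm, align_iterations, align_oversampling
    )
    aligned.intensities = rms_normalize(aligned.intensities)
    peaklists = pick_peaks_dataset(aligned, snr_threshold)
    matrix = bin_features(
        peaklists, aligned.meta, tolerance_scans, aligned.axis_spacing
    )
    return prevalence_filter(matrix, min_prevalence), shifts
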