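"""Core in-memory containers shared across the pipeline.

The pipeline operates on imaging datasets acquired in "continuous" mode:
every pixel spectrum shares one common, strictly ascending profile m/z axis.
``MSIDataset`` holds the full intensity block (pixels x axis points) plus a
per-pixel metadata table; ``Spectrum`` is the single-pixel view used by the
spectrum-level operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: ROI classes carried through the pipeline. Stroma regions are annotated but
#: excluded from all statistics; control/metastasis are carried for display.
ROI_CLASSES = ("WD", "PD", "control", "metastasis", "stroma")

META_COLUMNS = ("spectrum_index", "x", "y", "patient_id", "roi_id", "roi_class")


@dataclass
class Spectrum:
    """One pixel's profile spectrum with its annotation."""

    mz: np.ndarray
    intensities: np.ndarray
    x: int = 0
    y: int = 0
    patient_id: str = ""
    roi_id: str = ""
    roi_class: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensities = np.asarray(self.intensities)
        if self.mz.ndim != 1 or self.mz.shape != self.intensities.shape:
            raise ValueError("mz and intensities must be 1-D arrays of equal length")
        if self.mz.size >= 2 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("m/z axis must be strictly ascending")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")


@dataclass
class MSIDataset:
    """Continuous-mode imaging dataset: a common m/z axis, an intensity
    block of shape (n_spectra, n_points), and per-spectrum metadata."""

    mz_axis: np.ndarray
    intensities: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.mz_axis = np.asarray(self.mz_axis, dtype=float)
        if self.mz_axis.ndim != 1:
            raise ValueError("mz_axis must be 1-D")
        if self.mz_axis.size >= 2 and not np.all(np.diff(self.mz_axis) > 0):
            raise ValueError("m/z axis must be strictly ascending")
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 2 or self.intensities.shape[1] != self.mz_axis.size:
            raise ValueError("intensities must have shape (n_spectra, len(mz_axis))")
        if len(self.meta) != self.intensities.shape[0]:
            raise ValueError("meta must have one row per spectrum")

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def axis_spacing(self) -> float:
        """Median spacing of the profile axis in Da (one 'scan')."""
        return float(np.median(np.diff(self.mz_axis)))

    def spectrum(self, i: int) -> Spectrum:
        row = self.meta.iloc[i]
        return Spectrum(
            mz=self.mz_axis,
            intensities=self.intensities[i],
            x=int(row["x"]),
            y=int(row["y"]),
            patient_id=str(row["patient_id"]),
            roi_id=str(row["roi_id"]),
            roi_class=str(row["roi_class"]),
        )

    def spectra(self):
        for i in range(self.n_spectra):
            yield self.spectrum(i)

    @classmethod
    def from_spectra(cls, spectra) -> "MSIDataset":
        spectra = list(spectra)
        if not spectra:
            raise ValueError("no spectra")
        mz = spectra[0].mz
        for s in spectra[1:]:
            if s.mz.shape != mz.shape or not np.allclose(s.mz, mz):
                raise ValueError("spectra are not on a common m/z axis")
        block = np.stack([s.intensities for s in spectra])
        meta = pd.DataFrame(
            {
                "spectrum_index": np.arange(len(spectra)),
                "x": [s.x for s in spectra],
                "y": [s.y for s in spectra],
                "patient_id": [s.patient_id for s in spectra],
                "roi_id": [s.roi_id for s in spectra],
                "roi_class": [s.roi_class for s in spectra],
            }
        )
        return cls(mz_axis=mz.copy(), intensities=block, meta=meta)


@dataclass
class PeakList:
    """Centroided peaks of one spectrum."""

    centroids: np.ndarray
    heights: np.ndarray
    snr: np.ndarray

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        self.snr = np.asarray(self.snr, dtype=float)
        if not (self.centroids.shape == self.heights.shape == self.snr.shape):
            raise ValueError("centroids, heights, snr must have equal length")
        if self.centroids.size >= 2 and np.any(np.diff(self.centroids) < 0):
            raise ValueError("centroids must be ascending")

    def __len__(self) -> int:
        return self.centroids.size


@dataclass
class FeatureMatrix:
    """Spectra x binned-feature intensity matrix.

    ``intensities[i, j]`` is the picked peak height of feature j in spectrum
    i, or 0 where no peak fell into the feature's bin (absences are kept as
    zeros, never imputed). ``feature_mz`` is the intensity-weighted consensus
    centroid of each bin.
    """

    feature_mz: np.ndarray
    intensities: np.ndarray
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.feature_mz = np.asarray(self.feature_mz, dtype=float)
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 2 or self.intensities.shape[1] != self.feature_mz.size:
            raise ValueError("intensities must have shape (n_spectra, n_features)")
        if len(self.meta) != self.intensities.shape[0]:
            raise ValueError("meta must have one row per spectrum")
        if self.feature_mz.size >= 2 and np.any(np.diff(self.feature_mz) < 0):
            raise ValueError("feature_mz must be ascending")

    @property
    def n_features(self) -> int:
        return self.feature_mz.size

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def prevalence(self) -> np.ndarray:
        """Fraction of spectra with a nonzero entry, per feature."""
        if self.n_spectra == 0:
            return np.zeros(self.n_features)
        return (self.intensities > 0).mean(axis=0)

    def select_features(self, mask_or_index) -> "FeatureMatrix":
        idx = np.asarray(mask_or_index)
        return FeatureMatrix(
            feature_mz=self.feature_mz[idx],
            intensities=self.intensities[:, idx],
            meta=self.meta,
        )
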