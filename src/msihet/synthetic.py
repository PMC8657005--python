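"""Synthetic MSI datasets and survival cohorts with full ground truth.

The generator emulates the statistical structure the analysis assumes: a
cohort of patients, each contributing several annotated tumor regions of
two differentiation classes (WD/PD), each region a set of pixel spectra.
Every spectrum is a profile over a common m/z axis composed of

- additive exponential baseline noise (nonnegative by construction, its
  scale defines the S/N unit),
- charge-1 peptide isotope envelopes: Gaussian peaks at M, M+1.00335,
  M+2.00670 with relative abundances lambda^k / k! for
  lambda = 0.000594 * M (a truncated-Poisson stand-in for an averagine
  isotope model),
- per-spectrum rigid multiplicative mass drift, uniform within
  +/- drift_max_ppm,
- per-pixel, per-peptide log-normal multiplicative intensity noise,

and a planted subset of peptides carries a class-dependent fold change
(PD vs WD). Planted peptides are chosen so their envelopes do not collide
(monoisotopic masses and isotope slots mutually separated), keeping the
ground truth identifiable; overlapping-envelope resolution is explicitly
out of scope for the deisotoper.

The survival generator plants a hidden expression threshold: patients
above it have their event hazard multiplied by ``true_hr``, with an
expression gap around the threshold so threshold recovery is well defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MSIDataset
from .deisotoping import ISOTOPE_SPACING

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_protein_fasta",
    "simulate_msi_dataset",
    "simulate_survival_cohort",
    "generate_annotation_terms",
    "evaluate_screen",
]

# Approximate amino-acid frequencies of vertebrate proteomes; K+R ~ 11% so
# tryptic sites are realistically dense.
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_AA_FREQ = np.array([
    0.074, 0.025, 0.054, 0.054, 0.047, 0.074, 0.026, 0.068, 0.058, 0.099,
    0.025, 0.045, 0.039, 0.034, 0.052, 0.057, 0.051, 0.073, 0.013, 0.032,
])
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()

#: mean of the truncated-Poisson isotope model per Da of monoisotopic mass
ISOTOPE_LAMBDA_PER_DA = 0.000594


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic MSI experiment."""

    n_patients: int = 5
    rois_per_patient_per_class: int = 4
    pixels_per_roi: int = 50
    n_peptides: int = 300
    n_differential: int = 15
    fold_change: float = 2.0
    mz_range: tuple[float, float] = (600.0, 3500.0)
    axis_spacing: float = 0.01
    peak_sigma_mz: float = 0.006
    drift_max_ppm: float = 30.0
    noise_sd: float = 0.3
    baseline_scale: float = 1.0
    snr_of_planted_peaks: float = 15.0
    control_rois_per_patient: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "rois_per_patient_per_class",
                     "pixels_per_roi", "n_peptides"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_differential < 0 or self.n_differential > self.n_peptides:
            raise ValueError("n_differential must be in 0..n_peptides")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")
        if self.mz_range[0] >= self.mz_range[1]:
            raise ValueError("mz_range is inverted")
        if not (600.0 <= self.mz_range[0] and self.mz_range[1] <= 3500.0):
            raise ValueError("mz_range must lie within the instrument range 600-3500 Da")
        if self.drift_max_ppm < 0 or self.noise_sd < 0 or self.baseline_scale < 0:
            raise ValueError("noise parameters must be nonnegative")


@dataclass
class GroundTruth:
    """Everything needed for parameter-recovery evaluation."""

    peptides: pd.DataFrame  # peptide_id, sequence, proteins, mh_plus, abundance, is_differential, fold_change
    drift_ppm: np.ndarray
    noise_sd: float
    drift_max_ppm: float = 0.0

    def __post_init__(self) -> None:
        folds = self.peptides["fold_change"].to_numpy()
        if np.any(folds <= 0):
            raise ValueError("fold changes must be positive")
        if self.drift_max_ppm and np.any(
            np.abs(self.drift_ppm) > self.drift_max_ppm + 1e-9
        ):
            raise ValueError("drift exceeds the configured maximum")

    @property
    def peptide_ids(self) -> list[str]:
        return self.peptides["peptide_id"].tolist()

    @property
    def differential_ids(self) -> list[str]:
        return self.peptides.loc[
            self.peptides["is_differential"], "peptide_id"
        ].tolist()

    @property
    def differential_mz(self) -> np.ndarray:
        return self.peptides.loc[
            self.peptides["is_differential"], "mh_plus"
        ].to_numpy()


def generate_protein_fasta(n_proteins: int, mean_length: int, seed: int
                           ) -> dict[str, str]:
    """Random protein collection over the 20 canonical amino acids.

    Lengths are Poisson around ``mean_length`` (minimum 30); every sequence
    is guaranteed at least one K or R so tryptic digestion yields peptides.
    Deterministic under ``seed``.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    if mean_length < 30:
        raise ValueError("mean_length must be >= 30")
    rng = np.random.default_rng(seed)
    width = len(str(n_proteins))
    proteins: dict[str, str] = {}
    for i in range(n_proteins):
        length = max(30, int(rng.poisson(mean_length)))
        seq = "".join(rng.choice(_AA, size=length, p=_AA_FREQ))
        if "K" not in seq and "R" not in seq:
            pos = int(rng.integers(0, length - 1))  # keep off the C-terminus
            seq = seq[:pos] + "K" + seq[pos + 1 :]
        proteins[f"SYN{str(i + 1).zfill(width)}"] = seq
    return proteins


def isotope_ratios(mono_mass: float, n_isotopes: int = 3) -> np.ndarray:
    """Relative isotope abundances lambda^k / k!, k = 0..n_isotopes-1."""
    lam = ISOTOPE_LAMBDA_PER_DA * mono_mass
    k = np.arange(n_isotopes)
    return lam**k / np.array([math.factorial(int(i)) for i in k])


def _select_planted(masses: np.ndarray, n: int, rng,
                    guard: float = 0.3) -> np.ndarray:
    """Choose ``n`` peptide indices whose isotope envelopes stay resolvable.

    Two peptides conflict when any isotope slot of one (mono, +1, +2 times
    the 13C spacing) comes within ``guard`` Da of a slot of the other. The
    guard exceeds the default binning window so that planted envelopes can
    never be merged into hybrid features by tolerance binning — the ground
    truth stays identifiable feature-by-feature.
    """
    order = rng.permutation(masses.size)
    chosen: list[int] = []
    chosen_masses: list[float] = []
    for idx in order:
        m = masses[idx]
        ok = True
        for cm in chosen_masses:
            delta = m - cm
            # slot differences span -2..+2 isotope spacings
            if any(
                abs(delta - k * ISOTOPE_SPACING) < guard for k in range(-2, 3)
            ):
                ok = False
                break
        if ok:
            chosen.append(int(idx))
            chosen_masses.append(float(m))
            if len(chosen) == n:
                return np.asarray(chosen)
    raise ValueError(
        f"could only place {len(chosen)} of {n} peptides without envelope "
        f"collisions; supply a larger peptide table or wider mz_range"
    )


def simulate_msi_dataset(config: SimConfig, peptide_db: pd.DataFrame
                         ) -> tuple[MSIDataset, GroundTruth]:
    """Generate a full imaging dataset plus its ground truth.

    ``peptide_db`` must carry ``sequence``, ``proteins`` and ``mh_plus``
    columns (as built by :func:`msihet.peptide_id.build_peptide_table`) and
    contain at least ``n_peptides`` unmodified entries inside ``mz_range``.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.mz_range
    margin = 3 * ISOTOPE_SPACING
    db = peptide_db
    if "mods" in db.columns:
        db = db[(db["mods"].isna()) | (db["mods"] == "")]
    db = db[(db["mh_plus"] >= lo + 1) & (db["mh_plus"] <= hi - margin)]
    db = db.drop_duplicates("sequence").reset_index(drop=True)
    if len(db) < config.n_peptides:
        raise ValueError(
            f"peptide_db has only {len(db)} usable entries in mz_range, "
            f"need {config.n_peptides}"
        )
    masses = db["mh_plus"].to_numpy()
    sel = _select_planted(masses, config.n_peptides, rng)
    planted = db.iloc[sel].reset_index(drop=True)

    n_diff = config.n_differential
    diff_mask = np.zeros(len(planted), dtype=bool)
    diff_mask[rng.choice(len(planted), size=n_diff, replace=False)] = True
    # peak amplitudes are anchored to the baseline-noise unit so that
    # snr_of_planted_peaks is meaningful; with the baseline off, unit = 1
    noise_unit = config.baseline_scale if config.baseline_scale > 0 else 1.0
    abundance = (
        noise_unit
        * config.snr_of_planted_peaks
        * 10 ** rng.uniform(0.0, 1.0, size=len(planted))
    )
    truth_peptides = pd.DataFrame(
        {
            "peptide_id": [f"PEP{i + 1:04d}" for i in range(len(planted))],
            "sequence": planted["sequence"].to_numpy(),
            "proteins": planted["proteins"].to_numpy(),
            "mh_plus": planted["mh_plus"].to_numpy(),
            "abundance": abundance,
            "is_differential": diff_mask,
            "fold_change": np.where(diff_mask, config.fold_change, 1.0),
        }
    )

    # --- metadata ------------------------------------------------------
    rows = []
    roi_counter = 0
    classes = ["WD", "PD"] * 1
    for p in range(config.n_patients):
        pid = f"P{p + 1:02d}"
        blocks = [(cls, r) for cls in classes
                  for r in range(config.rois_per_patient_per_class)]
        blocks += [("control", r) for r in range(config.control_rois_per_patient)]
        for cls, r in blocks:
            roi_id = f"{pid}_{cls}_{r + 1}"
            for px in range(config.pixels_per_roi):
                rows.append((px + 1, roi_counter + 1, pid, roi_id, cls))
            roi_counter += 1
    meta = pd.DataFrame(
        rows, columns=["x", "y", "patient_id", "roi_id", "roi_class"]
    )
    meta.insert(0, "spectrum_index", np.arange(len(meta)))
    n_spectra = len(meta)

    # --- spectra -------------------------------------------------------
    mz_axis = np.arange(lo, hi + config.axis_spacing / 2, config.axis_spacing)
    n_points = mz_axis.size
    sigma = config.peak_sigma_mz
    half = max(1, int(np.ceil(4 * sigma / config.axis_spacing)))
    offsets = np.arange(-half, half + 1)

    ratios = np.stack([isotope_ratios(m) for m in truth_peptides["mh_plus"]])
    member_mass = (
        truth_peptides["mh_plus"].to_numpy()[:, None]
        + ISOTOPE_SPACING * np.arange(3)[None, :]
    )  # (P, 3)
    area_to_amp = 1.0 / (sigma * np.sqrt(2 * np.pi))

    drift = rng.uniform(-config.drift_max_ppm, config.drift_max_ppm, n_spectra)
    is_pd = (meta["roi_class"] == "PD").to_numpy()
    fold = truth_peptides["fold_change"].to_numpy()

    block = np.empty((n_spectra, n_points), dtype=np.float32)
    flat_member = member_mass.ravel()  # (P*3,)
    flat_ratio = ratios.ravel()
    pep_of_member = np.repeat(np.arange(len(planted)), 3)
    for i in range(n_spectra):
        if config.baseline_scale > 0:
            spec = rng.exponential(config.baseline_scale, n_points)
        else:
            spec = np.zeros(n_points)
        pixel_noise = (
            np.exp(rng.normal(0.0, config.noise_sd, len(planted)))
            if config.noise_sd > 0
            else np.ones(len(planted))
        )
        amp_pep = abundance * pixel_noise
        if is_pd[i]:
            amp_pep = amp_pep * fold
        member_amp = amp_pep[pep_of_member] * flat_ratio
        centers = flat_member * (1.0 + drift[i] * 1e-6)
        pos = (centers - lo) / config.axis_spacing
        nearest = np.rint(pos).astype(int)
        idx = nearest[:, None] + offsets[None, :]
        mzs = lo + idx * config.axis_spacing
        vals = (
            member_amp[:, None]
            * np.exp(-0.5 * ((mzs - centers[:, None]) / sigma) ** 2)
        )
        valid = (idx >= 0) & (idx < n_points)
        np.add.at(spec, idx[valid], vals[valid])
        block[i] = spec

    dataset = MSIDataset(mz_axis=mz_axis, intensities=block, meta=meta)
    truth = GroundTruth(
        peptides=truth_peptides,
        drift_ppm=drift,
        noise_sd=config.noise_sd,
        drift_max_ppm=config.drift_max_ppm,
    )
    # record the assigned (area) intensity convention for reference
    truth.peptides["peak_area_mono"] = abundance / area_to_amp
    return dataset, truth


# ---------------------------------------------------------------------------
# survival cohort

def simulate_survival_cohort(
    n_patients: int,
    true_hr: float,
    censor_rate: float = 0.0,
    seed: int = 0,
    frac_high: float = 0.4,
    baseline_scale_months: float = 20.0,
) -> tuple[pd.DataFrame, dict]:
    """Cohort with a hidden expression threshold driving the hazard.

    Expression is continuous and bimodal: a low group uniform on
    (0, 0.45) and a high group uniform on (0.55, 1), leaving a gap around
    the true threshold 0.5. Event times are exponential; patients above the
    threshold have their hazard multiplied by ``true_hr``. Censoring times
    are independent exponentials whose rate is matched to the cohort's
    mixture event rate so that roughly ``censor_rate`` of patients are
    censored.

    Returns the cohort table (patient_id, expression, time, event) and a
    ground-truth dict with the threshold, the realized expression gap and
    the latent group labels.
    """
    if n_patients < 20:
        raise ValueError("n_patients must be >= 20")
    if true_hr <= 0:
        raise ValueError("true_hr must be positive")
    if not (0 <= censor_rate < 1):
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_high = int(round(n_patients * frac_high))
    n_low = n_patients - n_high
    expr = np.concatenate(
        [rng.uniform(0.0, 0.45, n_low), rng.uniform(0.55, 1.0, n_high)]
    )
    high = np.arange(n_patients) >= n_low
    scale = np.where(high, baseline_scale_months / true_hr, baseline_scale_months)
    T = rng.exponential(scale)
    if censor_rate > 0:
        mix_rate = (
            n_low / n_patients / baseline_scale_months
            + n_high / n_patients * true_hr / baseline_scale_months
        )
        censor_scale = (1.0 - censor_rate) / (censor_rate * mix_rate)
        C = rng.exponential(censor_scale, n_patients)
    else:
        C = np.full(n_patients, np.inf)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    perm = rng.permutation(n_patients)
    cohort = pd.DataFrame(
        {
            "patient_id": [f"S{i + 1:04d}" for i in range(n_patients)],
            "expression": expr[perm],
            "time": time[perm],
            "event": event[perm],
        }
    )
    truth = {
        "threshold": 0.5,
        "gap": (float(expr[~high].max()), float(expr[high].min())),
        "high_group": high[perm],
        "true_hr": true_hr,
    }
    return cohort, truth


# ---------------------------------------------------------------------------
# annotation map & evaluation helpers

def generate_annotation_terms(
    gene_ids,
    n_terms: int = 20,
    term_size: tuple[int, int] = (5, 30),
    seed: int = 0,
) -> dict[str, list[str]]:
    """Random term -> gene map over the given universe (for pipeline runs
    on synthetic data)."""
    rng = np.random.default_rng(seed)
    genes = np.asarray(sorted(set(gene_ids)))
    lo, hi = term_size
    hi = min(hi, genes.size)
    terms = {}
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        terms[f"TERM{t + 1:03d}"] = sorted(members.tolist())
    return terms


def match_to_planted(feature_mz, planted_mz, tol_mz: float = 0.1) -> np.ndarray:
    """Index of the nearest planted mass within ``tol_mz`` per feature, or
    -1 where no planted mass is close enough."""
    feature_mz = np.atleast_1d(np.asarray(feature_mz, dtype=float))
    planted = np.sort(np.asarray(planted_mz, dtype=float))
    out = np.full(feature_mz.size, -1, dtype=int)
    if planted.size == 0:
        return out
    pos = np.searchsorted(planted, feature_mz)
    for i, (f, p) in enumerate(zip(feature_mz, pos)):
        best, err = -1, tol_mz
        for j in (p - 1, p):
            if 0 <= j < planted.size and abs(planted[j] - f) <= err:
                best, err = j, abs(planted[j] - f)
        out[i] = best
    return out


def evaluate_screen(screen: pd.DataFrame, truth: GroundTruth,
                    tol_mz: float = 0.1) -> dict:
    """Compare significant screen calls against the planted differential
    peptides.

    A significant feature is a true positive when its consensus mass lies
    within ``tol_mz`` of a planted differential monoisotopic [M+H]+ (each
    planted peptide counted once); anything else significant is a false
    positive. Sensitivity is recovered-planted / n-planted; the empirical
    FDR is FP / max(1, number of significant features).
    """
    sig_mz = screen.loc[screen["significant"], "feature_mz"].to_numpy()
    diff_mz = np.sort(truth.differential_mz)
    hits = match_to_planted(sig_mz, diff_mz, tol_mz)
    recovered = np.unique(hits[hits >= 0])
    n_sig = sig_mz.size
    tp = int((hits >= 0).sum())
    fp = int(n_sig - tp)
    return {
        "n_significant": int(n_sig),
        "n_planted": int(diff_mz.size),
        "n_recovered": int(recovered.size),
        "sensitivity": float(recovered.size / diff_mz.size) if diff_mz.size else np.nan,
        "false_positives": fp,
        "empirical_fdr": float(fp / n_sig) if n_sig else 0.0,
    }
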