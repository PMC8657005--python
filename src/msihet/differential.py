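"""Discriminative feature screening between WD and PD tumor regions.

The screen mirrors a two-stage design. First, a replicated ROC stage:
spectra are sampled in patient-balanced fashion (equal numbers per patient
per class), the per-feature AUC is computed on spectrum-level intensities,
and the draw is repeated independently; features reaching
``AUC >= auc_threshold`` (in either direction, via max(AUC, 1-AUC)) in at
least ``min_pass`` of the replicates become candidates. Second, candidates
are tested on biologically meaningful units: the mean intensity of each
feature within every ROI, compared between WD and PD ROIs with a two-sided
Mann-Whitney test and Benjamini-Hochberg correction. A feature is
significant when it passes the candidate rule and both p <= alpha and
FDR q <= fdr_alpha.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FeatureMatrix

__all__ = [
    "ScreenConfig",
    "balanced_sample",
    "auc",
    "roc_screen",
    "mann_whitney_p",
    "roi_mean_test",
    "bh_adjust",
    "select_significant",
    "screen_features",
]


@dataclass
class ScreenConfig:
    """Parameters of the two-stage screen.

    ``n_per_condition`` is the total number of spectra drawn per class per
    ROC replicate (split equally over patients); the cohort-scale default
    is 3000.
    """

    n_per_condition: int = 3000
    n_replicates: int = 5
    auc_threshold: float = 0.70
    min_pass: int = 3
    alpha: float = 0.05
    fdr_alpha: float = 0.05
    seed: int = 0
    replicate_mode: str = "resample"  # "resample" | "per-patient"
    bh_scope: str = "candidates"  # "candidates" | "all"

    def __post_init__(self) -> None:
        if not (1 <= self.min_pass <= self.n_replicates):
            raise ValueError("min_pass must be in 1..n_replicates")
        if not (0 < self.auc_threshold <= 1):
            raise ValueError("auc_threshold must be in (0, 1]")
        for name in ("alpha", "fdr_alpha"):
            if not (0 < getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.replicate_mode not in ("resample", "per-patient"):
            raise ValueError("replicate_mode must be 'resample' or 'per-patient'")
        if self.bh_scope not in ("candidates", "all"):
            raise ValueError("bh_scope must be 'candidates' or 'all'")


# ---------------------------------------------------------------------------
# sampling

def balanced_sample(
    class_labels,
    patient_labels,
    n_per_condition: int,
    rng,
    classes=("WD", "PD"),
) -> dict[str, np.ndarray]:
    """Draw equal numbers of spectra per patient per class, without
    replacement.

    The per-patient quota is ``n_per_condition // n_patients``; when a
    patient cannot fill it, the quota is reduced for every patient of that
    class (balance is kept) and a warning is issued. Returns a dict mapping
    class name to the drawn spectrum indices.
    """
    class_labels = np.asarray(class_labels)
    patient_labels = np.asarray(patient_labels)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out: dict[str, np.ndarray] = {}
    for cls in classes:
        cls_mask = class_labels == cls
        if not cls_mask.any():
            raise ValueError(f"class {cls!r} absent from the data")
        patients = np.unique(patient_labels[cls_mask])
        quota = n_per_condition // len(patients)
        avail = min(
            int(np.sum(cls_mask & (patient_labels == p))) for p in patients
        )
        if avail < quota:
            warnings.warn(
                f"class {cls}: per-patient quota reduced from {quota} to "
                f"{avail} to keep patient balance"
            )
            quota = avail
        picks = []
        for p in patients:
            idx = np.flatnonzero(cls_mask & (patient_labels == p))
            picks.append(rng.choice(idx, size=quota, replace=False))
        out[cls] = np.sort(np.concatenate(picks))
    return out


# ---------------------------------------------------------------------------
# AUC

def auc(values_class0, values_class1) -> float:
    """Probability that a random class-1 value exceeds a random class-0
    value, ties counted one half (Mann-Whitney U / (n0*n1))."""
    a = np.asarray(values_class0, dtype=float)
    b = np.asarray(values_class1, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    ranks = stats.rankdata(np.concatenate([a, b]))
    r1 = ranks[a.size :].sum()
    u1 = r1 - b.size * (b.size + 1) / 2.0
    return float(u1 / (a.size * b.size))


def _auc_block(x0: np.ndarray, x1: np.ndarray) -> np.ndarray:
    """Column-wise AUC of class-1 over class-0 for two intensity blocks."""
    n0, n1 = x0.shape[0], x1.shape[0]
    ranks = stats.rankdata(np.vstack([x0, x1]), axis=0)
    r1 = ranks[n0:].sum(axis=0)
    return (r1 - n1 * (n1 + 1) / 2.0) / (n0 * n1)


def roc_screen(
    matrix: FeatureMatrix,
    config: ScreenConfig,
    classes=("WD", "PD"),
) -> tuple[np.ndarray, np.ndarray]:
    """Replicated ROC stage on spectrum-level intensities.

    Returns (aucs, n_pass): ``aucs`` has shape (n_features, n_replicates)
    with the PD-over-WD orientation; ``n_pass`` counts replicates where
    ``max(AUC, 1-AUC) >= auc_threshold`` so that discrimination in either
    direction counts.

    ``replicate_mode="resample"`` draws ``n_replicates`` independent
    balanced samples seeded ``seed, seed+1, ...``; ``"per-patient"`` runs
    one ROC per patient (spectra of that patient only), a
    leave-one-patient-in alternative.
    """
    labels = matrix.meta["roi_class"].to_numpy()
    patients = matrix.meta["patient_id"].to_numpy()
    X = matrix.intensities
    aucs = []
    if config.replicate_mode == "per-patient":
        for p in np.unique(patients[np.isin(labels, classes)]):
            m0 = (labels == classes[0]) & (patients == p)
            m1 = (labels == classes[1]) & (patients == p)
            if not (m0.any() and m1.any()):
                raise ValueError(f"patient {p!r} lacks spectra in one class")
            aucs.append(_auc_block(X[m0], X[m1]))
    else:
        for r in range(config.n_replicates):
            rng = np.random.default_rng(config.seed + r)
            idx = balanced_sample(
                labels, patients, config.n_per_condition, rng, classes
            )
            aucs.append(_auc_block(X[idx[classes[0]]], X[idx[classes[1]]]))
    aucs = np.column_stack(aucs)
    two_sided = np.maximum(aucs, 1.0 - aucs)
    n_pass = (two_sided >= config.auc_threshold).sum(axis=1)
    return aucs, n_pass


# ---------------------------------------------------------------------------
# Mann-Whitney on ROI means

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    ranks = stats.rankdata(np.concatenate([a, b]))
    r1 = ranks[a.size :].sum()
    return float(r1 - b.size * (b.size + 1) / 2.0)


def mann_whitney_p(a, b, exact_max_n: int = 8) -> float:
    """Two-sided Mann-Whitney p-value.

    Exact by full enumeration of group labelings when both groups have at
    most ``exact_max_n`` observations (correct under ties); otherwise the
    normal approximation with tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if a.size <= exact_max_n and b.size <= exact_max_n:
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)  # pooled ranks are labeling-invariant
        offset = b.size * (b.size + 1) / 2.0
        u_obs = ranks[a.size :].sum() - offset
        mean_u = a.size * b.size / 2.0
        dev = abs(u_obs - mean_u)
        count = 0
        total = 0
        for comb in itertools.combinations(range(pooled.size), b.size):
            u = ranks[list(comb)].sum() - offset
            if abs(u - mean_u) >= dev - 1e-12:
                count += 1
            total += 1
        return count / total
    res = stats.mannwhitneyu(
        b, a, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.pvalue)


def roi_mean_test(
    matrix: FeatureMatrix,
    classes=("WD", "PD"),
    feature_index=None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-feature two-sided Mann-Whitney on ROI mean intensities.

    For each feature, one mean intensity per ROI is computed, and WD-ROI
    means are compared with PD-ROI means. Returns (p_values, roi_means)
    where ``roi_means`` is the ROI x feature table with its class labels.
    """
    meta = matrix.meta
    mask = meta["roi_class"].isin(classes).to_numpy()
    sub = meta.loc[mask, ["roi_id", "roi_class"]].reset_index(drop=True)
    X = matrix.intensities[mask]
    if feature_index is None:
        feature_index = np.arange(matrix.n_features)
    feature_index = np.asarray(feature_index, dtype=int)
    df = pd.DataFrame(X[:, feature_index])
    df["roi_id"] = sub["roi_id"].to_numpy()
    grouped = df.groupby("roi_id", sort=True).mean()
    roi_class = (
        sub.drop_duplicates("roi_id").set_index("roi_id")["roi_class"]
    ).reindex(grouped.index)
    for cls in classes:
        if (roi_class == cls).sum() < 2:
            raise ValueError(f"need >= 2 ROIs of class {cls!r}")
    a = grouped.loc[(roi_class == classes[0]).to_numpy()].to_numpy()
    b = grouped.loc[(roi_class == classes[1]).to_numpy()].to_numpy()
    pvals = np.array(
        [mann_whitney_p(a[:, k], b[:, k]) for k in range(a.shape[1])]
    )
    roi_means = grouped.copy()
    roi_means.columns = feature_index
    roi_means.insert(0, "roi_class", roi_class.to_numpy())
    return pvals, roi_means


# ---------------------------------------------------------------------------
# multiplicity

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# assembly

def select_significant(screen: pd.DataFrame, alpha: float = 0.05,
                       fdr_alpha: float = 0.05) -> pd.DataFrame:
    """Rows passing the candidate rule together with p <= alpha and
    q <= fdr_alpha."""
    sig = (
        screen["candidate"]
        & (screen["p_value"] <= alpha)
        & (screen["fdr_q"] <= fdr_alpha)
    )
    return screen.loc[sig.fillna(False)].copy()


def screen_features(
    matrix: FeatureMatrix,
    config: ScreenConfig,
    classes=("WD", "PD"),
) -> pd.DataFrame:
    """Run the full two-stage screen; one result row per feature.

    Columns: feature_mz, auc_rep1..N, mean_auc, n_pass, candidate,
    p_value, fdr_q, direction (+1 higher in PD, -1 higher in WD, from the
    medians of the ROI means), significant. The Mann-Whitney stage and BH
    correction are applied to candidate features only (configurable to all
    features via ``bh_scope``).
    """
    aucs, n_pass = roc_screen(matrix, config, classes)
    n_rep = aucs.shape[1]
    candidate = n_pass >= config.min_pass

    out = pd.DataFrame({"feature_mz": matrix.feature_mz})
    for r in range(n_rep):
        out[f"auc_rep{r + 1}"] = aucs[:, r]
    out["mean_auc"] = aucs.mean(axis=1)
    out["n_pass"] = n_pass
    out["candidate"] = candidate

    test_idx = (
        np.arange(matrix.n_features)
        if config.bh_scope == "all"
        else np.flatnonzero(candidate)
    )
    p_value = np.full(matrix.n_features, np.nan)
    fdr_q = np.full(matrix.n_features, np.nan)
    direction = np.zeros(matrix.n_features, dtype=int)
    if test_idx.size:
        pvals, roi_means = roi_mean_test(matrix, classes, test_idx)
        p_value[test_idx] = pvals
        fdr_q[test_idx] = bh_adjust(pvals)
        cls = roi_means["roi_class"].to_numpy()
        med0 = np.median(
            roi_means.loc[cls == classes[0], test_idx].to_numpy(), axis=0
        )
        med1 = np.median(
            roi_means.loc[cls == classes[1], test_idx].to_numpy(), axis=0
        )
        direction[test_idx] = np.sign(med1 - med0).astype(int)
    out["p_value"] = p_value
    out["fdr_q"] = fdr_q
    out["direction"] = direction
    out["significant"] = (
        candidate
        & (out["p_value"] <= config.alpha)
        & (out["fdr_q"] <= config.fdr_alpha)
    ).fillna(False)
    return out


def volcano_plot(screen: pd.DataFrame, ax=None):
    """Minimal volcano-style plot: mean AUC (PD orientation) against
    -log10 p, significant features highlighted."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    p = screen["p_value"].fillna(1.0)
    ax.scatter(screen["mean_auc"], -np.log10(np.maximum(p, 1e-300)),
               s=8, c="0.6", label="all")
    sig = screen["significant"]
    ax.scatter(screen.loc[sig, "mean_auc"],
               -np.log10(np.maximum(p[sig], 1e-300)), s=10, c="crimson",
               label="significant")
    ax.set_xlabel("mean AUC (PD vs WD)")
    ax.set_ylabel("-log10 p (ROI means)")
    ax.legend(frameon=False)
    return ax
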