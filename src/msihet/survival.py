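"""Kaplan-Meier / log-rank validation with best-cutoff dichotomization.

A cohort carries one expression value per patient, a follow-up time and an
event flag. Patients are dichotomized at an expression cutoff; every
candidate cutoff strictly between the lower and upper expression quartile
(midpoints between consecutive distinct values) is scanned, and the cutoff
minimizing the two-group log-rank p is reported together with its
Kaplan-Meier curves, hazard ratio and 95% CI.

The hazard ratio uses the O/E approximation derived from the log-rank
tabulation, HR = (O_hi/E_hi) / (O_lo/E_lo), with
CI = exp(log HR +/- 1.96 * sqrt(1/E_lo + 1/E_hi)). This approximates, and
is not identical to, a Cox proportional-hazards estimate.

Note the deliberate absence of any multiplicity correction across scanned
cutoffs: the reported minimum p is optimistic by construction (the scan is
a selection), which is why all scanned p-values are retained for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KMCurve",
    "CutoffResult",
    "km_estimate",
    "logrank",
    "hazard_ratio",
    "optimal_cutoff",
]


@dataclass
class KMCurve:
    """Product-limit estimate: survival step function with risk counts."""

    times: np.ndarray      # distinct event times, ascending
    survival: np.ndarray   # S(t) just after each event time
    n_at_risk: np.ndarray  # risk-set size just before each event time
    n_events: np.ndarray   # events at each event time

    def at(self, t: float) -> float:
        """S(t) for arbitrary t >= 0."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CutoffResult:
    cutoff: float
    high_mask: np.ndarray = field(repr=False)
    logrank_chi2: float = 0.0
    p_value: float = 1.0
    hr: float = 1.0
    hr_ci: tuple[float, float] = (0.0, np.inf)
    km_low: KMCurve | None = None
    km_high: KMCurve | None = None
    scanned: pd.DataFrame | None = None  # cutoff, chi2, p audit trail


def _check_cohort(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("empty cohort")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be 0 or 1")
    return times, events.astype(int)


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Censored observations reduce the risk set without producing a step.
    With no censoring, S(t) equals 1 minus the empirical CDF.
    """
    times, events = _check_cohort(times, events)
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    n = t.size
    uniq, first = np.unique(t, return_index=True)
    at_risk_all = n - first
    d_all = np.add.reduceat(e.astype(float), first).astype(int)
    has_event = d_all > 0
    uniq, at_risk, d = uniq[has_event], at_risk_all[has_event], d_all[has_event]
    surv = np.cumprod(1.0 - d / at_risk)
    return KMCurve(
        times=uniq,
        survival=surv,
        n_at_risk=at_risk.astype(int),
        n_events=d,
    )


def _logrank_tab(times_a, events_a, times_b, events_b):
    """O/E/V tabulation over pooled distinct event times.

    Returns (O_a, E_a, O_b, E_b, V) where V is the hypergeometric variance
    of O_b summed over event times.
    """
    ta, ea = _check_cohort(times_a, events_a)
    tb, eb = _check_cohort(times_b, events_b)
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb]).astype(float)
    grp = np.concatenate(
        [np.zeros(ta.size), np.ones(tb.size)]
    )
    order = np.argsort(t, kind="stable")
    t, e, grp = t[order], e[order], grp[order]
    n = t.size
    uniq, first = np.unique(t, return_index=True)
    # risk-set sizes just before each distinct time
    N = n - first
    n_b_before = np.concatenate([[0.0], np.cumsum(grp)])[first]
    N_b = grp.sum() - n_b_before
    d = np.add.reduceat(e, first)
    d_b = np.add.reduceat(e * grp, first)
    keep = (d > 0) & (N > 0)
    N, N_b, d, d_b = N[keep], N_b[keep], d[keep], d_b[keep]
    frac = N_b / N
    O_b = float(d_b.sum())
    E_b = float((d * frac).sum())
    O_a = float((d - d_b).sum())
    E_a = float((d * (1.0 - frac)).sum())
    mult = np.where(N > 1, (N - d) / np.maximum(N - 1, 1), 0.0)
    V = float((d * frac * (1.0 - frac) * mult).sum())
    return O_a, E_a, O_b, E_b, V


def logrank(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test: (chi2, p) with 1 degree of freedom."""
    from scipy import stats

    O_a, E_a, O_b, E_b, V = _logrank_tab(times_a, events_a, times_b, events_b)
    if O_a + O_b == 0:
        raise ValueError("no events in either arm; log-rank undefined")
    if V <= 0:
        return 0.0, 1.0
    chi2 = (O_b - E_b) ** 2 / V
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def hazard_ratio(times_a, events_a, times_b, events_b
                 ) -> tuple[float, tuple[float, float]]:
    """O/E hazard ratio of arm B relative to arm A, with 95% CI."""
    O_a, E_a, O_b, E_b, V = _logrank_tab(times_a, events_a, times_b, events_b)
    if O_a == 0 or O_b == 0:
        raise ValueError("need at least one event per arm")
    if E_a <= 0 or E_b <= 0:
        raise ValueError("zero expected events")
    hr = (O_b / E_b) / (O_a / E_a)
    se = np.sqrt(1.0 / E_a + 1.0 / E_b)
    ci = (float(hr * np.exp(-1.96 * se)), float(hr * np.exp(1.96 * se)))
    return float(hr), ci


def candidate_cutoffs(expression) -> np.ndarray:
    """Midpoints between consecutive distinct expression values that lie
    strictly between the lower and upper quartile."""
    expr = np.asarray(expression, dtype=float)
    q1, q3 = np.quantile(expr, [0.25, 0.75])
    if q1 == q3:
        raise ValueError("degenerate expression: lower and upper quartile equal")
    distinct = np.unique(expr)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    mids = mids[(mids > q1) & (mids < q3)]
    if mids.size == 0:
        raise ValueError("no candidate cutoff between the quartiles")
    return mids


def optimal_cutoff(expression, times, events, metric: str = "min-p"
                   ) -> CutoffResult:
    """Scan all quartile-bounded cutoffs and keep the best-performing one.

    Patients with expression <= cutoff form the low arm. "Best" is the
    minimum log-rank p (equivalently the maximum chi2; both metrics are
    exposed and coincide at 1 df). The full (cutoff, chi2, p) scan is
    returned for audit.
    """
    if metric not in ("min-p", "max-chi2"):
        raise ValueError("metric must be 'min-p' or 'max-chi2'")
    expr = np.asarray(expression, dtype=float)
    times, events = _check_cohort(times, events)
    if np.isnan(expr).any():
        raise ValueError("missing expression values")
    mids = candidate_cutoffs(expr)
    records = []
    for c in mids:
        high = expr > c
        if not high.any() or high.all():
            continue
        try:
            chi2, p = logrank(times[~high], events[~high],
                              times[high], events[high])
        except ValueError:
            continue
        records.append((c, chi2, p))
    if not records:
        raise ValueError("no valid cutoff produced a defined log-rank test")
    scanned = pd.DataFrame(records, columns=["cutoff", "chi2", "p_value"])
    best = int(np.argmax(scanned["chi2"].to_numpy()))  # max chi2 == min p at 1 df
    cutoff = float(scanned.loc[best, "cutoff"])
    high = expr > cutoff
    hr, ci = hazard_ratio(times[~high], events[~high], times[high], events[high])
    return CutoffResult(
        cutoff=cutoff,
        high_mask=high,
        logrank_chi2=float(scanned.loc[best, "chi2"]),
        p_value=float(scanned.loc[best, "p_value"]),
        hr=hr,
        hr_ci=ci,
        km_low=km_estimate(times[~high], events[~high]),
        km_high=km_estimate(times[high], events[high]),
        scanned=scanned,
    )


def plot_km(result: CutoffResult, ax=None, labels=("low", "high")):
    """Step plot of the two arms' Kaplan-Meier curves."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for curve, label, color in ((result.km_low, labels[0], "black"),
                                (result.km_high, labels[1], "crimson")):
        t = np.concatenate([[0.0], curve.times])
        s = np.concatenate([[1.0], curve.survival])
        ax.step(t, s, where="post", label=f"{label} (n={int(curve.n_at_risk[0]) if len(curve.n_at_risk) else 0})",
                color=color)
    ax.set_ylim(0, 1.05)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_title(
        f"cutoff={result.cutoff:.3g}  HR={result.hr:.2f} "
        f"[{result.hr_ci[0]:.2f}, {result.hr_ci[1]:.2f}]  p={result.p_value:.2g}"
    )
    ax.legend(frameon=False)
    return ax
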