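"""Charge-1 deisotoping of the binned feature matrix.

Tryptic peptides measured as singly protonated ions produce isotope
envelopes whose members are spaced by the 13C-12C mass difference
(1.00335 Da). Deisotoping groups features into such envelopes and keeps
only the monoisotopic (lowest-mass) member, so each peptide contributes one
feature to downstream statistics. Intensities of removed isotope features
are discarded, not summed into the monoisotopic feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FeatureMatrix

#: 13C - 12C monoisotopic mass difference (Da).
ISOTOPE_SPACING = 1.00335


@dataclass
class IsotopeEnvelope:
    """Indices of features forming one charge-1 isotope envelope."""

    member_features: list[int]
    monoisotopic_mz: float
    charge: int = 1


def find_envelopes(
    matrix: FeatureMatrix,
    max_charge: int = 1,
    iso_tolerance: float = 0.02,
    max_isotopes: int = 3,
    decline_factor: float = 1.2,
) -> list[IsotopeEnvelope]:
    """Greedy left-to-right envelope detection on the feature masses.

    Feature ``j`` joins the envelope seeded at ``i`` when its mass lies
    within ``iso_tolerance`` of ``mz_i + k * 1.00335`` for the next expected
    ``k``, and its mean intensity across spectra is at most
    ``decline_factor`` times the previous member's (a loose declining-
    envelope check, valid for peptides below ~1800 Da where the
    monoisotopic peak is the base peak). Each feature belongs to at most
    one envelope; an envelope never exceeds ``max_isotopes`` members.

    Only charge 1+ is supported; ``max_charge`` is part of the signature to
    make that assumption explicit.
    """
    if max_charge != 1:
        raise NotImplementedError("only charge 1+ deisotoping is supported")
    mz = matrix.feature_mz
    mean_int = matrix.intensities.mean(axis=0) if matrix.n_spectra else np.zeros(mz.size)
    assigned = np.zeros(mz.size, dtype=bool)
    envelopes: list[IsotopeEnvelope] = []
    for i in range(mz.size):
        if assigned[i]:
            continue
        members = [i]
        assigned[i] = True
        prev_int = mean_int[i]
        for k in range(1, max_isotopes):
            target = mz[i] + k * ISOTOPE_SPACING
            lo = np.searchsorted(mz, target - iso_tolerance, side="left")
            hi = np.searchsorted(mz, target + iso_tolerance, side="right")
            # absorb every unassigned candidate inside the slot window that
            # passes the declining check (binning can leave near-duplicate
            # features inside one window); the closest one represents the
            # slot's intensity for the next decline comparison
            slot = [
                j for j in range(lo, hi)
                if not assigned[j] and mean_int[j] <= decline_factor * prev_int
            ]
            if not slot:
                break
            best = min(slot, key=lambda j: abs(mz[j] - target))
            for j in slot:
                members.append(j)
                assigned[j] = True
            prev_int = mean_int[best]
        envelopes.append(IsotopeEnvelope(member_features=members,
                                         monoisotopic_mz=float(mz[i])))
    return envelopes


def deisotope(
    matrix: FeatureMatrix,
    iso_tolerance: float = 0.02,
    max_isotopes: int = 3,
    decline_factor: float = 1.2,
) -> tuple[FeatureMatrix, list[IsotopeEnvelope]]:
    """Keep only the monoisotopic member of every envelope.

    Returns the reduced matrix (columns unchanged for retained features)
    and the detected envelopes. Idempotent: a second pass finds only
    singleton envelopes.
    """
    envelopes = find_envelopes(
        matrix,
        iso_tolerance=iso_tolerance,
        max_isotopes=max_isotopes,
        decline_factor=decline_factor,
    )
    keep = sorted(env.member_features[0] for env in envelopes)
    return matrix.select_features(np.asarray(keep, dtype=int)), envelopes


def envelopes_to_frame(envelopes: list[IsotopeEnvelope],
                       feature_mz: np.ndarray) -> pd.DataFrame:
    """Tabular envelope report (one row per envelope)."""
    rows = [
        {
            "monoisotopic_mz": env.monoisotopic_mz,
            "charge": env.charge,
            "n_members": len(env.member_features),
            "member_mz": ";".join(
                f"{feature_mz[j]:.4f}" for j in env.member_features
            ),
        }
        for env in envelopes
    ]
    return pd.DataFrame(
        rows, columns=["monoisotopic_mz", "charge", "n_members", "member_mz"]
    )
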