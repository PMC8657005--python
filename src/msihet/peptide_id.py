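"""Peptide identity assignment by accurate-mass matching.

Significant m/z features from the imaging screen are matched against a
peptide table — either built here by in-silico tryptic digestion of a
protein collection, or loaded from a filtered LC-MS/MS identification
table — using a signed ppm mass window. Fixed carbamidomethylation of
cysteine is always applied; methionine oxidation (+15.99491 Da) and the
main formaldehyde reaction product on lysine (+12.000 Da, typical for
formalin-fixed tissue) are enumerated as variable modifications.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Monoisotopic residue masses (Da), canonical 20 amino acids.
RESIDUE_MASS = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

WATER = 18.010565
PROTON = 1.007276

#: Modification mass deltas (Da). Carbamidomethyl-C is fixed (applied to
#: every cysteine exactly once); the other two are variable.
MOD_MASS = {
    "carbamidomethyl": 57.02146,
    "oxidation": 15.99491,
    "formaldehyde": 12.000,
}

VARIABLE_MOD_TARGETS = {"oxidation": "M", "formaldehyde": "K"}


@dataclass
class PeptideRecord:
    """A (possibly modified) tryptic peptide and its theoretical [M+H]+."""

    sequence: str
    proteins: tuple[str, ...]
    mods: tuple[str, ...] = ()  # variable mods only, e.g. ("oxidation",)
    missed_cleavages: int = 0
    mh_plus: float = 0.0

    def __post_init__(self) -> None:
        if not self.mh_plus:
            self.mh_plus = peptide_mh(self.sequence, self.mods)


@dataclass
class MatchResult:
    """Candidates within the ppm window for one observed feature mass."""

    feature_mz: float
    candidates: list = field(default_factory=list)  # (PeptideRecord, ppm_error)
    status: str = "unmatched"  # unmatched | unique | family_multi | ambiguous


def _check_sequence(sequence: str) -> None:
    bad = set(sequence) - set(RESIDUE_MASS)
    if bad:
        raise ValueError(
            f"non-canonical residue(s) {sorted(bad)} in sequence {sequence!r}"
        )


def tryptic_digest(protein: str, max_missed_cleavages: int = 1) -> list[tuple[str, int]]:
    """In-silico trypsin digest: cleave after K or R, except before P.

    Returns ``(peptide, n_missed)`` pairs for 0..max_missed_cleavages missed
    cleavage sites, deduplicated per protein (first occurrence wins).
    """
    _check_sequence(protein)
    if max_missed_cleavages < 0:
        raise ValueError("max_missed_cleavages must be >= 0")
    # cut positions: after index i when protein[i] in KR and next residue != P
    cuts = [
        i + 1
        for i in range(len(protein) - 1)
        if protein[i] in "KR" and protein[i + 1] != "P"
    ]
    bounds = [0] + cuts + [len(protein)]
    out: list[tuple[str, int]] = []
    seen: set[str] = set()
    for i in range(len(bounds) - 1):
        for miss in range(max_missed_cleavages + 1):
            j = i + 1 + miss
            if j >= len(bounds):
                break
            pep = protein[bounds[i] : bounds[j]]
            if pep and pep not in seen:
                seen.add(pep)
                out.append((pep, miss))
    return out


def peptide_mh(sequence: str, variable_mods: tuple[str, ...] = ()) -> float:
    """Theoretical monoisotopic [M+H]+ of a peptide.

    Sum of residue masses + water + proton, plus carbamidomethyl on every C
    (fixed) and the given variable modifications. Each variable mod entry
    occupies one residue; there may not be more mods than matching residues.
    """
    _check_sequence(sequence)
    mass = sum(RESIDUE_MASS[aa] for aa in sequence) + WATER + PROTON
    mass += sequence.count("C") * MOD_MASS["carbamidomethyl"]
    counts: dict[str, int] = {}
    for mod in variable_mods:
        if mod not in VARIABLE_MOD_TARGETS:
            raise ValueError(f"unknown variable modification {mod!r}")
        counts[mod] = counts.get(mod, 0) + 1
        mass += MOD_MASS[mod]
    for mod, n in counts.items():
        target = VARIABLE_MOD_TARGETS[mod]
        if n > sequence.count(target):
            raise ValueError(
                f"{n}x {mod} requested but sequence has only "
                f"{sequence.count(target)} {target} residue(s)"
            )
    return mass


def enumerate_variable_mods(sequence: str, max_mods: int = 2):
    """All variable-modification multisets of a peptide, up to ``max_mods``
    simultaneous modifications (the unmodified form is always included)."""
    slots = []
    for mod, target in VARIABLE_MOD_TARGETS.items():
        slots.extend([mod] * sequence.count(target))
    combos = {()}
    for k in range(1, max_mods + 1):
        for combo in itertools.combinations(slots, k):
            combos.add(tuple(sorted(combo)))
    return sorted(combos)


def build_peptide_table(
    proteins: dict[str, str],
    max_missed_cleavages: int = 1,
    max_variable_mods: int = 2,
    min_length: int = 4,
) -> pd.DataFrame:
    """Digest a protein collection into a peptide table.

    Peptides shared between proteins are collapsed into one row whose
    ``proteins`` field lists every parent (semicolon-separated). Returns a
    DataFrame with columns (sequence, proteins, mods, missed_cleavages,
    mh_plus) sorted by mass.
    """
    parents: dict[str, set[str]] = {}
    missed: dict[str, int] = {}
    for prot_id, seq in proteins.items():
        for pep, miss in tryptic_digest(seq, max_missed_cleavages):
            if len(pep) < min_length:
                continue
            parents.setdefault(pep, set()).add(prot_id)
            missed[pep] = min(missed.get(pep, miss), miss)
    rows = []
    for pep in sorted(parents):
        for mods in enumerate_variable_mods(pep, max_variable_mods):
            rows.append(
                {
                    "sequence": pep,
                    "proteins": ";".join(sorted(parents[pep])),
                    "mods": ";".join(mods),
                    "missed_cleavages": missed[pep],
                    "mh_plus": peptide_mh(pep, mods),
                }
            )
    df = pd.DataFrame(
        rows, columns=["sequence", "proteins", "mods", "missed_cleavages", "mh_plus"]
    )
    return df.sort_values("mh_plus", kind="stable", ignore_index=True)


def _record_from_row(row) -> PeptideRecord:
    mods = tuple(m for m in str(row.mods).split(";") if m) if row.mods else ()
    return PeptideRecord(
        sequence=row.sequence,
        proteins=tuple(str(row.proteins).split(";")),
        mods=mods,
        missed_cleavages=int(row.missed_cleavages),
        mh_plus=float(row.mh_plus),
    )


def match_features(
    feature_mzs,
    peptide_table: pd.DataFrame,
    tolerance_ppm: float = 10.0,
    family_map: dict[str, str] | None = None,
) -> list[MatchResult]:
    """Match observed feature masses to the peptide table within +/- ppm.

    ppm error is signed, (observed - theoretical) / theoretical * 1e6, with
    the theoretical mass in the denominator. Status per feature:

    - ``unmatched``: no candidate inside the window;
    - ``unique``: all candidates point to one single protein;
    - ``family_multi``: several proteins, but all mapped to one family by
      ``family_map`` (kept, since family-level identity is still useful);
    - ``ambiguous``: anything else. Candidates are reported sorted by
      absolute ppm error; no winner is silently chosen.
    """
    if peptide_table.empty:
        raise ValueError("peptide table is empty")
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be positive")
    family_map = family_map or {}
    table = peptide_table.sort_values("mh_plus", kind="stable", ignore_index=True)
    masses = table["mh_plus"].to_numpy()
    results = []
    for obs in np.asarray(feature_mzs, dtype=float):
        lo = np.searchsorted(masses, obs / (1 + tolerance_ppm * 1e-6), side="left")
        hi = np.searchsorted(masses, obs / (1 - tolerance_ppm * 1e-6), side="right")
        cands = []
        for row in table.iloc[lo:hi].itertuples(index=False):
            ppm = (obs - row.mh_plus) / row.mh_plus * 1e6
            if abs(ppm) <= tolerance_ppm:
                cands.append((_record_from_row(row), ppm))
        cands.sort(key=lambda c: abs(c[1]))
        res = MatchResult(feature_mz=float(obs), candidates=cands)
        if cands:
            prot_union = sorted({p for rec, _ in cands for p in rec.proteins})
            if len(prot_union) == 1:
                res.status = "unique"
            else:
                fams = {family_map.get(p) for p in prot_union}
                if None not in fams and len(fams) == 1:
                    res.status = "family_multi"
                else:
                    res.status = "ambiguous"
        results.append(res)
    return results


def matches_to_frame(results: list[MatchResult]) -> pd.DataFrame:
    """Flatten match results into one row per feature (best candidate shown,
    all candidate proteins listed)."""
    rows = []
    for res in results:
        if res.candidates:
            best, ppm = res.candidates[0]
            rows.append(
                {
                    "feature_mz": res.feature_mz,
                    "status": res.status,
                    "sequence": best.sequence,
                    "proteins": ";".join(
                        sorted({p for rec, _ in res.candidates for p in rec.proteins})
                    ),
                    "mods": ";".join(best.mods),
                    "mh_plus": best.mh_plus,
                    "ppm_error": ppm,
                    "n_candidates": len(res.candidates),
                }
            )
        else:
            rows.append(
                {
                    "feature_mz": res.feature_mz,
                    "status": "unmatched",
                    "sequence": "",
                    "proteins": "",
                    "mods": "",
                    "mh_plus": np.nan,
                    "ppm_error": np.nan,
                    "n_candidates": 0,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "feature_mz",
            "status",
            "sequence",
            "proteins",
            "mods",
            "mh_plus",
            "ppm_error",
            "n_candidates",
        ],
    )


def load_identifications(
    path,
    min_score: float = 25.0,
    max_fdr: float = 0.01,
    mass_check_ppm: float = 5.0,
) -> pd.DataFrame:
    """Load an LC-MS/MS identification table and apply the acceptance filter.

    Rows must carry sequence, protein(s), score and FDR columns; rows with
    score < ``min_score`` or FDR > ``max_fdr`` are dropped. Masses are
    recomputed from sequence + declared mods; if the table carries its own
    mass column, disagreement beyond ``mass_check_ppm`` raises a warning.
    Malformed rows are reported with their line number.
    """
    df = pd.read_csv(path)
    required = {"sequence", "proteins", "score", "fdr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"identification table missing column(s): {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            seq = str(row["sequence"]).strip().upper()
            score = float(row["score"])
            fdr = float(row["fdr"])
            if score < min_score or fdr > max_fdr:
                continue
            mods_raw = row.get("mods", "")
            mods = tuple(
                m for m in str("" if pd.isna(mods_raw) else mods_raw).split(";") if m
            )
            mh = peptide_mh(seq, mods)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed identification row at line {line}: {exc}")
        if "mh_plus" in df.columns and not pd.isna(row["mh_plus"]):
            declared = float(row["mh_plus"])
            if abs(mh - declared) / mh * 1e6 > mass_check_ppm:
                warnings.warn(
                    f"line {line}: recomputed [M+H]+ {mh:.5f} disagrees with "
                    f"declared {declared:.5f} by more than {mass_check_ppm} ppm"
                )
        records.append(
            {
                "sequence": seq,
                "proteins": str(row["proteins"]),
                "mods": ";".join(mods),
                "missed_cleavages": int(row.get("missed_cleavages", 0) or 0),
                "mh_plus": mh,
            }
        )
    out = pd.DataFrame(
        records,
        columns=["sequence", "proteins", "mods", "missed_cleavages", "mh_plus"],
    )
    return out.sort_values("mh_plus", kind="stable", ignore_index=True)
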