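"""Overrepresentation analysis of matched protein identifiers.

Given a query set of gene/protein symbols and a term -> gene annotation map
(GMT format), each term is tested for overrepresentation with a one-sided
Fisher's exact test on the 2x2 table (in query / not x in term / not),
followed by Benjamini-Hochberg correction across tested terms. Fold
enrichment is observed / expected, with expected = query_size * term_size /
background_size. The background defaults to the union of all annotated
genes; pass an explicit background list to reproduce a genome-wide
reference set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .differential import bh_adjust


@dataclass
class AnnotationMap:
    """Term id -> gene set map over a background gene universe."""

    terms: dict[str, set] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)
    background: set = field(default_factory=set)

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {term!r} has an empty gene set")
            if not genes <= self.background:
                raise ValueError(f"term {term!r} has genes outside the background")


def load_annotation(gmt_path, background=None) -> AnnotationMap:
    """Read a GMT file (term <tab> description <tab> gene ...).

    Duplicate genes within a term are deduplicated. If ``background`` is
    given, genes outside it are dropped (with a warning when any are);
    otherwise the background is the union of all term gene sets.
    """
    terms: dict[str, set] = {}
    names: dict[str, str] = {}
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{gmt_path}: malformed GMT line {lineno} "
                    f"(need term, description, >=1 gene)"
                )
            term, desc, genes = parts[0], parts[1], set(filter(None, parts[2:]))
            if not genes:
                raise ValueError(f"{gmt_path}: line {lineno} has no genes")
            terms[term] = genes
            names[term] = desc
    if background is not None:
        background = set(background)
        dropped = 0
        for term in list(terms):
            outside = terms[term] - background
            dropped += len(outside)
            terms[term] -= outside
            if not terms[term]:
                del terms[term], names[term]
        if dropped:
            warnings.warn(
                f"{dropped} gene entries outside the explicit background dropped"
            )
    else:
        background = set().union(*terms.values()) if terms else set()
    return AnnotationMap(terms=terms, names=names, background=background)


def overrepresentation(
    query,
    annotation: AnnotationMap,
    fdr_alpha: float = 0.05,
    alternative: str = "greater",
    include_zero_observed: bool = False,
    return_all: bool = False,
) -> pd.DataFrame:
    """Fisher-exact overrepresentation of a query gene set per term.

    Query ids outside the background are dropped (logged). Terms with no
    query overlap are skipped before BH unless ``include_zero_observed``.
    Rows are sorted by q then term id; by default only rows with
    ``q <= fdr_alpha`` are returned (``return_all`` keeps everything, with
    a ``significant`` column). Fold enrichment is stored exactly; values
    above 100 are conventionally displayed as ">100" but never stored so.
    """
    query = set(query)
    inside = query & annotation.background
    n_dropped = len(query) - len(inside)
    if n_dropped:
        warnings.warn(f"{n_dropped} query id(s) outside the background dropped")
    if not inside:
        raise ValueError("query is empty after intersection with the background")
    N = len(annotation.background)
    n = len(inside)
    rows = []
    for term in sorted(annotation.terms):
        genes = annotation.terms[term]
        K = len(genes)
        members = sorted(inside & genes)
        obs = len(members)
        if obs == 0 and not include_zero_observed:
            continue
        expected = n * K / N
        table = [[obs, K - obs], [n - obs, N - K - (n - obs)]]
        p = float(stats.fisher_exact(table, alternative=alternative)[1])
        rows.append(
            {
                "term_id": term,
                "term_name": annotation.names.get(term, ""),
                "observed": obs,
                "expected": expected,
                "fold_enrichment": obs / expected,
                "p_value": p,
                "member_ids": ";".join(members),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "term_id", "term_name", "observed", "expected",
            "fold_enrichment", "p_value", "member_ids",
        ],
    )
    if out.empty:
        out["fdr_q"] = []
        out["significant"] = []
        return out
    out["fdr_q"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = out["fdr_q"] <= fdr_alpha
    out = out.sort_values(["fdr_q", "term_id"], kind="stable", ignore_index=True)
    if not return_all:
        out = out.loc[out["significant"]].reset_index(drop=True)
    return out


def format_fold(fold: float) -> str:
    """Display convention for fold enrichment: values above 100 as '>100'."""
    return ">100" if fold > 100 else f"{fold:.2f}"
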