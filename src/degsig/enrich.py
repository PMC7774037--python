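"""Hypergeometric over-representation analysis against GMT gene sets."""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from degsig.errors import ParseError, ValidationError
from degsig.diffexp import bh_adjust


@dataclass(frozen=True)
class EnrichmentRecord:
    term_id: str
    term_name: str
    k: int  # overlap of the tested set with the term, inside the universe
    n_set: int
    K: int  # term size in universe
    N: int  # universe size
    pvalue: float
    qvalue: float


# --------------------------------------------------------------------------
# GMT I/O
# --------------------------------------------------------------------------

def read_gmt(path: str | os.PathLike) -> pd.DataFrame:
    """Parse a GMT file to a frame with columns term, description, members."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT needs term, description and "
                    f"at least one member"
                )
            rows.append(
                {
                    "term": parts[0],
                    "description": parts[1],
                    "members": [m for m in parts[2:] if m],
                }
            )
    return pd.DataFrame(rows)


def write_gmt(terms: pd.DataFrame, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for row in terms.itertuples(index=False):
            fh.write("\t".join([row.term, row.description, *row.members]) + "\n")


# --------------------------------------------------------------------------
# over-representation
# --------------------------------------------------------------------------

def ora(
    geneset: Iterable[str],
    gmt: pd.DataFrame,
    universe: Iterable[str],
    min_term: int = 5,
    max_term: int = 2000,
) -> list[EnrichmentRecord]:
    """One-sided hypergeometric over-representation test per term.

    Terms are intersected with the universe before the size filter; the
    p-value is P(X >= k) for X ~ Hypergeometric(N, K, n_set), BH-adjusted
    across the retained terms.  Results are sorted by p-value (stable).
    """
    uni = set(universe)
    if not uni:
        raise ValidationError("empty universe")
    genes = set(geneset) & uni
    if not genes:
        raise ValidationError("empty gene set (after intersection with universe)")
    n_set = len(genes)
    n_uni = len(uni)

    kept = []
    for row in gmt.itertuples(index=False):
        members = set(row.members) & uni
        if min_term <= len(members) <= max_term:
            kept.append((row.term, row.description, members))
    if not kept:
        warnings.warn("no terms retained after universe intersection and size filter")
        return []

    pvals = np.array(
        [
            float(hypergeom.sf(len(members & genes) - 1, n_uni, len(members), n_set))
            for (_, _, members) in kept
        ]
    )
    qvals = bh_adjust(pvals)
    records = [
        EnrichmentRecord(
            term_id=term,
            term_name=desc,
            k=len(members & genes),
            n_set=n_set,
            K=len(members),
            N=n_uni,
            pvalue=min(max(p, 0.0), 1.0),
            qvalue=float(q),
        )
        for (term, desc, members), p, q in zip(kept, pvals, qvals)
    ]
    records.sort(key=lambda r: (r.pvalue, r.term_id))
    return records


def records_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in records],
            "term_name": [r.term_name for r in records],
            "k": [r.k for r in records],
            "n_set": [r.n_set for r in records],
            "K": [r.K for r in records],
            "N": [r.N for r in records],
            "pvalue": [r.pvalue for r in records],
            "qvalue": [r.qvalue for r in records],
        }
    )


def enrichment_report(
    up_set: Iterable[str],
    down_set: Iterable[str],
    gmt: pd.DataFrame,
    universe: Iterable[str],
    min_term: int = 5,
    max_term: int = 2000,
) -> tuple[list[EnrichmentRecord], list[EnrichmentRecord], pd.DataFrame]:
    """ORA on the up and down sets plus a per-term -log10(q) comparison table."""
    up_rec = ora(up_set, gmt, universe, min_term=min_term, max_term=max_term)
    down_rec = ora(down_set, gmt, universe, min_term=min_term, max_term=max_term)
    up_q = {r.term_id: r.qvalue for r in up_rec}
    down_q = {r.term_id: r.qvalue for r in down_rec}
    terms = sorted(set(up_q) | set(down_q))
    comparison = pd.DataFrame(
        {
            "term_id": terms,
            "neglog10_q_up": [
                -np.log10(max(up_q.get(t, 1.0), 1e-300)) for t in terms
            ],
            "neglog10_q_down": [
                -np.log10(max(down_q.get(t, 1.0), 1e-300)) for t in terms
            ],
        }
    )
    return up_rec, down_rec, comparison
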