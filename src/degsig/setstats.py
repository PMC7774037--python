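"""Gene-set statistics against phenotypes and other gene sets.

Two families of tests:

* pairwise overlap between gene lists on a fixed universe, scored with a
  2x2 Pearson chi-square (df = 1, no continuity correction);
* the competitive randomization test: the mean absolute Pearson correlation
  between a gene set's expression and a per-animal phenotype is compared to
  the means of equally sized random draws of background genes.  Significance
  follows the exceed-max rule (observed greater than every null draw, i.e.
  empirical p = 1/(B+1) at its minimum), alongside a z-score against the
  null moments.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import chi2

from degsig.errors import ValidationError
from degsig.preprocess import ExpressionMatrix
from degsig.simcohort import GENOTYPES

PHENOTYPES = ("aversion_index", "abeta42")


@dataclass(frozen=True)
class OverlapResult:
    n_both: int
    n_a_only: int
    n_b_only: int
    n_neither: int
    chi2: float
    pvalue: float


@dataclass
class AbsCorrTable:
    """Per-gene |Pearson r| against one phenotype within one genotype."""

    values: pd.Series  # index: gene ids with a defined correlation
    genotype: str
    phenotype: str
    n_undefined: int  # zero-variance genes excluded from the table


@dataclass(frozen=True)
class AssociationResult:
    set_label: str
    genotype: str
    phenotype: str
    n_set: int
    mean_abs_r: float
    null_mean: float
    null_sd: float
    z: float
    empirical_p: float
    exceeds_max: bool
    B: int
    seed: int | None
    degenerate: bool = False
    mode: str = "monte-carlo"


# --------------------------------------------------------------------------
# overlap chi-square
# --------------------------------------------------------------------------

def overlap_chisq(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> OverlapResult:
    """Pearson chi-square on the 2x2 membership table over the universe."""
    uni = set(universe)
    a = set(set_a)
    b = set(set_b)
    if len(uni) < 2:
        raise ValidationError("universe must contain at least 2 genes")
    stray = sorted((a | b) - uni)
    if stray:
        raise ValidationError(f"sets not subsets of universe: {stray[:10]}")
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = len(uni) - n11 - n10 - n01
    n = len(uni)
    row1, row0 = n11 + n10, n01 + n00
    col1, col0 = n11 + n01, n10 + n00
    if 0 in (row1, row0, col1, col0):
        raise ValidationError("degenerate margin in the 2x2 overlap table")
    stat = n * (n11 * n00 - n10 * n01) ** 2 / (row1 * row0 * col1 * col0)
    return OverlapResult(
        n_both=n11,
        n_a_only=n10,
        n_b_only=n01,
        n_neither=n00,
        chi2=float(stat),
        pvalue=float(chi2.sf(stat, df=1)),
    )


# --------------------------------------------------------------------------
# gene-phenotype correlations
# --------------------------------------------------------------------------

def gene_phenotype_abscorr(
    expr: ExpressionMatrix,
    samples: pd.DataFrame,
    genotype: str,
    phenotype: str,
) -> AbsCorrTable:
    """Per-gene |Pearson r| between expression and a phenotype, within genotype.

    Uses all samples of the requested genotype across all ages.  Genes with
    zero expression variance in the subset have no defined correlation; they
    are excluded from the table and counted in ``n_undefined``.
    """
    if genotype not in GENOTYPES:
        raise ValidationError(f"unknown genotype {genotype!r}")
    if phenotype not in samples.columns:
        raise ValidationError(f"unknown phenotype column {phenotype!r}")
    sub = samples[samples["genotype"] == genotype]
    if len(sub) < 3:
        raise ValidationError(f"need >= 3 {genotype} samples, got {len(sub)}")
    ids = [s for s in expr.sample_ids if s in set(sub["sample_id"])]
    if len(ids) < 3:
        raise ValidationError("fewer than 3 genotype samples present in matrix")
    y = sub.set_index("sample_id").loc[ids, phenotype].to_numpy(dtype=float)
    if np.std(y) == 0:
        raise ValidationError(f"phenotype {phenotype!r} constant across {genotype}")

    x = expr.values[ids].to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    defined = sx > 0
    r = np.full(x.shape[0], np.nan)
    r[defined] = (xc[defined] @ yc) / (sx[defined] * sy)
    values = pd.Series(np.abs(r), index=expr.gene_ids)
    n_undefined = int((~defined).sum())
    return AbsCorrTable(
        values=values.dropna(),
        genotype=genotype,
        phenotype=phenotype,
        n_undefined=n_undefined,
    )


# --------------------------------------------------------------------------
# competitive randomization test
# --------------------------------------------------------------------------

def _cell_seed(master_seed: int, *parts: str) -> int:
    payload = ":".join([str(master_seed), *parts]).encode()
    return int.from_bytes(hashlib.sha256(payload).digest()[:8], "big")


def set_association_test(
    abscorr: AbsCorrTable,
    geneset: Iterable[str],
    background: Iterable[str] | None = None,
    B: int = 1000,
    seed: int | None = None,
    set_label: str = "set",
    mode: str = "monte-carlo",
    exclude_set_from_background: bool = False,
) -> AssociationResult:
    """Competitive test of a gene set's mean |r| against random background sets.

    Monte-Carlo mode draws ``B`` without-replacement samples of background
    genes, each the size of the tested set; empirical p is
    (1 + #{null >= observed}) / (B + 1) and ``exceeds_max`` is True when the
    observed mean beats every draw.  Exhaustive mode enumerates all subsets
    of the background (only sensible for tiny backgrounds); there, p is the
    fraction of subsets with mean >= observed and B reports the subset count.

    Genes without a defined correlation were already excluded from the
    table; set members absent from the table are dropped symmetrically.
    """
    table = abscorr.values
    set_ids = [g for g in dict.fromkeys(geneset) if g in table.index]
    if len(set_ids) < 2:
        raise ValidationError("gene set must have >= 2 members with defined |r|")
    if background is None:
        bg_ids = list(table.index)
    else:
        bg_ids = [g for g in dict.fromkeys(background) if g in table.index]
    if exclude_set_from_background:
        setset = set(set_ids)
        bg_ids = [g for g in bg_ids if g not in setset]
    if len(bg_ids) <= len(set_ids):
        raise ValidationError(
            f"background ({len(bg_ids)}) must be larger than the set ({len(set_ids)})"
        )

    observed = float(table.loc[set_ids].mean())
    bg_vals = table.loc[bg_ids].to_numpy(dtype=float)
    k = len(set_ids)

    if mode == "exhaustive":
        n_subsets = comb(len(bg_vals), k)
        if n_subsets > 2_000_000:
            raise ValidationError(
                f"exhaustive mode infeasible: C({len(bg_vals)},{k}) subsets"
            )
        means = np.fromiter(
            (bg_vals[list(idx)].mean() for idx in combinations(range(len(bg_vals)), k)),
            dtype=float,
            count=n_subsets,
        )
        null_mean = float(means.mean())
        null_sd = float(means.std(ddof=0))
        n_ge = int((means >= observed - 1e-15).sum())
        empirical_p = n_ge / n_subsets
        exceeds_max = n_ge <= 1  # only the set itself (if in background) ties the max
        b_eff = n_subsets
    elif mode == "monte-carlo":
        rng = np.random.default_rng(seed)
        means = np.empty(B)
        for i in range(B):
            means[i] = bg_vals[rng.choice(len(bg_vals), size=k, replace=False)].mean()
        null_mean = float(means.mean())
        null_sd = float(means.std(ddof=0))
        empirical_p = (1 + int((means >= observed).sum())) / (B + 1)
        exceeds_max = bool(observed > means.max())
        b_eff = B
    else:
        raise ValidationError(f"unknown mode {mode!r}")

    degenerate = null_sd <= 1e-12 * max(1.0, abs(null_mean))
    if degenerate:
        null_sd = 0.0
    z = 0.0 if degenerate else (observed - null_mean) / null_sd
    return AssociationResult(
        set_label=set_label,
        genotype=abscorr.genotype,
        phenotype=abscorr.phenotype,
        n_set=k,
        mean_abs_r=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z=float(z),
        empirical_p=float(empirical_p),
        exceeds_max=exceeds_max,
        B=b_eff,
        seed=seed,
        degenerate=degenerate,
        mode=mode,
    )


def signature_grid(
    expr: ExpressionMatrix,
    samples: pd.DataFrame,
    genesets: Mapping[str, Iterable[str]],
    B: int = 1000,
    seed: int = 0,
    background: Iterable[str] | None = None,
    exclude_set_from_background: bool = False,
) -> tuple[pd.DataFrame, list[AssociationResult]]:
    """Run the competitive test for every (genotype, phenotype, set) cell.

    Per-cell seeds are derived by hashing the master seed with the cell
    labels, so the grid is reproducible and cells are independent.
    Returns a tidy table plus the raw results.
    """
    results: list[AssociationResult] = []
    for genotype in GENOTYPES:
        for phenotype in PHENOTYPES:
            table = gene_phenotype_abscorr(expr, samples, genotype, phenotype)
            for label, members in genesets.items():
                cell_seed = _cell_seed(seed, genotype, phenotype, str(label))
                results.append(
                    set_association_test(
                        table,
                        members,
                        background=background,
                        B=B,
                        seed=cell_seed,
                        set_label=str(label),
                        exclude_set_from_background=exclude_set_from_background,
                    )
                )
    tidy = pd.DataFrame(
        {
            "set_label": [r.set_label for r in results],
            "genotype": [r.genotype for r in results],
            "phenotype": [r.phenotype for r in results],
            "n_set": [r.n_set for r in results],
            "mean_abs_r": [r.mean_abs_r for r in results],
            "null_mean": [r.null_mean for r in results],
            "null_sd": [r.null_sd for r in results],
            "z": [r.z for r in results],
            "empirical_p": [r.empirical_p for r in results],
            "exceeds_max": [r.exceeds_max for r in results],
            "B": [r.B for r in results],
            "seed": [r.seed for r in results],
        }
    )
    return tidy, results
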