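"""Two-group negative-binomial exact-test differential expression.

Per age: TMM-normalize the age subset, map counts to a common library size,
estimate a common NB dispersion by conditional maximum likelihood, run the
two-sided exact test gene by gene, and adjust with Benjamini-Hochberg.
Directional DEG sets are pooled across ages by union.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import nbinom, poisson

from degsig.errors import ValidationError
from degsig.preprocess import tmm_factors
from degsig.simcohort import AD, WT, Cohort, CountMatrix

_TIE_TOL = 1e-12  # log-space tolerance for probability ties in the exact test


@dataclass(frozen=True)
class DEGRecord:
    gene_id: str
    age_months: int
    log2fc: float  # AD relative to WT
    pvalue: float
    fdr: float
    direction: str  # "up" (higher in AD) or "down"


@dataclass(frozen=True)
class DispersionEstimate:
    phi: float
    method: str  # "qcml", "fixed" or "poisson"
    pseudo_libsize: float


@dataclass(frozen=True)
class GeneSet:
    label: str  # "all", "up" or "down"
    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)


# --------------------------------------------------------------------------
# building blocks
# --------------------------------------------------------------------------

def quantile_adjust(
    counts: np.ndarray, effective_libsizes: np.ndarray
) -> tuple[np.ndarray, float]:
    """Scale each sample's counts to the geometric-mean common library size.

    Returns (pseudo-counts, common size).  Zeros map to zeros; equal library
    sizes leave the counts untouched.
    """
    eff = np.asarray(effective_libsizes, dtype=float)
    if (eff <= 0).any():
        raise ValidationError("effective library sizes must be > 0")
    common = float(np.exp(np.mean(np.log(eff))))
    pseudo = np.asarray(counts, dtype=float) * (common / eff)[None, :]
    return pseudo, common


def _group_cll(y: np.ndarray, r: float) -> float:
    """Conditional log-likelihood of a genes-x-samples block given row sums."""
    n = y.shape[1]
    z = y.sum(axis=1)
    ll = (
        gammaln(y + r).sum(axis=1)
        - n * gammaln(r)
        + gammaln(n * r)
        - gammaln(z + n * r)
    )
    return float(ll.sum())


def estimate_common_dispersion(
    pseudo_a: np.ndarray, pseudo_b: np.ndarray, tol: float = 1e-6
) -> DispersionEstimate:
    """Common NB dispersion by quantile-adjusted conditional max likelihood.

    Maximizes the summed conditional log-likelihood over
    delta = phi/(1+phi) in [0, 0.999] by golden-section search.  A maximum at
    the lower boundary returns phi = 0 with method "poisson".
    """
    a = np.asarray(pseudo_a, dtype=float)
    b = np.asarray(pseudo_b, dtype=float)
    if a.sum() + b.sum() <= 0:
        raise ValidationError("all-zero matrix: cannot estimate dispersion")
    common = 0.0  # informational only here; run_de records the real one

    blocks = [m for m in (a, b) if m.shape[1] >= 2]
    if not blocks:
        raise ValidationError("need at least 2 samples in some group")

    def objective(delta: float) -> float:
        delta = max(delta, 1e-12)
        r = (1.0 - delta) / delta  # r = 1/phi
        return sum(_group_cll(m, r) for m in blocks)

    lo, hi = 1e-10, 0.999
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    c = hi - invphi * (hi - lo)
    d = lo + invphi * (hi - lo)
    fc, fd = objective(c), objective(d)
    f_samples = [fc, fd]
    while hi - lo > tol:
        if fc >= fd:
            hi, d, fd = d, c, fc
            c = hi - invphi * (hi - lo)
            fc = objective(c)
            f_samples.append(fc)
        else:
            lo, c, fc = c, d, fd
            d = lo + invphi * (hi - lo)
            fd = objective(d)
            f_samples.append(fd)
    delta_hat = 0.5 * (lo + hi)

    # flat likelihood (e.g. a single gene with identical counts) -> Poisson
    if max(f_samples) - min(f_samples) < 1e-9:
        return DispersionEstimate(phi=0.0, method="poisson", pseudo_libsize=common)
    if delta_hat <= 10 * tol:
        return DispersionEstimate(phi=0.0, method="poisson", pseudo_libsize=common)
    phi = delta_hat / (1.0 - delta_hat)
    return DispersionEstimate(phi=float(phi), method="qcml", pseudo_libsize=common)


def _logpmf_groupsum(k: np.ndarray, mean: float, phi_over_n: float) -> np.ndarray:
    if phi_over_n <= 0:
        return poisson.logpmf(k, mean)
    r = 1.0 / phi_over_n
    p = r / (r + mean)
    return nbinom.logpmf(k, r, p)


def nb_exact_test(sum_a: float, n_a: int, sum_b: float, n_b: int, phi: float) -> float:
    """Two-sided exact test on two NB group sums, conditional on their total.

    Group sums are rounded to integers; under the null both group means are
    proportional to group size and the group-sum dispersions are phi/n.  The
    p-value sums the conditional probabilities of all splits no more likely
    than the observed one (ties included within a 1e-12 log tolerance).
    """
    if n_a < 1 or n_b < 1:
        raise ValidationError("both groups need at least one sample")
    if sum_a < 0 or sum_b < 0:
        raise ValidationError("group sums must be >= 0")
    a_obs = int(round(sum_a))
    b_obs = int(round(sum_b))
    total = a_obs + b_obs
    if total == 0:
        return 1.0

    mean_a = total * n_a / (n_a + n_b)
    mean_b = total * n_b / (n_a + n_b)
    support = np.arange(total + 1)
    logp = _logpmf_groupsum(support, mean_a, phi / n_a) + _logpmf_groupsum(
        support[::-1], mean_b, phi / n_b
    )
    logp -= logsumexp(logp)
    p = float(np.exp(logsumexp(logp[logp <= logp[a_obs] + _TIE_TOL])))
    return min(max(p, 0.0), 1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, clamped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# --------------------------------------------------------------------------
# per-age pipeline
# --------------------------------------------------------------------------

def de_table(
    cohort: Cohort,
    age: int,
    kept_genes: list[str] | None = None,
    prior: float = 0.5,
    fixed_phi: float | None = None,
) -> pd.DataFrame:
    """Full per-gene DE table (log2fc, pvalue, fdr, direction) at one age.

    Pipeline: TMM on the age subset -> pseudo-counts at a common library
    size -> common dispersion (conditional ML, unless ``fixed_phi``) ->
    per-gene exact test -> BH across genes.  log2fc compares AD to WT group
    mean pseudo-counts with a 0.5 prior.
    """
    sdf = cohort.samples_frame()
    sub = sdf[sdf["age_months"] == age]
    for g in (WT, AD):
        if (sub["genotype"] == g).sum() == 0:
            raise ValidationError(f"no {g} samples at age {age}")
    ids_wt = list(sub.loc[sub["genotype"] == WT, "sample_id"])
    ids_ad = list(sub.loc[sub["genotype"] == AD, "sample_id"])
    ids = ids_wt + ids_ad

    counts = cohort.counts.counts[ids]
    genes = kept_genes if kept_genes is not None else list(counts.index)
    counts = counts.loc[genes]
    sub_matrix = CountMatrix(
        counts=counts, lengths_bp=cohort.counts.lengths_bp.loc[genes]
    )
    norm = tmm_factors(sub_matrix)
    eff = norm.effective_libsize.loc[ids].to_numpy()

    pseudo, common = quantile_adjust(counts.to_numpy(), eff)
    pa = pseudo[:, : len(ids_wt)]  # WT block
    pb = pseudo[:, len(ids_wt) :]  # AD block

    if fixed_phi is not None:
        disp = DispersionEstimate(
            phi=float(fixed_phi),
            method="poisson" if fixed_phi == 0 else "fixed",
            pseudo_libsize=common,
        )
    else:
        est = estimate_common_dispersion(pa, pb)
        disp = DispersionEstimate(
            phi=est.phi, method=est.method, pseudo_libsize=common
        )

    sum_wt = pa.sum(axis=1)
    sum_ad = pb.sum(axis=1)
    pvals = np.array(
        [
            nb_exact_test(sw, len(ids_wt), sa, len(ids_ad), disp.phi)
            for sw, sa in zip(sum_wt, sum_ad)
        ]
    )
    fdr = bh_adjust(pvals)
    log2fc = np.log2(
        (pb.mean(axis=1) + prior) / (pa.mean(axis=1) + prior)
    )
    table = pd.DataFrame(
        {
            "gene_id": genes,
            "age_months": age,
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": fdr,
            "direction": np.where(log2fc > 0, "up", "down"),
        }
    ).set_index("gene_id", drop=False)
    table.attrs["dispersion"] = disp
    return table


def run_de(
    cohort: Cohort,
    age: int,
    alpha: float = 0.05,
    kept_genes: list[str] | None = None,
    **kwargs,
) -> list[DEGRecord]:
    """Significant DEGs (BH fdr < alpha) at one age, as records."""
    table = de_table(cohort, age, kept_genes=kept_genes, **kwargs)
    hits = table[table["fdr"] < alpha]
    return [
        DEGRecord(
            gene_id=row.gene_id,
            age_months=int(row.age_months),
            log2fc=float(row.log2fc),
            pvalue=float(row.pvalue),
            fdr=float(row.fdr),
            direction=row.direction,
        )
        for row in hits.itertuples(index=False)
    ]


def pool_degs(per_age: dict[int, list[DEGRecord]]) -> dict[str, GeneSet]:
    """Union directional DEG sets across ages.

    A gene up at one age and down at another belongs to both the up and down
    sets but appears once in "all" (so |up| + |down| can exceed |all|).
    """
    up: set[str] = set()
    down: set[str] = set()
    for records in per_age.values():
        for rec in records:
            (up if rec.direction == "up" else down).add(rec.gene_id)
    return {
        "all": GeneSet("all", frozenset(up | down)),
        "up": GeneSet("up", frozenset(up)),
        "down": GeneSet("down", frozenset(down)),
    }
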