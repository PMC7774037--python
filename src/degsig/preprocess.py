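"""Expression preprocessing: RPKM, gene filtering, TMM factors, logCPM, MDS.

Filtering follows two rules, applied in order: genes with exactly zero
expression variance across samples are dropped first, then genes whose
cumulative RPKM over all samples is strictly below a threshold (default 5).

TMM scaling factors are computed with the classic doubly trimmed (30% on
log-ratios M, 5% on average log-abundance A), precision-weighted mean of
per-gene log2 ratios against a reference sample, then renormalized to unit
product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from degsig.errors import ValidationError
from degsig.simcohort import CountMatrix

RPKM = "RPKM"
LOG_RPKM = "logRPKM"
LOG_CPM = "logCPM"
_SCALES = (RPKM, LOG_RPKM, LOG_CPM)


@dataclass
class ExpressionMatrix:
    values: pd.DataFrame  # genes x samples
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValidationError(f"unknown expression scale {self.scale!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class NormFactors:
    factors: pd.Series  # per sample, unit product
    effective_libsize: pd.Series  # column sum * factor
    reference: str
    diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class FilterReport:
    n_input: int
    n_zero_variance: int
    n_low_expression: int
    n_kept: int
    kept: list[str]


def compute_rpkm(counts: CountMatrix) -> ExpressionMatrix:
    """RPKM_ij = counts_ij * 1e9 / (length_i * columnsum_j)."""
    mat = counts.counts.to_numpy(dtype=float)
    colsums = mat.sum(axis=0)
    if (colsums <= 0).any():
        bad = [s for s, c in zip(counts.sample_ids, colsums) if c <= 0]
        raise ValidationError(f"zero column sum for sample(s): {bad}")
    lengths = counts.lengths_bp.to_numpy(dtype=float)
    rpkm = mat * 1e9 / (lengths[:, None] * colsums[None, :])
    return ExpressionMatrix(
        values=pd.DataFrame(rpkm, index=counts.counts.index, columns=counts.counts.columns),
        scale=RPKM,
    )


def filter_genes(
    rpkm: ExpressionMatrix,
    min_cumulative_rpkm: float = 5.0,
) -> tuple[list[str], FilterReport]:
    """Apply the zero-variance and low-cumulative-expression filters.

    A gene failing both rules is attributed to the zero-variance rule.  The
    cumulative-expression cut is strict: a row summing to exactly the
    threshold is kept.
    """
    if rpkm.scale != RPKM:
        raise ValidationError("filter_genes expects an RPKM matrix")
    vals = rpkm.values.to_numpy(dtype=float)
    if vals.size == 0:
        raise ValidationError("empty expression matrix")
    zero_var = vals.var(axis=1) == 0.0
    low = vals.sum(axis=1) < min_cumulative_rpkm
    low_only = low & ~zero_var
    keep = ~zero_var & ~low
    kept = [g for g, k in zip(rpkm.gene_ids, keep) if k]
    report = FilterReport(
        n_input=len(rpkm.gene_ids),
        n_zero_variance=int(zero_var.sum()),
        n_low_expression=int(low_only.sum()),
        n_kept=len(kept),
        kept=kept,
    )
    return kept, report


def _pick_reference(cpm: np.ndarray, sample_ids: list[str]) -> int:
    """Sample whose 75th CPM percentile is closest to the mean such percentile."""
    uq = np.quantile(cpm, 0.75, axis=0)
    return int(np.argmin(np.abs(uq - uq.mean())))


def _trim_mask(values: np.ndarray, lo_frac: float, hi_frac: float) -> np.ndarray:
    """Boolean mask keeping entries not in the lowest/highest rank fractions.

    Deterministic under ties via stable argsort on (value, original index).
    """
    n = len(values)
    k_lo = int(np.floor(lo_frac * n))
    k_hi = int(np.floor(hi_frac * n))
    order = np.argsort(values, kind="stable")
    keep = np.ones(n, dtype=bool)
    if k_lo > 0:
        keep[order[:k_lo]] = False
    if k_hi > 0:
        keep[order[n - k_hi :]] = False
    return keep


def tmm_factors(
    counts: CountMatrix,
    kept_genes: list[str] | None = None,
    ref_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormFactors:
    """Trimmed-mean-of-M-values scaling factors across samples.

    For each sample s versus the reference r, over genes positive in both:
    M = log2((c_s/N_s)/(c_r/N_r)), A = 0.5*log2((c_s/N_s)*(c_r/N_r)); the top
    and bottom ``trim_m`` of genes by M and ``trim_a`` by A are discarded and
    the factor is 2**(weighted mean of the remaining M), with inverse
    asymptotic binomial variance weights.  Factors are renormalized to unit
    product; library sizes are column sums over the kept genes.
    """
    sub = counts.counts
    if kept_genes is not None:
        sub = sub.loc[kept_genes]
    sample_ids = list(sub.columns)
    if len(sample_ids) < 2:
        raise ValidationError("TMM requires at least 2 samples")
    mat = sub.to_numpy(dtype=float)
    libsizes = mat.sum(axis=0)
    if (libsizes <= 0).any():
        bad = [s for s, c in zip(sample_ids, libsizes) if c <= 0]
        raise ValidationError(f"zero library size for sample(s): {bad}")

    cpm = mat / libsizes[None, :] * 1e6
    if ref_sample is None:
        r = _pick_reference(cpm, sample_ids)
    else:
        if ref_sample not in sample_ids:
            raise ValidationError(f"unknown reference sample {ref_sample!r}")
        r = sample_ids.index(ref_sample)

    cr = mat[:, r]
    nr = libsizes[r]
    log_factors = np.zeros(len(sample_ids))
    diag = []
    for s in range(len(sample_ids)):
        if s == r:
            diag.append({"sample_id": sample_ids[s], "trimmed_m_mean": 0.0, "weight_sum": np.inf})
            continue
        cs = mat[:, s]
        ns = libsizes[s]
        pos = (cs > 0) & (cr > 0)
        if not pos.any():
            raise ValidationError(
                f"sample {sample_ids[s]} shares no positive genes with the "
                f"reference {sample_ids[r]}"
            )
        fs = cs[pos] / ns
        fr = cr[pos] / nr
        m = np.log2(fs / fr)
        a = 0.5 * np.log2(fs * fr)
        keep = _trim_mask(m, trim_m, trim_m) & _trim_mask(a, trim_a, trim_a)
        if not keep.any():
            # heavy double trim can empty tiny gene sets; fall back to no trim
            keep = np.ones(len(m), dtype=bool)
        w_inv = (ns - cs[pos]) / (ns * cs[pos]) + (nr - cr[pos]) / (nr * cr[pos])
        w = np.where(w_inv > 0, 1.0 / np.where(w_inv > 0, w_inv, 1.0), 0.0)
        wk = w[keep]
        mk = m[keep]
        if wk.sum() <= 0:
            mean_m = float(mk.mean())
        else:
            mean_m = float(np.sum(wk * mk) / np.sum(wk))
        log_factors[s] = mean_m
        diag.append(
            {
                "sample_id": sample_ids[s],
                "trimmed_m_mean": mean_m,
                "weight_sum": float(wk.sum()),
            }
        )

    log_factors -= log_factors.mean()  # unit product
    factors = pd.Series(np.exp2(log_factors), index=sample_ids, name="tmm_factor")
    eff = pd.Series(libsizes * factors.to_numpy(), index=sample_ids, name="effective_libsize")
    return NormFactors(
        factors=factors,
        effective_libsize=eff,
        reference=sample_ids[r],
        diagnostics=pd.DataFrame(diag).set_index("sample_id"),
    )


def log_expression(
    counts: CountMatrix,
    norm: NormFactors,
    kept_genes: list[str] | None = None,
    prior: float = 0.5,
) -> ExpressionMatrix:
    """logCPM_ij = log2((c_ij + prior) / (effective_libsize_j + 2*prior) * 1e6)."""
    sub = counts.counts
    if kept_genes is not None:
        sub = sub.loc[kept_genes]
    eff = norm.effective_libsize.loc[list(sub.columns)].to_numpy(dtype=float)
    vals = np.log2(
        (sub.to_numpy(dtype=float) + prior) / (eff[None, :] + 2.0 * prior) * 1e6
    )
    return ExpressionMatrix(
        values=pd.DataFrame(vals, index=sub.index, columns=sub.columns), scale=LOG_CPM
    )


def _pairwise_top_rms(mat: np.ndarray, top_genes: int) -> np.ndarray:
    n = mat.shape[1]
    d = np.zeros((n, n))
    k = min(top_genes, mat.shape[0])
    for s in range(n):
        for t in range(s + 1, n):
            diff2 = (mat[:, s] - mat[:, t]) ** 2
            if k < len(diff2):
                top = np.partition(diff2, len(diff2) - k)[len(diff2) - k :]
            else:
                top = diff2
            d[s, t] = d[t, s] = float(np.sqrt(top.mean()))
    return d


def mds_coordinates(
    logcpm: ExpressionMatrix,
    top_genes: int = 500,
    dims: int = 2,
) -> pd.DataFrame:
    """Classical (Torgerson) MDS of samples.

    The distance between two samples is the root-mean-square of the
    ``top_genes`` largest absolute gene-wise logCPM differences.  Axes are
    ordered by eigenvalue; the sign of each axis is fixed so that its first
    nonzero coordinate is positive.
    """
    n = len(logcpm.sample_ids)
    if n < 3:
        raise ValidationError("MDS requires at least 3 samples")
    if dims >= n:
        raise ValidationError(f"dims ({dims}) must be < number of samples ({n})")
    mat = logcpm.values.to_numpy(dtype=float)
    d = _pairwise_top_rms(mat, top_genes)

    d2 = d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    lam = np.clip(evals[:dims], 0.0, None)
    coords = evecs[:, :dims] * np.sqrt(lam)[None, :]
    for k in range(dims):
        col = coords[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if len(nz) and col[nz[0]] < 0:
            coords[:, k] = -col
    return pd.DataFrame(
        coords,
        index=logcpm.sample_ids,
        columns=[f"dim{k + 1}" for k in range(dims)],
    )
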