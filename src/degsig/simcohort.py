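"""Synthetic longitudinal cohort generator.

Produces gene-level count matrices for a two-genotype (WT vs AD), multi-age,
replicated design together with per-animal phenotypes (aversion index from a
taste-aversion task, amyloid-beta-42 concentration) and a full truth table of
planted effects, so that every downstream analysis stage can be verified
against known ground truth.

Generative model (all draws from one seeded :class:`numpy.random.Generator`):

1. per-gene relative abundance ``q_i`` from a log-normal, normalized to sum
   to one; per-sample sequencing depth ``N_j`` uniform in ``depth_range``;
2. amyloid: WT animals ~ Normal(baseline mean, sd) truncated at zero; AD
   animals follow ``intercept + slope * (age - min age)`` plus Normal noise,
   truncated at zero;
3. a latent cortical-function variable ``L_j``: WT ~ Normal(1, sd); in AD,
   ``L = 1 - gamma * abeta / max(abeta)`` plus noise, so L degrades as
   amyloid accumulates;
4. aversion index via a logistic link on ``L`` (WT) or, when decoupling is
   enabled (default), on an age-driven decline term (AD) — this severs the
   behavior/expression correlation in AD animals while leaving it intact in
   WT;
5. counts ~ NegativeBinomial(mean ``q_i * N_j * 2**eta_ij``, dispersion
   ``phi``), with ``eta_ij = [AD and age active] * lfc_i +
   beta_i * (L_j - 1)``; ``beta_i`` is nonzero only for "signature" genes, a
   subset of the down-regulated DEGs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from degsig.errors import ConfigError, ParseError, ValidationError

WT = "WT"
AD = "AD"
GENOTYPES = (WT, AD)

STATUS_NULL = "null"
STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_SIGNATURE = "signature"


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AbetaParams:
    """Amyloid-beta-42 generative parameters (pg/mL)."""

    wt_mean: float = 45.0
    wt_sd: float = 9.0
    ad_intercept: float = 250.0
    ad_slope: float = 7.0  # per month past the youngest age
    ad_sd: float = 180.0


@dataclass(frozen=True)
class LatentParams:
    """Latent cortical-function variable L.

    L has ``n_factors`` independent components per mouse; signature genes
    couple to one component each (round robin) and behavior couples to the
    component mean.  Splitting the latent variable keeps the planted
    couplings intact while preventing a single chance correlation between
    phenotype noise and one shared factor from moving every signature gene
    at once (which would make the competitive test's null cells heavy
    tailed at n = 15 animals per genotype).
    """

    wt_sd: float = 0.4
    gamma: float = 1.2  # amyloid-driven degradation in AD
    ad_noise_sd: float = 0.08
    n_factors: int = 1


@dataclass(frozen=True)
class BehaviorParams:
    """Logistic link from latent function to the aversion index.

    Lower aversion index = stronger learned aversion = better learning, so
    ``slope`` is negative: higher cortical function gives lower consumption
    of the aversive flavor.  With ``decouple`` on (default), AD behavior is
    driven by an age-decline term instead of L, with larger noise.
    """

    intercept: float = 1.2
    slope: float = -3.0
    wt_noise_sd: float = 0.10
    ad_noise_sd: float = 1.5
    decouple: bool = True
    ad_age_decline: float = 0.05  # total drop of the age-driven term over the age span


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 5000
    ages: tuple[int, ...] = (2, 7, 8, 11, 14)
    n_rep: int = 3
    n_up_total: int = 829
    n_down_total: int = 1125
    de_age_profile: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    lfc_range: tuple[float, float] = (1.0, 2.0)
    n_signature: int = 300
    beta_range: tuple[float, float] = (0.4, 0.6)
    dispersion: float = 0.1
    depth_range: tuple[float, float] = (0.8e6, 1.2e6)
    abeta_params: AbetaParams = field(default_factory=AbetaParams)
    latent_params: LatentParams = field(default_factory=LatentParams)
    behavior_params: BehaviorParams = field(default_factory=BehaviorParams)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if len(self.ages) < 1 or len(set(self.ages)) != len(self.ages):
            raise ConfigError("ages must be non-empty and unique")
        if self.n_rep < 1:
            raise ConfigError("n_rep must be >= 1")
        for name in ("n_up_total", "n_down_total", "n_signature"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_up_total + self.n_down_total + self.n_signature > self.n_genes:
            raise ConfigError(
                "n_up_total + n_down_total + n_signature must not exceed n_genes"
            )
        if self.n_signature > self.n_down_total:
            raise ConfigError("n_signature must not exceed n_down_total")
        if len(self.de_age_profile) != len(self.ages):
            raise ConfigError("de_age_profile must have one entry per age")
        if any(not (0.0 <= f <= 1.0) for f in self.de_age_profile):
            raise ConfigError("de_age_profile values must lie in [0, 1]")
        if not (0 < self.lfc_range[0] <= self.lfc_range[1]):
            raise ConfigError("lfc_range must satisfy 0 < lo <= hi")
        if not (0 <= self.beta_range[0] <= self.beta_range[1]):
            raise ConfigError("beta_range must satisfy 0 <= lo <= hi")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if not (0 < self.depth_range[0] <= self.depth_range[1]):
            raise ConfigError("depth_range must satisfy 0 < lo <= hi")
        ab, lt, bh = self.abeta_params, self.latent_params, self.behavior_params
        if ab.wt_sd <= 0 or ab.ad_sd <= 0:
            raise ConfigError("abeta_params sd values must be > 0")
        if lt.wt_sd <= 0 or lt.ad_noise_sd <= 0:
            raise ConfigError("latent_params sd values must be > 0")
        if lt.n_factors < 1:
            raise ConfigError("latent_params.n_factors must be >= 1")
        if bh.wt_noise_sd <= 0 or bh.ad_noise_sd <= 0:
            raise ConfigError("behavior_params noise sd values must be > 0")

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def scaled_sim_config(n_genes: int, seed: int = 0, **kwargs) -> SimConfig:
    """Default config with planted-set sizes scaled to ``n_genes``.

    Keeps the default proportions of up/down/signature genes (829/1125/300
    out of 5000) so desk-scale cohorts preserve the default structure.
    """
    base = SimConfig()
    scale = n_genes / base.n_genes
    cfg = SimConfig(
        n_genes=n_genes,
        n_up_total=int(round(base.n_up_total * scale)),
        n_down_total=int(round(base.n_down_total * scale)),
        n_signature=int(round(base.n_signature * scale)),
        seed=seed,
        **kwargs,
    )
    cfg.validate()
    return cfg


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    genotype: str
    age_months: int
    replicate: int
    aversion_index: float
    abeta42: float

    def validate(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValidationError(f"unknown genotype {self.genotype!r}")
        if not (0.0 <= self.aversion_index <= 1.0):
            raise ValidationError(
                f"aversion_index {self.aversion_index} outside [0, 1] "
                f"for sample {self.sample_id}"
            )
        if self.abeta42 < 0:
            raise ValidationError(f"abeta42 < 0 for sample {self.sample_id}")


@dataclass
class CountMatrix:
    """Integer read counts (genes x samples) with per-gene lengths."""

    counts: pd.DataFrame  # index: gene ids, columns: sample ids
    lengths_bp: pd.Series  # index: gene ids

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def validate(self) -> None:
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise ValidationError("counts must be integer")
        if (vals < 0).any():
            raise ValidationError("counts must be non-negative")
        if not self.lengths_bp.index.equals(self.counts.index):
            raise ValidationError("lengths_bp index must match counts index")
        if (self.lengths_bp.to_numpy() < 1).any():
            raise ValidationError("gene lengths must be >= 1 bp")
        colsums = vals.sum(axis=0)
        if (colsums <= 0).any():
            bad = [s for s, c in zip(self.counts.columns, colsums) if c <= 0]
            raise ValidationError(f"zero column sum for sample(s): {bad}")


@dataclass
class SimTruth:
    """Planted effects: per-gene status/effects and per-sample latent L."""

    genes: pd.DataFrame  # index gene_id; columns status, active_ages, lfc, beta
    latent: pd.Series  # index sample_id; latent L per animal


@dataclass
class Cohort:
    counts: CountMatrix
    samples: list[SampleInfo]
    truth: SimTruth | None = None

    def samples_frame(self) -> pd.DataFrame:
        return samples_to_frame(self.samples)


def samples_to_frame(samples: Sequence[SampleInfo]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "genotype": [s.genotype for s in samples],
            "age_months": [s.age_months for s in samples],
            "replicate": [s.replicate for s in samples],
            "aversion_index": [s.aversion_index for s in samples],
            "abeta42": [s.abeta42 for s in samples],
        }
    )
    return df.set_index("sample_id", drop=False)


def _check_unique_design(samples: Sequence[SampleInfo]) -> None:
    keys = [(s.genotype, s.age_months, s.replicate) for s in samples]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValidationError(f"duplicated (genotype, age, replicate): {dupes}")
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicated sample_id")


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB draws with variance mu + phi*mu^2; phi == 0 falls back to Poisson."""
    mu = np.asarray(mu, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    pois = phi <= 0
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    if (~pois).any():
        r = 1.0 / phi[~pois]
        p = r / (r + mu[~pois])
        out[~pois] = rng.negative_binomial(r, p)
    return out


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate a full synthetic cohort (counts, phenotypes, truth).

    Deterministic given ``config`` (including its ``seed``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cfg = config

    n_genes = cfg.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    ages = list(cfg.ages)
    min_age, max_age = min(ages), max(ages)
    age_span = max(max_age - min_age, 1)

    # (1) baselines, lengths, depths
    lengths = np.clip(
        np.round(rng.lognormal(mean=7.6, sigma=0.6, size=n_genes)), 200, 100_000
    ).astype(np.int64)
    # moderate abundance spread: keeps counts informative even for genes
    # knocked down by the largest planted fold change, so the competitive
    # test's background stays comparable to the DEG sets
    q = rng.lognormal(mean=0.0, sigma=0.9, size=n_genes)
    q /= q.sum()

    # gene status assignment: one permutation; up block, then down block with
    # the signature genes placed first so they stay DE-active at every age
    # for any non-degenerate de_age_profile
    perm = rng.permutation(n_genes)
    up_idx = perm[: cfg.n_up_total]
    down_idx = perm[cfg.n_up_total : cfg.n_up_total + cfg.n_down_total]
    sig_idx = down_idx[: cfg.n_signature]

    status = np.full(n_genes, STATUS_NULL, dtype=object)
    status[up_idx] = STATUS_UP
    status[down_idx] = STATUS_DOWN
    status[sig_idx] = STATUS_SIGNATURE

    lfc = np.zeros(n_genes)
    lfc[up_idx] = rng.uniform(*cfg.lfc_range, size=len(up_idx))
    lfc[down_idx] = -rng.uniform(*cfg.lfc_range, size=len(down_idx))

    beta = np.zeros(n_genes)
    beta[sig_idx] = rng.uniform(*cfg.beta_range, size=len(sig_idx))

    # nested per-age activation: at each age the first round(frac * n) genes
    # of the block order are active, so active counts follow the profile
    # exactly and active sets at later ages nest inside earlier ones when
    # the profile is non-increasing
    active = np.zeros((n_genes, len(ages)), dtype=bool)
    for a, frac in enumerate(cfg.de_age_profile):
        k_up = int(round(frac * len(up_idx)))
        k_down = int(round(frac * len(down_idx)))
        active[up_idx[:k_up], a] = True
        active[down_idx[:k_down], a] = True

    # sample scaffold in fixed order: age-major, genotype (WT, AD), replicate
    design: list[tuple[str, int, int]] = [
        (g, age, r) for age in ages for g in GENOTYPES for r in range(1, cfg.n_rep + 1)
    ]
    n_samples = len(design)
    sample_ids = [f"{g}_{age}m_r{r}" for (g, age, r) in design]
    genos = np.array([g for (g, _, _) in design])
    s_ages = np.array([age for (_, age, _) in design])
    is_ad = genos == AD

    depths = rng.uniform(*cfg.depth_range, size=n_samples)

    # (2) amyloid
    ab = cfg.abeta_params
    abeta = np.empty(n_samples)
    wt_noise = rng.normal(0.0, ab.wt_sd, size=n_samples)
    ad_noise = rng.normal(0.0, ab.ad_sd, size=n_samples)
    abeta[~is_ad] = ab.wt_mean + wt_noise[~is_ad]
    abeta[is_ad] = (
        ab.ad_intercept + ab.ad_slope * (s_ages[is_ad] - min_age) + ad_noise[is_ad]
    )
    abeta = np.clip(abeta, 0.0, None)

    # (3) latent cortical function: n_factors independent components per
    # mouse; in AD each component shares the systematic amyloid-driven
    # decline plus its own noise
    lt = cfg.latent_params
    n_fac = lt.n_factors
    latent_fac = np.empty((n_fac, n_samples))
    latent_fac[:, ~is_ad] = 1.0 + rng.normal(
        0.0, lt.wt_sd, size=(n_fac, (~is_ad).sum())
    )
    ad_abeta_max = abeta[is_ad].max() if is_ad.any() else 1.0
    ad_abeta_max = max(ad_abeta_max, 1e-12)
    latent_fac[:, is_ad] = (
        1.0
        - lt.gamma * abeta[is_ad][None, :] / ad_abeta_max
        + rng.normal(0.0, lt.ad_noise_sd, size=(n_fac, is_ad.sum()))
    )
    # standardize each factor within genotype to its nominal scale (mean
    # kept, sd exactly wt_sd); correlations are affine-invariant, so this
    # only pins the coupling amplitude, removing seed-to-seed power drift
    for mask in (~is_ad, is_ad):
        if mask.sum() >= 2:
            block = latent_fac[:, mask]
            mu_b = block.mean(axis=1, keepdims=True)
            sd_b = block.std(axis=1, keepdims=True)
            sd_b = np.where(sd_b > 0, sd_b, 1.0)
            latent_fac[:, mask] = mu_b + (block - mu_b) / sd_b * lt.wt_sd
    latent = latent_fac.mean(axis=0)  # per-mouse summary, drives behavior

    # signature gene -> component, round robin in signature order
    gene_factor = np.full(n_genes, -1, dtype=np.int64)
    gene_factor[sig_idx] = np.arange(len(sig_idx)) % n_fac

    # (4) behavior
    bh = cfg.behavior_params
    aversion = np.empty(n_samples)
    aversion[~is_ad] = _logistic(
        bh.intercept
        + bh.slope * latent[~is_ad]
        + rng.normal(0.0, bh.wt_noise_sd, size=(~is_ad).sum())
    )
    if bh.decouple:
        c_age = 1.0 - bh.ad_age_decline * (s_ages[is_ad] - min_age) / age_span
        drive = c_age
    else:
        drive = latent[is_ad]
    aversion[is_ad] = _logistic(
        bh.intercept
        + bh.slope * drive
        + rng.normal(0.0, bh.ad_noise_sd, size=is_ad.sum())
    )

    # (5) counts
    age_col = np.array([ages.index(a) for a in s_ages])
    gene_latent = latent_fac[np.where(gene_factor >= 0, gene_factor, 0), :]
    eta = beta[:, None] * (gene_latent - 1.0)
    de_on = active[:, age_col] & is_ad[None, :]
    eta = eta + np.where(de_on, lfc[:, None], 0.0)
    mu = q[:, None] * depths[None, :] * np.exp2(eta)
    counts = _draw_counts(rng, mu, cfg.dispersion)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    lengths_s = pd.Series(lengths, index=gene_ids, name="length_bp")
    matrix = CountMatrix(counts=counts_df, lengths_bp=lengths_s)

    samples = [
        SampleInfo(
            sample_id=sid,
            genotype=g,
            age_months=int(age),
            replicate=int(r),
            aversion_index=float(aversion[j]),
            abeta42=float(abeta[j]),
        )
        for j, (sid, (g, age, r)) in enumerate(zip(sample_ids, design))
    ]
    for s in samples:
        s.validate()
    _check_unique_design(samples)

    active_ages = [
        ",".join(str(ages[a]) for a in range(len(ages)) if active[i, a])
        for i in range(n_genes)
    ]
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "status": status,
            "active_ages": active_ages,
            "lfc": lfc,
            "beta": beta,
            "latent_factor": gene_factor,
        }
    ).set_index("gene_id", drop=False)
    truth = SimTruth(
        genes=genes, latent=pd.Series(latent, index=sample_ids, name="latent")
    )
    return Cohort(counts=matrix, samples=samples, truth=truth)


# --------------------------------------------------------------------------
# disk round trip (plain TSV)
# --------------------------------------------------------------------------

COUNTS_FILE = "counts.tsv"
SAMPLES_FILE = "samples.tsv"
TRUTH_GENES_FILE = "truth.tsv"
TRUTH_LATENT_FILE = "truth_latent.tsv"


def write_cohort(cohort: Cohort, out_dir: str | os.PathLike) -> list[str]:
    """Write a cohort as tab-delimited text; returns the paths written."""
    os.makedirs(out_dir, exist_ok=True)
    written = []

    counts = cohort.counts.counts.copy()
    counts.insert(0, "length_bp", cohort.counts.lengths_bp)
    counts.insert(0, "gene_id", counts.index)
    path = os.path.join(out_dir, COUNTS_FILE)
    counts.to_csv(path, sep="\t", index=False)
    written.append(path)

    path = os.path.join(out_dir, SAMPLES_FILE)
    cohort.samples_frame().to_csv(path, sep="\t", index=False)
    written.append(path)

    if cohort.truth is not None:
        path = os.path.join(out_dir, TRUTH_GENES_FILE)
        cohort.truth.genes.to_csv(path, sep="\t", index=False)
        written.append(path)
        path = os.path.join(out_dir, TRUTH_LATENT_FILE)
        cohort.truth.latent.rename_axis("sample_id").reset_index().to_csv(
            path, sep="\t", index=False
        )
        written.append(path)
    return written


def _read_tsv(path: str, required: Sequence[str]) -> pd.DataFrame:
    if not os.path.exists(path):
        raise ParseError(f"{path}: file not found")
    try:
        # round_trip parsing so written floats read back bit-identical;
        # default NA tokens disabled because "null" is a legitimate gene
        # status and empty active_ages strings must stay empty strings
        df = pd.read_csv(
            path, sep="\t", float_precision="round_trip",
            keep_default_na=False, na_values=[],
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    return df


def read_cohort(in_dir: str | os.PathLike) -> Cohort:
    """Read a cohort written by :func:`write_cohort`, validating invariants."""
    cpath = os.path.join(in_dir, COUNTS_FILE)
    cdf = _read_tsv(cpath, ["gene_id", "length_bp"])
    sample_cols = [c for c in cdf.columns if c not in ("gene_id", "length_bp")]
    if not sample_cols:
        raise ParseError(f"{cpath}: no sample columns")
    counts = cdf.set_index("gene_id")[sample_cols]
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        raise ParseError(f"{cpath}: counts must be integers")
    if (arr < 0).any():
        g, s = np.argwhere(arr < 0)[0]
        # +2: header line plus 1-based numbering
        raise ParseError(
            f"{cpath}: negative count at line {g + 2} (gene {counts.index[g]}, "
            f"sample {sample_cols[s]})"
        )
    lengths = cdf.set_index("gene_id")["length_bp"]
    if (lengths.to_numpy() < 1).any():
        bad = lengths.index[lengths < 1][0]
        raise ParseError(f"{cpath}: length_bp < 1 for gene {bad}")
    matrix = CountMatrix(counts=counts, lengths_bp=lengths)
    matrix.validate()

    spath = os.path.join(in_dir, SAMPLES_FILE)
    sdf = _read_tsv(
        spath,
        ["sample_id", "genotype", "age_months", "replicate", "aversion_index", "abeta42"],
    )
    samples = [
        SampleInfo(
            sample_id=str(row.sample_id),
            genotype=str(row.genotype),
            age_months=int(row.age_months),
            replicate=int(row.replicate),
            aversion_index=float(row.aversion_index),
            abeta42=float(row.abeta42),
        )
        for row in sdf.itertuples(index=False)
    ]
    for s in samples:
        s.validate()
    _check_unique_design(samples)
    if set(s.sample_id for s in samples) != set(sample_cols):
        raise ValidationError(
            f"{spath}: sample ids do not match count matrix columns"
        )

    truth = None
    tg = os.path.join(in_dir, TRUTH_GENES_FILE)
    tl = os.path.join(in_dir, TRUTH_LATENT_FILE)
    if os.path.exists(tg) and os.path.exists(tl):
        genes = _read_tsv(tg, ["gene_id", "status", "active_ages", "lfc", "beta"])
        genes["active_ages"] = genes["active_ages"].fillna("")
        genes = genes.set_index("gene_id", drop=False)
        ldf = _read_tsv(tl, ["sample_id", "latent"])
        latent = ldf.set_index("sample_id")["latent"]
        truth = SimTruth(genes=genes, latent=latent)

    return Cohort(counts=matrix, samples=samples, truth=truth)


# --------------------------------------------------------------------------
# synthetic annotation (GMT fixture with optional planted enrichment)
# --------------------------------------------------------------------------

def make_annotation(
    truth: SimTruth,
    n_terms: int,
    enriched_fraction: float,
    seed: int,
    term_size_range: tuple[int, int] = (20, 200),
    planted_weight: float = 0.75,
) -> pd.DataFrame:
    """Build a synthetic term table (columns: term, description, members).

    ``enriched_fraction`` of the terms are "planted": each draws
    ``planted_weight`` of its members from the signature/down-regulated gene
    pool and the rest uniformly; remaining terms are uniform draws over all
    genes.  Planted terms are named ``PLANTED###``, others ``RAND###``.
    """
    if n_terms < 1:
        raise ConfigError("n_terms must be >= 1")
    if not (0.0 <= enriched_fraction <= 1.0):
        raise ConfigError("enriched_fraction must lie in [0, 1]")
    lo, hi = term_size_range
    if not (1 <= lo <= hi):
        raise ConfigError("term_size_range must satisfy 1 <= lo <= hi")

    rng = np.random.default_rng(seed)
    all_genes = np.asarray(truth.genes["gene_id"], dtype=object)
    down_pool = np.asarray(
        truth.genes.loc[
            truth.genes["status"].isin([STATUS_DOWN, STATUS_SIGNATURE]), "gene_id"
        ],
        dtype=object,
    )
    n_planted = int(round(enriched_fraction * n_terms))

    rows = []
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(all_genes))
        planted = t < n_planted and len(down_pool) > 0
        if planted:
            n_from_pool = min(int(round(planted_weight * size)), len(down_pool))
            members = list(rng.choice(down_pool, size=n_from_pool, replace=False))
            rest = np.setdiff1d(all_genes, np.asarray(members, dtype=object))
            n_rest = min(size - n_from_pool, len(rest))
            if n_rest > 0:
                members += list(rng.choice(rest, size=n_rest, replace=False))
            name = f"PLANTED{t:03d}"
            desc = "planted down-enriched term"
        else:
            members = list(rng.choice(all_genes, size=size, replace=False))
            name = f"RAND{t:03d}"
            desc = "uniform random term"
        rows.append({"term": name, "description": desc, "members": sorted(members)})
    return pd.DataFrame(rows)
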