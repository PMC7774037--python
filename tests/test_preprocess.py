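import numpy as np
import pandas as pd
import pytest

from degsig.errors import ValidationError
from degsig.preprocess import (
    RPKM,
    ExpressionMatrix,
    compute_rpkm,
    filter_genes,
    log_expression,
    mds_coordinates,
    tmm_factors,
    _trim_mask,
)
from degsig.simcohort import AD, WT, CountMatrix, SimConfig, simulate_cohort


def make_matrix(counts, lengths=None, prefix="S"):
    counts = np.asarray(counts, dtype=np.int64)
    genes = [f"G{i}" for i in range(counts.shape[0])]
    samples = [f"{prefix}{j}" for j in range(counts.shape[1])]
    if lengths is None:
        lengths = np.full(counts.shape[0], 1000)
    return CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        lengths_bp=pd.Series(lengths, index=genes),
    )


# --------------------------------------------------------------------------
# RPKM
# --------------------------------------------------------------------------

class TestRpkm:
    def test_arithmetic_identity(self):
        # 10 counts, 1 kb gene, 1e6 library -> RPKM 10
        counts = np.zeros((2, 1), dtype=int)
        counts[0, 0] = 10
        counts[1, 0] = 1_000_000 - 10
        cm = make_matrix(counts, lengths=[1000, 1000])
        rpkm = compute_rpkm(cm)
        assert rpkm.values.iloc[0, 0] == pytest.approx(10.0)

    def test_zero_counts_zero_rpkm(self):
        cm = make_matrix([[0, 5], [10, 3]])
        rpkm = compute_rpkm(cm)
        assert rpkm.values.iloc[0, 0] == 0.0

    def test_matches_brute_force(self, rng):
        counts = rng.integers(0, 400, size=(20, 4))
        lengths = rng.integers(200, 5000, size=20)
        cm = make_matrix(counts, lengths=lengths)
        rpkm = compute_rpkm(cm).values.to_numpy()
        colsum = counts.sum(axis=0)
        for i in range(20):
            for j in range(4):
                expected = counts[i, j] * 1e9 / (lengths[i] * colsum[j])
                assert rpkm[i, j] == pytest.approx(expected, rel=1e-12)

    def test_zero_column_sum_names_sample(self):
        cm = make_matrix([[0, 5], [0, 3]])
        with pytest.raises(ValidationError, match="S0"):
            compute_rpkm(cm)


# --------------------------------------------------------------------------
# filtering
# --------------------------------------------------------------------------

class TestFilterGenes:
    def _rpkm_from(self, values):
        values = np.asarray(values, dtype=float)
        genes = [f"G{i}" for i in range(values.shape[0])]
        samples = [f"S{j}" for j in range(values.shape[1])]
        return ExpressionMatrix(
            values=pd.DataFrame(values, index=genes, columns=samples), scale=RPKM
        )

    def test_constant_row_dropped_as_zero_variance(self):
        rpkm = self._rpkm_from([[1.0] * 30, [1.0, 2.0] + [3.0] * 28])
        kept, report = filter_genes(rpkm)
        assert "G0" not in kept and "G1" in kept
        assert report.n_zero_variance == 1

    def test_cumulative_threshold_is_strict(self):
        row_low = [4.99 / 30] * 29 + [4.99 - 29 * (4.99 / 30)]
        row_keep = [5.00 / 30] * 29 + [5.00 - 29 * (5.00 / 30)]
        # perturb one entry so variance is nonzero without changing the sum
        row_low[0] += 0.001
        row_low[1] -= 0.001
        row_keep[0] += 0.001
        row_keep[1] -= 0.001
        assert sum(row_low) < 5.0 and sum(row_keep) >= 5.0
        rpkm = self._rpkm_from([row_low, row_keep])
        kept, report = filter_genes(rpkm)
        assert kept == ["G1"]
        assert report.n_low_expression == 1

    def test_all_zero_gene_attributed_to_zero_variance(self):
        rpkm = self._rpkm_from([[0.0] * 5, [1.0, 2.0, 3.0, 4.0, 5.0]])
        kept, report = filter_genes(rpkm)
        assert report.n_zero_variance == 1
        assert report.n_low_expression == 0

    def test_idempotent(self, default_cohort):
        rpkm = compute_rpkm(default_cohort.counts)
        kept, _ = filter_genes(rpkm)
        filtered = ExpressionMatrix(values=rpkm.values.loc[kept], scale=RPKM)
        kept2, report2 = filter_genes(filtered)
        assert kept2 == kept
        assert report2.n_zero_variance == 0
        assert report2.n_low_expression == 0

    def test_empty_matrix_errors(self):
        with pytest.raises(ValidationError, match="empty"):
            filter_genes(self._rpkm_from(np.empty((0, 0))))


# --------------------------------------------------------------------------
# TMM
# --------------------------------------------------------------------------

def tmm_factor_oracle(counts, s, r, trim_m=0.30, trim_a=0.05):
    """Loop-based reimplementation of the doubly trimmed weighted M mean."""
    counts = np.asarray(counts, dtype=float)
    ns = counts[:, s].sum()
    nr = counts[:, r].sum()
    rows = [
        (counts[g, s] / ns, counts[g, r] / nr, counts[g, s], counts[g, r])
        for g in range(counts.shape[0])
        if counts[g, s] > 0 and counts[g, r] > 0
    ]
    m = np.array([np.log2(fs / fr) for fs, fr, _, _ in rows])
    a = np.array([0.5 * np.log2(fs * fr) for fs, fr, _, _ in rows])
    n = len(rows)
    k_m = int(np.floor(trim_m * n))
    k_a = int(np.floor(trim_a * n))
    order_m = np.argsort(m, kind="stable")
    order_a = np.argsort(a, kind="stable")
    keep = np.ones(n, dtype=bool)
    keep[order_m[:k_m]] = False
    if k_m:
        keep[order_m[n - k_m:]] = False
    keep[order_a[:k_a]] = False
    if k_a:
        keep[order_a[n - k_a:]] = False
    num = den = 0.0
    for i in range(n):
        if not keep[i]:
            continue
        _, _, cs, cr = rows[i]
        w_inv = (ns - cs) / (ns * cs) + (nr - cr) / (nr * cr)
        w = 1.0 / w_inv
        num += w * m[i]
        den += w
    return 2.0 ** (num / den)


class TestTmm:
    def test_identical_columns_unit_factors(self):
        col = np.arange(1, 101)
        cm = make_matrix(np.column_stack([col] * 4))
        nf = tmm_factors(cm)
        assert np.allclose(nf.factors, 1.0)

    def test_pure_depth_change_equal_factors(self, rng):
        col = rng.integers(1, 500, size=300)
        cm = make_matrix(np.column_stack([col, 3 * col, col]))
        nf = tmm_factors(cm, ref_sample="S0")
        assert nf.factors["S1"] == pytest.approx(nf.factors["S0"], abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        from conftest import nb_matrix

        counts = nb_matrix(rng, 200, 4)
        cm = make_matrix(counts)
        nf = tmm_factors(cm, ref_sample="S0")
        raw = np.array(
            [1.0] + [tmm_factor_oracle(counts, s, 0) for s in range(1, 4)]
        )
        normalized = raw / np.exp(np.mean(np.log(raw)))
        for s in range(4):
            assert nf.factors.iloc[s] == pytest.approx(normalized[s], abs=1e-10)

    def test_unit_product_invariant(self, default_cohort):
        nf = tmm_factors(default_cohort.counts)
        assert np.prod(nf.factors.to_numpy()) == pytest.approx(1.0, abs=1e-9)

    def test_gene_permutation_invariance(self, rng):
        from conftest import nb_matrix

        counts = nb_matrix(rng, 150, 3)
        cm = make_matrix(counts)
        perm = rng.permutation(150)
        cm_perm = CountMatrix(
            counts=cm.counts.iloc[perm], lengths_bp=cm.lengths_bp.iloc[perm]
        )
        a = tmm_factors(cm, ref_sample="S0").factors
        b = tmm_factors(cm_perm, ref_sample="S0").factors
        assert np.allclose(a, b, atol=1e-12)

    def test_disjoint_support_errors(self):
        counts = np.array([[5, 0], [7, 0], [0, 3], [0, 9]])
        cm = make_matrix(counts)
        with pytest.raises(ValidationError, match="S1|S0"):
            tmm_factors(cm, ref_sample="S0")

    def test_trim_mask_bounds(self):
        vals = np.arange(10, dtype=float)
        keep = _trim_mask(vals, 0.3, 0.3)
        assert keep.sum() == 4
        assert keep[3] and keep[6]
        assert not keep[0] and not keep[9]


# --------------------------------------------------------------------------
# logCPM
# --------------------------------------------------------------------------

class TestLogExpression:
    def test_zero_count_value(self):
        cm = make_matrix([[0, 0], [999_999, 1_000_001]])
        nf = tmm_factors(cm)
        # force unit factors / 1e6 effective libsize scenario approximately
        logcpm = log_expression(cm, nf)
        expected = np.log2(
            0.5 / (nf.effective_libsize.iloc[0] + 1.0) * 1e6
        )
        assert logcpm.values.iloc[0, 0] == pytest.approx(expected, abs=1e-12)
        assert logcpm.values.iloc[0, 0] == pytest.approx(-1.0, abs=1e-2)

    def test_scale_invariance_under_doubling(self, rng):
        # doubling counts doubles effective libsizes; only the prior breaks
        # exact equality, with error ~ prior/(4 ln2 c), so use counts >> prior
        counts = rng.integers(500, 5000, size=(50, 3))
        cm1 = make_matrix(counts)
        cm2 = make_matrix(counts * 2)
        nf1 = tmm_factors(cm1, ref_sample="S0")
        nf2 = tmm_factors(cm2, ref_sample="S0")
        l1 = log_expression(cm1, nf1).values.to_numpy()
        l2 = log_expression(cm2, nf2).values.to_numpy()
        assert np.abs(l1 - l2).max() < 1e-3

    def test_matches_brute_force(self, rng):
        counts = rng.integers(0, 500, size=(30, 4))
        cm = make_matrix(counts)
        nf = tmm_factors(cm)
        logcpm = log_expression(cm, nf, prior=0.5).values.to_numpy()
        eff = nf.effective_libsize.to_numpy()
        for i in range(30):
            for j in range(4):
                expected = np.log2((counts[i, j] + 0.5) / (eff[j] + 1.0) * 1e6)
                assert logcpm[i, j] == pytest.approx(expected, rel=1e-12)


# --------------------------------------------------------------------------
# MDS
# --------------------------------------------------------------------------

class TestMds:
    def test_duplicated_samples_coincide(self, rng):
        counts = rng.integers(1, 300, size=(100, 3))
        counts = np.column_stack([counts, counts[:, 0]])  # S3 duplicates S0
        cm = make_matrix(counts)
        nf = tmm_factors(cm, ref_sample="S0")
        logcpm = log_expression(cm, nf)
        coords = mds_coordinates(logcpm, top_genes=50)
        assert np.allclose(coords.loc["S0"], coords.loc["S3"], atol=1e-8)

    def test_three_point_oracle(self):
        # place 3 samples on a line in expression space; with top_genes >=
        # n_genes the distance is the full RMS, i.e. Euclidean / sqrt(G)
        vals = np.array([[0.0, 1.0, 4.0], [0.0, 1.0, 4.0]])
        em = ExpressionMatrix(
            values=pd.DataFrame(vals, index=["G0", "G1"], columns=["A", "B", "C"]),
            scale="logCPM",
        )
        coords = mds_coordinates(em, top_genes=2, dims=2)
        d = lambda s, t: np.linalg.norm(coords.loc[s] - coords.loc[t])
        assert d("A", "B") == pytest.approx(1.0, abs=1e-8)
        assert d("B", "C") == pytest.approx(3.0, abs=1e-8)
        assert d("A", "C") == pytest.approx(4.0, abs=1e-8)

    def test_embedding_reproduces_distances_full_rank(self, rng):
        vals = rng.normal(size=(40, 6))
        em = ExpressionMatrix(
            values=pd.DataFrame(
                vals, index=[f"G{i}" for i in range(40)],
                columns=[f"S{j}" for j in range(6)],
            ),
            scale="logCPM",
        )
        coords = mds_coordinates(em, top_genes=40, dims=5)
        for s in range(6):
            for t in range(s + 1, 6):
                target = np.sqrt(np.mean((vals[:, s] - vals[:, t]) ** 2))
                got = np.linalg.norm(coords.iloc[s] - coords.iloc[t])
                assert got == pytest.approx(target, abs=1e-6)

    def test_dims_bound(self, rng):
        vals = rng.normal(size=(10, 4))
        em = ExpressionMatrix(
            values=pd.DataFrame(
                vals, index=[f"G{i}" for i in range(10)],
                columns=[f"S{j}" for j in range(4)],
            ),
            scale="logCPM",
        )
        with pytest.raises(ValidationError, match="dims"):
            mds_coordinates(em, dims=4)

    def test_genotype_separation_on_dim1(self, small_config):
        ok = 0
        for seed in range(10):
            cohort = simulate_cohort(small_config.with_(seed=seed))
            rpkm = compute_rpkm(cohort.counts)
            kept, _ = filter_genes(rpkm)
            nf = tmm_factors(cohort.counts, kept_genes=kept)
            logcpm = log_expression(cohort.counts, nf, kept_genes=kept)
            coords = mds_coordinates(logcpm)
            sdf = cohort.samples_frame()
            wt = coords.loc[sdf.loc[sdf["genotype"] == WT, "sample_id"], "dim1"]
            ad = coords.loc[sdf.loc[sdf["genotype"] == AD, "sample_id"], "dim1"]
            # perfect 1-D separation == zero 2-means misassignments
            if wt.max() < ad.min() or ad.max() < wt.min():
                ok += 1
        assert ok >= 9
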