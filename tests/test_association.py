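"""Genotype QC, structure, kinship, the mixed-model scan and FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

from grainspec import association as A
from grainspec.errors import AlignmentError, DimensionError, EmptyPanelError
from grainspec.synthetic import SimConfig, simulate_genotypes


def make_geno(matrix, chrom=None, pos=None):
    matrix = np.asarray(matrix, dtype=np.int8)
    n, m = matrix.shape
    chrom = np.array(["chr1"] * m) if chrom is None else np.asarray(chrom)
    pos = np.arange(1, m + 1) * 1000 if pos is None else np.asarray(pos)
    ids = np.array([f"snp{j}" for j in range(m)])
    return A.GenotypeData(matrix, chrom, pos, ids, [f"S{i}" for i in range(n)])


class TestFilter:
    def test_missing_rate_threshold(self):
        mat = np.ones((4, 2), dtype=np.int8)
        mat[0, 0] = 0  # keep marker 0 polymorphic
        mat[:1, 1] = A.MISSING  # 25% missing
        mat[0, 1] = A.MISSING
        mat[1, 1] = 0
        geno = make_geno(mat)
        kept, report = A.filter_genotypes(geno, max_missing=0.20, min_maf=0.0)
        assert kept.n_markers == 1
        assert report["dropped_missing"] == 1

    def test_monomorphic_dropped(self):
        mat = np.array([[2, 0], [2, 1], [2, 2], [2, 1]], dtype=np.int8)
        kept, report = A.filter_genotypes(make_geno(mat), min_maf=0.05)
        assert kept.n_markers == 1
        assert report["dropped_maf"] == 1

    def test_ten_marker_toy_counts(self):
        """Hand-built panel: 2 markers over the missing cap, 1 under the MAF
        floor; the other 7 survive."""
        rng = np.random.default_rng(0)
        n = 20
        mat = rng.integers(0, 3, size=(n, 10)).astype(np.int8)
        mat[:, 0] = np.array([0, 1] * 10)  # safely polymorphic columns
        mat[: int(0.25 * n), 3] = A.MISSING  # 25% missing
        mat[: int(0.30 * n), 7] = A.MISSING  # 30% missing
        mat[:, 5] = 2
        mat[0, 5] = 1  # MAF 1/40 < 0.05
        kept, report = A.filter_genotypes(make_geno(mat))
        assert kept.n_markers == 7
        assert report["dropped_missing"] == 2
        assert report["dropped_maf"] == 1

    def test_all_dropped_errors(self):
        mat = np.full((4, 3), 2, dtype=np.int8)
        with pytest.raises(EmptyPanelError):
            A.filter_genotypes(make_geno(mat))


class TestStructure:
    def test_pc1_separates_diverged_subpops(self):
        cfg = SimConfig(n_samples=100, n_subpops=2, subpop_names=("A", "B"),
                        n_snps=2000, fst=0.2, seed=1)
        geno, truth = simulate_genotypes(cfg)
        pcs = A.structure_covariates(geno, 3)
        binary = (truth.subpop == "A").astype(float)
        r = np.corrcoef(pcs[:, 0], binary)[0, 1]
        assert abs(r) >= 0.9

    def test_duplicate_samples_identical_rows(self):
        rng = np.random.default_rng(2)
        mat = rng.integers(0, 3, size=(10, 50)).astype(np.int8)
        mat[1] = mat[0]
        pcs = A.structure_covariates(make_geno(mat), 2)
        np.testing.assert_allclose(pcs[0], pcs[1], atol=1e-10)

    def test_zero_pcs_and_dimension_error(self):
        mat = np.random.default_rng(3).integers(0, 3, size=(6, 20)).astype(np.int8)
        assert A.structure_covariates(make_geno(mat), 0).shape == (6, 0)
        with pytest.raises(DimensionError):
            A.structure_covariates(make_geno(mat), 6)


class TestKinship:
    def test_symmetry_exact(self):
        mat = np.random.default_rng(4).integers(0, 3, size=(15, 200)).astype(np.int8)
        k = A.kinship(make_geno(mat)).values
        np.testing.assert_array_equal(k, k.T)

    def test_duplicated_sample_like_self(self):
        mat = np.random.default_rng(5).integers(0, 3, size=(12, 500)).astype(np.int8)
        mat[1] = mat[0]
        k = A.kinship(make_geno(mat)).values
        assert k[0, 1] == pytest.approx(k[0, 0], rel=1e-10)

    def test_unrelated_offdiagonals_vanish(self):
        """Independent equal-frequency markers, m=20,000: mean off-diagonal
        relatedness is ~0."""
        rng = np.random.default_rng(6)
        n = 100  # sample-centering biases off-diagonals by -1/(n-1)
        mat = rng.binomial(2, 0.5, size=(n, 20000)).astype(np.int8)
        k = A.kinship(make_geno(mat, pos=np.arange(1, 20001))).values
        off = k[~np.eye(n, dtype=bool)]
        assert abs(off.mean()) < 0.02


def brute_force_gls_scan(y, x_marker, covariates, kmat):
    """Independent oracle: dense-matrix REML over delta for one marker.

    Uses explicit V = K + delta I inverses (no eigendecomposition), a coarse
    log-grid followed by bounded scalar minimization, and a Wald t-test.
    """
    n = y.size
    x = np.column_stack([np.ones(n), covariates, x_marker])
    q = x.shape[1]

    def crit(delta):
        v = kmat + delta * np.eye(n)
        vi = np.linalg.inv(v)
        a = x.T @ vi @ x
        beta = np.linalg.solve(a, x.T @ vi @ y)
        r = y - x @ beta
        ypy = float(r @ vi @ r)
        return (
            (n - q) * np.log(ypy)
            + np.linalg.slogdet(v)[1]
            + np.linalg.slogdet(a)[1]
        )

    grid = np.logspace(-5, 5, 61)
    vals = [crit(d) for d in grid]
    i = int(np.argmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, 60)]
    res = minimize_scalar(lambda ld: crit(10**ld), bounds=(np.log10(lo), np.log10(hi)),
                          method="bounded", options={"xatol": 1e-4})
    delta = 10**res.x
    v = kmat + delta * np.eye(n)
    vi = np.linalg.inv(v)
    a = x.T @ vi @ x
    beta = np.linalg.solve(a, x.T @ vi @ y)
    r = y - x @ beta
    sg2 = float(r @ vi @ r) / (n - q)
    se = np.sqrt(sg2 * np.linalg.inv(a)[-1, -1])
    t = beta[-1] / se
    return float(beta[-1]), float(2 * stats.t.sf(abs(t), n - q))


class TestMLMScan:
    def test_identity_kinship_reduces_to_ols(self):
        """With K = I the Wald p equals the per-marker OLS F-test p."""
        rng = np.random.default_rng(7)
        n, m = 40, 25
        mat = rng.integers(0, 3, size=(n, m)).astype(np.int8)
        y = rng.normal(size=n)
        res = A.mlm_scan(y, make_geno(mat), None, A.KinshipMatrix(np.eye(n)))
        for j in range(m):
            x = np.column_stack([np.ones(n), mat[:, j]])
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            r = y - x @ beta
            se = np.sqrt((r @ r / (n - 2)) * np.linalg.inv(x.T @ x)[1, 1])
            p_ols = 2 * stats.t.sf(abs(beta[1] / se), n - 2)
            assert res.table.loc[j, "p"] == pytest.approx(p_ols, abs=1e-8)

    def test_toy_matches_brute_force_gls(self):
        """6-sample, 2-marker toy agrees with the dense GLS lambda-grid oracle."""
        rng = np.random.default_rng(8)
        mat = np.array([[0, 2], [1, 0], [2, 1], [0, 0], [1, 2], [2, 1]], dtype=np.int8)
        z = rng.normal(size=(6, 4))
        kmat = z @ z.T / 4
        kmat = kmat + np.eye(6) * 0.1  # keep it PD for the dense inverses
        y = np.array([1.0, -0.5, 2.0, 0.3, -1.2, 1.8])
        res = A.mlm_scan(y, make_geno(mat), None, A.KinshipMatrix(kmat))
        for j in range(2):
            beta, p = brute_force_gls_scan(y, mat[:, j].astype(float), np.empty((6, 0)), kmat)
            assert res.table.loc[j, "beta"] == pytest.approx(beta, abs=1e-6)
            assert res.table.loc[j, "p"] == pytest.approx(p, abs=1e-6)

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(9)
        n, m = 30, 10
        mat = rng.integers(0, 3, size=(n, m)).astype(np.int8)
        z = rng.normal(size=(n, 50))
        kmat = z @ z.T / 50
        y = rng.normal(size=n)
        cov = rng.normal(size=(n, 2))
        res1 = A.mlm_scan(y, make_geno(mat), cov, A.KinshipMatrix(kmat))
        perm = rng.permutation(n)
        gp = make_geno(mat[perm])
        res2 = A.mlm_scan(y[perm], gp, cov[perm],
                          A.KinshipMatrix(kmat[np.ix_(perm, perm)]))
        np.testing.assert_allclose(
            res1.table["p"], res2.table["p"], rtol=1e-6
        )

    def test_series_alignment(self):
        rng = np.random.default_rng(10)
        mat = rng.integers(0, 3, size=(8, 5)).astype(np.int8)
        geno = make_geno(mat)
        y = pd.Series(rng.normal(size=8), index=geno.sample_ids[::-1])
        res = A.mlm_scan(y, geno, None, A.KinshipMatrix(np.eye(8)))
        assert np.isfinite(res.table["p"]).all()
        with pytest.raises(AlignmentError):
            A.mlm_scan(y.iloc[:4], geno, None, A.KinshipMatrix(np.eye(8)))


class TestFDR:
    def test_all_ones(self):
        q = A.storey_qvalues(np.ones(10), pi0=1.0)
        np.testing.assert_array_equal(q, 1.0)

    def test_bh_closed_form(self):
        """p = [.01,.02,.03,.04] with pi0=1: every q is 0.04 (step-up)."""
        q = A.storey_qvalues(np.array([0.01, 0.02, 0.03, 0.04]), pi0=1.0)
        np.testing.assert_allclose(q, 0.04)

    def test_monotone_on_uniform(self):
        p = np.random.default_rng(11).uniform(size=10000)
        q = A.storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_cutoff_flag(self):
        table = pd.DataFrame({
            "chrom": ["chr1"] * 3, "pos": [1, 2, 3], "id": list("abc"),
            "beta": [0.0] * 3, "se": [1.0] * 3,
            "p": [1e-8, 1e-6, 1e-3], "r2": [0.1] * 3,
        })
        res = A.fdr_threshold(A.AssociationResult(table), p_cutoff=1e-6)
        assert res.table["significant"].tolist() == [True, True, False]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            A.storey_qvalues(np.array([0.0, 0.5]))


class TestManhattanQQ:
    def test_lambda_gc_near_one_under_null(self):
        p = np.random.default_rng(12).uniform(size=10000)
        table = pd.DataFrame({
            "chrom": ["chr1"] * 10000, "pos": np.arange(1, 10001),
            "id": [f"s{i}" for i in range(10000)],
            "beta": 0.0, "se": 1.0, "p": p, "r2": 0.0,
        })
        out = A.manhattan_qq_data(A.AssociationResult(table))
        assert out["lambda_gc"] == pytest.approx(1.0, abs=0.05)

    def test_chromosome_offsets_cumulative(self):
        table = pd.DataFrame({
            "chrom": ["chr1", "chr1", "chr2"], "pos": [100, 500, 50],
            "id": list("abc"), "beta": 0.0, "se": 1.0,
            "p": [0.5, 0.5, 0.5], "r2": 0.0,
        })
        out = A.manhattan_qq_data(A.AssociationResult(table))
        assert out["chrom_offsets"]["chr2"] == 500
        assert out["manhattan"]["cum_pos"].tolist() == [100, 500, 550]

    def test_single_marker_qq_median(self):
        table = pd.DataFrame({
            "chrom": ["chr1"], "pos": [1], "id": ["a"],
            "beta": [0.0], "se": [1.0], "p": [0.3], "r2": [0.0],
        })
        out = A.manhattan_qq_data(A.AssociationResult(table))
        assert out["qq"]["expected_neglog10p"].iloc[0] == pytest.approx(-np.log10(0.5))


class TestVCFRoundtrip:
    def test_write_read(self, tmp_path, small_study):
        _, geno, _, _ = small_study
        path = tmp_path / "g.vcf"
        A.write_vcf(geno, path)
        back = A.read_vcf(path)
        assert back.sample_ids == geno.sample_ids
        np.testing.assert_array_equal(back.matrix, geno.matrix)
        np.testing.assert_array_equal(back.pos, geno.pos)
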