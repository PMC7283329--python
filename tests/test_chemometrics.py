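"""PLS-DA, VIP, LDA, wavelength grouping and trait regression."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster
from sklearn.metrics import adjusted_rand_score

from grainspec import chemometrics as chem
from grainspec.errors import DegenerateModelError, SelectionError
from grainspec.imaging import SpectraTable
from grainspec.synthetic import SimConfig, designed_spectrum


def table(x):
    x = np.asarray(x, dtype=float)
    wl = 400.0 + 4.0 * np.arange(x.shape[1])
    return SpectraTable([f"s{i}" for i in range(x.shape[0])], x, wl)


def synthetic_chalk_spectra(n=60, seed=0, noise=0.01, tiers=None):
    """Designed spectra for n samples with varying chalk (no image needed)."""
    cfg = SimConfig(n_samples=n, n_snps=200, seed=seed)
    rng = np.random.default_rng(seed)
    chalk = (
        rng.uniform(0, 60, n)
        if tiers is None
        else np.repeat(tiers, int(np.ceil(n / len(tiers))))[:n] + rng.normal(0, 1.5, n)
    )
    rows = np.vstack(
        [
            designed_spectrum(cfg, "white", float(c), "AR09", "TEJ")
            for c in chalk
        ]
    )
    rows += rng.normal(0, noise, rows.shape)
    return table(rows), np.clip(chalk, 0, 100), cfg


class TestPLS:
    def test_full_components_equal_least_squares(self):
        """With as many components as the rank, PLS beta is the OLS solution
        (10x4 single-response oracle)."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        model = chem.fit_pls(x, y, n_components=4)
        xs = (x - x.mean(0)) / x.std(0, ddof=1)
        yc = y - y.mean()
        ols, *_ = np.linalg.lstsq(xs, yc, rcond=None)
        np.testing.assert_allclose(model.beta[:, 0], ols, atol=1e-8)

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(30, 12))
        y = rng.normal(size=(30, 3))
        model = chem.fit_pls(x, y, n_components=5)
        gram = model.scores.T @ model.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.diag(gram).max()

    def test_invariant_to_per_band_affine_rescaling(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(25, 8))
        y = rng.normal(size=25)
        a = rng.uniform(0.5, 3.0, 8)
        b = rng.normal(size=8)
        m1 = chem.fit_pls(x, y, 3)
        m2 = chem.fit_pls(x * a + b, y, 3)
        np.testing.assert_allclose(m1.scores, m2.scores, atol=1e-8)
        np.testing.assert_allclose(
            m1.predict(x), m2.predict(x * a + b), atol=1e-8
        )


class TestPLSDA:
    def test_separable_classes_perfect_holdback(self):
        x = np.full((40, 10), 0.5)
        labels = np.array(["a"] * 20 + ["b"] * 20)
        x[20:, 3] = 0.9  # one discriminating band, no noise
        res = chem.fit_plsda(table(x), chem.ClassCoding.from_labels(labels),
                             n_components=1, seed=0)
        assert res.holdback_accuracy == 1.0
        assert res.train_accuracy == 1.0

    def test_permutation_null_accuracy_near_majority(self):
        """With labels shuffled, holdback accuracy hovers at the majority-class
        rate (permutation null, 100 reps)."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=(60, 15))
        labels = np.array(["a"] * 30 + ["b"] * 20 + ["c"] * 10)
        accs = []
        for rep in range(100):
            perm = rng.permutation(labels)
            res = chem.fit_plsda(
                table(x), chem.ClassCoding.from_labels(perm),
                n_components=2, seed=rep,
            )
            accs.append(res.holdback_accuracy)
        majority = 30 / 60
        assert abs(np.mean(accs) - majority) < 0.15

    def test_small_class_rejected(self):
        x = np.random.default_rng(1).normal(size=(5, 6))
        labels = np.array(["a", "a", "a", "a", "b"])
        with pytest.raises(Exception):
            chem.fit_plsda(table(x), chem.ClassCoding.from_labels(labels),
                           n_components=1, seed=0)


class TestVIP:
    def test_mean_square_identity(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            x = rng.normal(size=(25, 9))
            y = rng.normal(size=(25, 2))
            model = chem.fit_pls(x, y, rng.integers(1, 6))
            scores = chem.vip(model).scores
            assert np.mean(scores**2) == pytest.approx(1.0, abs=1e-8)
            assert np.all(scores >= 0)

    def test_symmetric_bands_both_one(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=40)
        x = np.column_stack([z, z])
        model = chem.fit_pls(x, z, 1)
        np.testing.assert_allclose(chem.vip(model).scores, 1.0, atol=1e-10)

    def test_single_informative_band_approaches_sqrt_p(self):
        rng = np.random.default_rng(6)
        p = 20
        x = rng.normal(size=(300, p))
        y = x[:, 0] + rng.normal(0, 1e-4, 300)
        model = chem.fit_pls(x, y, 1)
        scores = chem.vip(model).scores
        assert scores[0] > 0.9 * np.sqrt(p)


class TestSelection:
    def test_threshold_zero_selects_all(self):
        rng = np.random.default_rng(7)
        t = table(rng.normal(size=(20, 8)))
        model = chem.fit_pls(t.spectra, rng.normal(size=20), 2)
        model.wavelengths = t.wavelengths
        assert chem.select_wavelengths(model, vip_threshold=0.0).size == 8

    def test_unreachable_threshold_errors(self):
        rng = np.random.default_rng(8)
        model = chem.fit_pls(rng.normal(size=(20, 8)), rng.normal(size=20), 2)
        with pytest.raises(SelectionError):
            chem.select_wavelengths(model, vip_threshold=10.0)

    def test_planted_bands_recovered_single_seed(self):
        """Five planted discriminative bands clear the 0.8 VIP threshold."""
        rng = np.random.default_rng(9)
        n, p = 120, 40
        planted = np.array([5, 12, 20, 28, 35])
        x = rng.normal(0, 1, size=(n, p))
        labels = np.array(["a"] * 60 + ["b"] * 60)
        x[60:, planted] += 3.0  # effect-to-noise 3
        t = table(x)
        res = chem.fit_plsda(t, chem.ClassCoding.from_labels(labels),
                             n_components=2, seed=0)
        selected = chem.select_wavelengths(res.model, vip_threshold=0.8)
        assert set(t.wavelengths[planted]).issubset(set(selected))


class TestLDA:
    def test_separated_classes_perfect(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(60, 4))
        x[30:] += 10.0
        labels = np.array(["a"] * 30 + ["b"] * 30)
        train = np.arange(0, 50)
        test = np.arange(50, 60)
        res = chem.fit_lda(table(x), labels, train, test)
        assert res.holdback_accuracy == 1.0

    def test_canonical_dimension_bound(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(60, 9))
        labels = np.repeat(["a", "b", "c"], 20)
        res = chem.fit_lda(table(x), labels, np.arange(50), np.arange(50, 60))
        assert res.axes.shape[1] <= 2

    def test_null_accuracy_near_chance(self):
        """Three identical class distributions: accuracy ~ 1/3 over 100 draws."""
        rng = np.random.default_rng(12)
        accs = []
        for _ in range(100):
            x = rng.normal(size=(60, 5))
            labels = rng.permutation(np.repeat(["a", "b", "c"], 20))
            perm = rng.permutation(60)
            res = chem.fit_lda(table(x), labels, perm[:48], perm[48:])
            accs.append(res.holdback_accuracy)
        assert abs(np.mean(accs) - 1 / 3) < 0.08

    def test_holdback_sample_at_class_mean_classified(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=(41, 3))
        labels = np.array(["a"] * 20 + ["b"] * 21)
        x[:20] += 2.0
        x[40] = x[20:40].mean(axis=0)  # holdback point at the b-class mean
        res = chem.fit_lda(table(x), labels, np.arange(40), np.array([40]))
        assert res.holdback_accuracy == 1.0


class TestGroups:
    def test_k1_single_group(self):
        t, _, _ = synthetic_chalk_spectra(n=20)
        g = chem.group_wavelengths(t, k=1)
        assert np.all(g.group_of_band == 0)
        assert g.ranges == [(float(t.wavelengths[0]), float(t.wavelengths[-1]))]

    def test_duplicate_band_profiles_same_group(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=(30, 10))
        x[:, 4] = x[:, 3]  # identical profiles
        g = chem.group_wavelengths(table(x), k=3, seed=0)
        assert g.group_of_band[3] == g.group_of_band[4]

    def test_groups_partition_contiguously(self):
        t, _, _ = synthetic_chalk_spectra(n=60, seed=1)
        g = chem.group_wavelengths(t, k=5, seed=0)
        assert np.all(np.diff(g.group_of_band) >= 0)
        assert set(g.group_of_band) == set(range(5))

    def test_chalk_band_group_recovered(self):
        """One recovered group overlaps the 690-920 nm chalk band (Jaccard)."""
        t, chalk, cfg = synthetic_chalk_spectra(n=80, seed=2)
        g = chem.group_wavelengths(t, k=5, seed=0)
        wl = t.wavelengths
        truth = set(np.flatnonzero((wl >= 690) & (wl <= 920)))
        best = max(
            len(truth & set(g.band_indices(j).tolist()))
            / len(truth | set(g.band_indices(j).tolist()))
            for j in range(5)
        )
        assert best >= 0.7


class TestSpectralTrait:
    def test_rank_one_group_variance_proportion_one(self):
        u = np.random.default_rng(15).normal(size=20)
        v = np.abs(np.random.default_rng(16).normal(size=6)) + 0.5
        t = table(np.outer(u, v))
        trait = chem.spectral_trait_pc1(t, np.arange(6))
        assert trait.variance_proportion == pytest.approx(1.0)
        assert abs(trait.scores.mean()) < 1e-10

    def test_sign_convention_uplift(self):
        rng = np.random.default_rng(17)
        x = rng.normal(0, 0.01, size=(30, 8)) + 0.5
        x[:15] += 0.3  # uplifted half must get the larger PC1 scores
        trait = chem.spectral_trait_pc1(table(x), np.arange(8))
        assert trait.scores[:15].mean() > trait.scores[15:].mean()

    def test_pc1_tracks_chalk(self):
        t, chalk, _ = synthetic_chalk_spectra(n=80, seed=3)
        wl = t.wavelengths
        idx = np.flatnonzero((wl >= 702) & (wl <= 922))
        trait = chem.spectral_trait_pc1(t, idx)
        assert abs(np.corrcoef(trait.scores, chalk)[0, 1]) >= 0.9


class TestRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        out = chem.regress_trait(2 * x, x)
        assert out["r2"] == pytest.approx(1.0)
        assert out["stars"] == "**"

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            chem.regress_trait(np.array([1.0, 2.0]), np.array([1.0, 2.0]))

    def test_constant_predictor(self):
        with pytest.raises(DegenerateModelError):
            chem.regress_trait(np.arange(5.0), np.ones(5))

    def test_null_type_one_rate(self):
        """Independent x, y: p uniform; rejections at 0.05 within [0.03, 0.07]."""
        rng = np.random.default_rng(18)
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            out = chem.regress_trait(rng.normal(size=30), rng.normal(size=30))
            hits += out["p"] < 0.05
        assert 0.03 <= hits / n_sim <= 0.07


class TestHeatmap:
    def test_identical_rows_merge_first_at_zero(self):
        rng = np.random.default_rng(19)
        x = rng.uniform(0.1, 0.9, size=(10, 4))
        x[:, 1] = x[:, 0]
        res = chem.cluster_heatmap(table(x), metric="euclidean", normalize01=False)
        assert res.linkage[0, 2] == 0.0
        assert {int(res.linkage[0, 0]), int(res.linkage[0, 1])} == {0, 1}

    def test_normalize01(self):
        from grainspec.chemometrics import _normalize01

        np.testing.assert_allclose(
            _normalize01(np.array([[2.0, 4.0, 8.0]]))[0], [0, 1 / 3, 1]
        )

    def test_chalk_tiers_cluster_contiguously(self):
        """Planted chalk tiers are recovered by sample clustering (ARI)."""
        aris = []
        for seed in range(20):
            t, chalk, _ = synthetic_chalk_spectra(
                n=60, seed=seed, tiers=np.array([5.0, 25.0, 50.0])
            )
            truth = np.repeat([0, 1, 2], 20)
            res = chem.cluster_heatmap(t, metric="euclidean", axis="samples")
            got = fcluster(res.linkage, t=3, criterion="maxclust")
            aris.append(adjusted_rand_score(truth, got))
        assert np.mean(np.array(aris) >= 0.8) >= 0.9

    def test_constant_row_pearson_rejected(self):
        x = np.ones((5, 4))
        with pytest.raises(DegenerateModelError):
            chem.cluster_heatmap(table(x), metric="pearson", normalize01=False)
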