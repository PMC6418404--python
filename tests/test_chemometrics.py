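"""Mean-spectrum construction, difference spectra, PCA and random forest."""

import numpy as np
import pytest
from sklearn.decomposition import PCA as SkPCA

from thermospec import (
    GroupProfile,
    Spectrum,
    SpectralImage,
    SyntheticConfig,
    WavenumberAxis,
    average_disjoint_groups,
    build_mean_spectrum_table,
    difference_spectra,
    fit_pca,
    fit_random_forest,
    generate_image,
    generate_study,
    group_mean_spectrum,
    intensity_at,
    pure_component_spectrum,
    rank_wavenumbers_by_gini,
)
from thermospec.chemometrics import GiniImportance

from conftest import noiseless_config


def _image_of(matrix, axis, sample_id="img", group="normothermia"):
    n = matrix.shape[0]
    spectra = [
        Spectrum(axis, matrix[i], {"row": 0, "col": i, "sample_id": sample_id,
                                   "group": group})
        for i in range(n)
    ]
    return SpectralImage(sample_id, group, 1, n, spectra)


@pytest.fixture()
def random_image(axis):
    rng = np.random.default_rng(20)
    return _image_of(rng.normal(size=(160, len(axis))), axis)


class TestAverageDisjointGroups:
    def test_160_pixels_yield_16_means(self, random_image):
        ms = average_disjoint_groups(random_image, k=10, seed=1)
        assert len(ms) == 16

    def test_k1_is_a_permutation_of_pixels(self, random_image):
        ms = average_disjoint_groups(random_image, k=1, seed=2)
        assert len(ms) == 160
        got = np.sort([s.meta["member_pixels"][0] for s in ms])
        np.testing.assert_array_equal(got, np.arange(160))
        for s in ms:
            np.testing.assert_array_equal(
                s.absorbance, random_image.spectra[s.meta["member_pixels"][0]].absorbance
            )

    def test_identical_pixels_average_to_themselves(self, axis):
        img = _image_of(np.tile(np.linspace(0, 1, len(axis)), (20, 1)), axis)
        ms = average_disjoint_groups(img, k=10, seed=3)
        for s in ms:
            np.testing.assert_allclose(s.absorbance, np.linspace(0, 1, len(axis)))

    def test_member_pixels_are_disjoint_and_exhaustive(self, random_image):
        ms = average_disjoint_groups(random_image, k=10, seed=4)
        members = [i for s in ms for i in s.meta["member_pixels"]]
        assert len(members) == len(set(members)) == 160

    def test_averaging_conservation(self, random_image):
        # mean of the k-group means == mean of the retained pixels
        ms = average_disjoint_groups(random_image, k=10, seed=5)
        mean_of_means = np.mean([s.absorbance for s in ms], axis=0)
        np.testing.assert_allclose(
            mean_of_means, random_image.to_matrix().mean(axis=0), atol=1e-12
        )

    def test_remainder_pixels_discarded(self, axis):
        rng = np.random.default_rng(21)
        img = _image_of(rng.normal(size=(23, len(axis))), axis)
        ms = average_disjoint_groups(img, k=10, seed=6)
        assert len(ms) == 2
        members = [i for s in ms for i in s.meta["member_pixels"]]
        assert len(members) == 20

    def test_errors(self, random_image):
        with pytest.raises(ValueError):
            average_disjoint_groups(random_image, k=0)
        with pytest.raises(ValueError):
            average_disjoint_groups(random_image, k=161)

    def test_deterministic(self, random_image):
        a = average_disjoint_groups(random_image, k=10, seed=9)
        b = average_disjoint_groups(random_image, k=10, seed=9)
        for sa, sb in zip(a, b):
            assert sa.meta["member_pixels"] == sb.meta["member_pixels"]


class TestMeanSpectrumTable:
    def test_counts_per_group(self, small_study):
        ms = build_mean_spectrum_table(small_study, k=10, seed=1)
        # 4x5 = 20 pixels -> 2 means per image; groups of 3/3/2 images
        assert ms.counts() == {
            "hypothermia": 6, "hyperthermia": 6, "normothermia": 4,
        }

    def test_same_seed_identical_partitions(self, small_study):
        a = build_mean_spectrum_table(small_study, k=5, seed=2)
        b = build_mean_spectrum_table(small_study, k=5, seed=2)
        for sa, sb in zip(a, b):
            assert sa.meta["member_pixels"] == sb.meta["member_pixels"]


class TestGroupMeanAndDifferences:
    def test_mean_of_one_is_itself(self, axis):
        s = Spectrum(axis, np.linspace(1, 2, len(axis)), {"group": "normothermia"})
        np.testing.assert_allclose(
            group_mean_spectrum([s]).absorbance, s.absorbance
        )

    def test_mirror_pair_cancels(self, axis):
        s = Spectrum(axis, np.random.default_rng(7).normal(size=len(axis)),
                     {"group": "normothermia"})
        neg = Spectrum(axis, -s.absorbance, {"group": "normothermia"})
        np.testing.assert_allclose(
            group_mean_spectrum([s, neg]).absorbance, 0.0, atol=1e-12
        )

    def test_identical_means_give_zero_differences(self, axis):
        s = Spectrum(axis, np.linspace(0, 1, len(axis)))
        diffs = difference_spectra({g: s for g in
                                    ("hypothermia", "hyperthermia", "normothermia")})
        assert set(diffs) == {
            "hypothermia-normothermia",
            "hyperthermia-normothermia",
            "hypothermia-hyperthermia",
        }
        for d in diffs.values():
            assert not np.any(d.absorbance)

    def test_antisymmetry_identity(self, axis):
        rng = np.random.default_rng(8)
        means = {
            g: Spectrum(axis, rng.normal(size=len(axis)))
            for g in ("hypothermia", "hyperthermia", "normothermia")
        }
        d = difference_spectra(means)
        np.testing.assert_allclose(
            d["hypothermia-hyperthermia"].absorbance,
            -(d["hyperthermia-normothermia"].absorbance
              - d["hypothermia-normothermia"].absorbance),
            atol=1e-12,
        )

    def test_missing_group_named_in_error(self, axis):
        s = Spectrum(axis, np.zeros(len(axis)))
        with pytest.raises(ValueError, match="hyperthermia"):
            difference_spectra({"hypothermia": s, "normothermia": s})

    def test_cold_group_difference_positive_at_ch2_bands(self):
        # noise-free regeneration: CH2 multipliers > 1 must surface as
        # positive hypothermia-normothermia differences at 2850/2920
        cfg = noiseless_config()
        means = {
            g: pure_component_spectrum(cfg.profiles[g].modulate(cfg.bands),
                                       cfg.axis())
            for g in ("hypothermia", "hyperthermia", "normothermia")
        }
        d = difference_spectra(means)["hypothermia-normothermia"]
        assert intensity_at(d, 2920.0) > 0
        assert intensity_at(d, 2850.0) > 0


class TestPCA:
    def test_identical_observations_no_variance(self):
        X = np.tile(np.linspace(0, 1, 30), (8, 1))
        res = fit_pca(X, n_components=2)
        np.testing.assert_allclose(res.scores, 0.0, atol=1e-10)
        np.testing.assert_allclose(res.explained_variance_ratio, 0.0)

    def test_two_observations_pc1_explains_all(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(2, 40))
        res = fit_pca(X, n_components=2)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(50, 200))
        res = fit_pca(X, n_components=50)
        recon = res.scores @ res.loadings + res.mean
        rms = np.sqrt(np.mean((recon - X) ** 2))
        assert rms < 1e-6

    def test_scores_centered_and_decorrelated(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(40, 60))
        res = fit_pca(X, n_components=5)
        np.testing.assert_allclose(res.scores.mean(axis=0), 0.0, atol=1e-8)
        cov = res.scores.T @ res.scores
        off = cov - np.diag(np.diag(cov))
        assert np.max(np.abs(off)) < 1e-8

    def test_loadings_orthonormal_and_sign_fixed(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(30, 80))
        res = fit_pca(X, n_components=4)
        np.testing.assert_allclose(
            res.loadings @ res.loadings.T, np.eye(4), atol=1e-8
        )
        for row in res.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_matches_sklearn_explained_variance(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(25, 50)) * np.linspace(1, 3, 50)
        res = fit_pca(X, n_components=3)
        sk = SkPCA(n_components=3).fit(X)
        np.testing.assert_allclose(
            res.explained_variance_ratio, sk.explained_variance_ratio_, atol=1e-8
        )

    def test_bad_component_counts_raise(self):
        X = np.random.default_rng(14).normal(size=(5, 8))
        with pytest.raises(ValueError):
            fit_pca(X, n_components=0)
        with pytest.raises(ValueError):
            fit_pca(X, n_components=6)


class TestRandomForest:
    def _null_data(self, p=50, seed=15):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(90, p))
        labels = np.array(["a"] * 36 + ["b"] * 36 + ["c"] * 18)
        return X, labels, np.linspace(1800, 900, p)

    def test_null_labels_flat_importance_and_chance_oob(self):
        X, labels, wn = self._null_data()
        imp = fit_random_forest(X, labels, wn, n_trees=500, seed=16)
        med = np.median(imp.importance)
        assert np.max(imp.importance) <= 3.0 * med
        majority = 36 / 90
        assert abs(imp.oob_accuracy - majority) <= 0.15

    def test_separating_feature_ranks_first(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(60, 30))
        labels = np.array(["a"] * 20 + ["b"] * 20 + ["c"] * 20)
        X[:, 7] = np.repeat([0.0, 5.0, 10.0], 20) + 0.01 * rng.normal(size=60)
        wn = np.linspace(1800, 900, 30)
        imp = fit_random_forest(X, labels, wn, n_trees=200, seed=18)
        assert rank_wavenumbers_by_gini(imp, 1)[0] == wn[7]

    def test_deterministic_given_seed(self):
        X, labels, wn = self._null_data(seed=19)
        a = fit_random_forest(X, labels, wn, n_trees=100, seed=20)
        b = fit_random_forest(X, labels, wn, n_trees=100, seed=20)
        np.testing.assert_array_equal(a.importance, b.importance)

    def test_single_class_rejected(self):
        X = np.zeros((10, 5))
        with pytest.raises(ValueError):
            fit_random_forest(X, ["a"] * 10, np.arange(5), n_trees=10, seed=0)


class TestRankWavenumbers:
    def test_argmax(self):
        imp = GiniImportance(np.array([1000.0, 1200.0, 1400.0, 1600.0]),
                             np.array([0.0, 0.0, 5.0, 0.0]), 10, 0, 1.0)
        assert rank_wavenumbers_by_gini(imp, 1)[0] == 1400.0

    def test_tie_break_prefers_small_wavenumbers(self):
        imp = GiniImportance(np.array([1600.0, 1000.0, 1400.0, 1200.0]),
                             np.full(4, 0.25), 10, 0, 1.0)
        np.testing.assert_array_equal(
            rank_wavenumbers_by_gini(imp, 3), [1000.0, 1200.0, 1400.0]
        )

    def test_clamp_with_warning(self):
        imp = GiniImportance(np.array([1000.0, 1200.0]),
                             np.array([0.6, 0.4]), 10, 0, 1.0)
        with pytest.warns(UserWarning, match="clamping"):
            top = rank_wavenumbers_by_gini(imp, 5)
        assert top.size == 2
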