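import numpy as np
import pytest

from lenspol import (
    LensModel,
    LensSet,
    OpinionWave,
    build_lens,
    build_lens_set,
    subjective_distance,
    weighted_group_covariance,
)

from conftest import _random_cov


def _wave_1d(values, weights=None, group="G"):
    values = np.asarray(values, dtype=float)
    return OpinionWave(
        wave_label="w",
        opinions=values[:, None],
        identities=[group] * len(values),
        weights=np.ones(len(values)) if weights is None else np.asarray(weights),
        item_names=["q"],
    )


class TestWeightedGroupCovariance:
    def test_unbiased_1d_two_points(self):
        # oracle: sum (x - xbar)^2 / (n - 1) = (0.25 + 0.25) / 1
        wave = _wave_1d([0.0, 1.0])
        cov = weighted_group_covariance(wave, "G", min_members=2)
        assert cov[0, 0] == pytest.approx(0.5, abs=1e-15)

    def test_identical_opinions_give_zero_matrix(self):
        wave = OpinionWave(
            "w", np.tile([0.3, 0.7], (5, 1)), ["G"] * 5, np.ones(5), ["a", "b"]
        )
        np.testing.assert_allclose(weighted_group_covariance(wave, "G"), 0.0, atol=1e-15)

    def test_weight_scale_invariance(self, rng):
        x = rng.uniform(size=(20, 3))
        w = rng.uniform(0.5, 2.0, size=20)
        wave1 = OpinionWave("w", x, ["G"] * 20, w, list("abc"))
        wave2 = OpinionWave("w", x, ["G"] * 20, 7.3 * w, list("abc"))
        np.testing.assert_allclose(
            weighted_group_covariance(wave1, "G"),
            weighted_group_covariance(wave2, "G"),
            rtol=1e-12,
        )

    def test_matches_numpy_unweighted(self, rng):
        x = rng.uniform(size=(15, 2))
        wave = OpinionWave("w", x, ["G"] * 15, np.ones(15), ["a", "b"])
        np.testing.assert_allclose(
            weighted_group_covariance(wave, "G"), np.cov(x.T), rtol=1e-12
        )

    def test_nonpartisan_uses_full_sample(self, tiny_wave):
        np.testing.assert_allclose(
            weighted_group_covariance(tiny_wave, "None"),
            np.cov(tiny_wave.opinions.T),
            rtol=1e-12,
        )

    def test_too_small_group_raises(self, tiny_wave):
        with pytest.raises(ValueError, match="'A' has 2"):
            weighted_group_covariance(tiny_wave, "A", min_members=3)
        with pytest.raises(ValueError, match="'missing' has 0"):
            weighted_group_covariance(tiny_wave, "missing")


class TestBuildLens:
    def test_identity_covariance_gives_euclidean_metric(self):
        lens = build_lens(np.eye(3), "G", ridge_epsilon=0.0)
        np.testing.assert_allclose(lens.metric, np.eye(3), atol=1e-14)
        np.testing.assert_allclose(lens.eigenvalues, 1.0)

    def test_diagonal_inversion(self):
        lens = build_lens(np.diag([0.25, 1.0]), "G", ridge_epsilon=0.0)
        np.testing.assert_allclose(lens.metric, np.diag([4.0, 1.0]), atol=1e-12)

    def test_metric_matches_closed_form_2x2_inverse(self):
        # independent oracle: adjugate / determinant
        cov = np.array([[1.0, 0.3], [0.3, 1.0]])
        det = 1.0 - 0.3 * 0.3
        expected = np.array([[1.0, -0.3], [-0.3, 1.0]]) / det
        lens = build_lens(cov, "G", ridge_epsilon=0.0)
        np.testing.assert_allclose(lens.metric, expected, rtol=1e-12)

    def test_basis_and_metric_invariant(self, rng):
        # metric @ (basis basis^T + reg I) == I, eigenvalues nonincreasing
        cov = _random_cov(rng, 4)
        lens = build_lens(cov, "G", ridge_epsilon=1e-6)
        lhs = lens.metric @ (
            lens.basis @ lens.basis.T + lens.regularization_applied * np.eye(4)
        )
        np.testing.assert_allclose(lhs, np.eye(4), atol=1e-8)
        assert np.all(np.diff(lens.eigenvalues) <= 1e-12)
        np.testing.assert_allclose(lens.metric, lens.metric.T, atol=1e-10)

    def test_singular_without_ridge_raises(self):
        with pytest.raises(ValueError, match="singular lens"):
            build_lens(np.zeros((2, 2)), "G", ridge_epsilon=0.0)

    def test_unanimous_group_with_ridge_is_finite(self):
        lens = build_lens(np.zeros((2, 2)), "G", ridge_epsilon=1e-6)
        d = subjective_distance([0.0, 0.0], [0.1, 0.0], lens)
        assert np.isfinite(d) and d > 50  # huge but finite

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            build_lens(np.array([[1.0, 0.2], [0.4, 1.0]]), "G")


class TestSubjectiveDistance:
    def test_euclidean_three_four_five(self):
        lens = build_lens(np.eye(2), "G", ridge_epsilon=0.0)
        assert subjective_distance([0, 0], [0.3, 0.4], lens) == pytest.approx(0.5)

    def test_1d_normalized_by_group_standard_deviation(self, rng):
        values = rng.uniform(size=30)
        wave = _wave_1d(values)
        cov = weighted_group_covariance(wave, "G")
        lens = build_lens(cov, "G", ridge_epsilon=0.0)
        sigma = np.std(values, ddof=1)
        assert subjective_distance([0.2], [0.6], lens) == pytest.approx(
            0.4 / sigma, rel=1e-10
        )

    def test_agrees_with_quadratic_form_oracle(self, rng):
        # brute force: invert the covariance directly, evaluate delta' S^-1 delta
        for _ in range(50):
            m = int(rng.integers(2, 6))
            cov = _random_cov(rng, m)
            lens = build_lens(cov, "G", ridge_epsilon=0.0)
            xi, xj = rng.uniform(size=m), rng.uniform(size=m)
            delta = xi - xj
            expected = delta @ np.linalg.inv(cov) @ delta
            assert subjective_distance(xi, xj, lens) ** 2 == pytest.approx(
                expected, rel=1e-8
            )

    def test_symmetric_in_arguments_and_zero_iff_equal(self, rng):
        lens = build_lens(_random_cov(rng, 3), "G", ridge_epsilon=0.0)
        x, y = rng.uniform(size=3), rng.uniform(size=3)
        assert subjective_distance(x, y, lens) == subjective_distance(y, x, lens)
        assert subjective_distance(x, x, lens) == 0.0

    def test_eigenvector_sign_and_order_independence(self, rng):
        # the metric depends only on the covariance, not the eigenbasis choice
        cov = _random_cov(rng, 3)
        evals, evecs = np.linalg.eigh(cov)
        flipped = evecs * np.array([-1, 1, -1])
        rebuilt = (flipped * evals) @ flipped.T
        l1 = build_lens(cov, "G", ridge_epsilon=0.0)
        l2 = build_lens(rebuilt, "G", ridge_epsilon=0.0)
        x, y = rng.uniform(size=3), rng.uniform(size=3)
        assert subjective_distance(x, y, l1) == pytest.approx(
            subjective_distance(x, y, l2), rel=1e-10
        )

    def test_affine_invariance(self, rng):
        # distances are invariant to any invertible linear map + shift of
        # the whole opinion space, once the lens is refitted
        x = rng.uniform(0.2, 0.8, size=(40, 2))
        a = np.array([[0.5, 0.1], [-0.2, 0.3]])
        b = np.array([0.1, 0.2])
        xt = x @ a.T + b
        m1 = LensModel(ridge_epsilon=0.0).fit(x)
        m2 = LensModel(ridge_epsilon=0.0).fit(xt)
        d1 = m1.pairwise_distance(x[:5], x[5:10])
        d2 = m2.pairwise_distance(xt[:5], xt[5:10])
        np.testing.assert_allclose(d1, d2, rtol=1e-6)

    def test_contraction_scales_distances_by_inverse_root_factor(self, rng):
        cov = _random_cov(rng, 3)
        x, y = rng.uniform(size=3), rng.uniform(size=3)
        base = subjective_distance(x, y, build_lens(cov, "G", ridge_epsilon=0.0))
        for c in (0.25, 0.5, 0.9):
            contracted = subjective_distance(
                x, y, build_lens(c * cov, "G", ridge_epsilon=0.0)
            )
            assert contracted == pytest.approx(base / np.sqrt(c), rel=1e-10)

    def test_asymmetry_across_lenses(self):
        narrow = build_lens(np.diag([0.01, 0.01]), "red", ridge_epsilon=0.0)
        wide = build_lens(np.diag([0.04, 0.04]), "blue", ridge_epsilon=0.0)
        r, b = np.array([0.3, 0.3]), np.array([0.7, 0.7])
        d_red = subjective_distance(r, b, narrow)
        d_blue = subjective_distance(r, b, wide)
        assert d_red == pytest.approx(2.0 * d_blue, rel=1e-12)

    def test_dimension_mismatch_raises(self):
        lens = build_lens(np.eye(2), "G")
        with pytest.raises(ValueError, match="dimension mismatch"):
            subjective_distance([0.1, 0.2, 0.3], [0.0, 0.0, 0.0], lens)


class TestLensModel:
    def test_transform_distances_equal_subjective_distance(self, rng):
        x = rng.uniform(size=(30, 2))
        model = LensModel(ridge_epsilon=0.0).fit(x)
        y = model.transform(x)
        d_direct = np.linalg.norm(y[0] - y[1])
        assert d_direct == pytest.approx(
            subjective_distance(x[0], x[1], model.lens_), rel=1e-12
        )

    def test_sklearn_params_round_trip(self):
        model = LensModel(ridge_epsilon=0.01, group_label="blue")
        params = model.get_params()
        assert params == {"ridge_epsilon": 0.01, "group_label": "blue"}
        model.set_params(ridge_epsilon=0.5)
        assert model.ridge_epsilon == 0.5


class TestLensSet:
    def test_one_lens_per_group_plus_population(self, two_lenses_waves):
        lens_set = build_lens_set(two_lenses_waves)
        assert set(lens_set.lenses) == {"red", "blue", "None"}

    def test_single_group_equals_population_lens(self, rng):
        x = rng.uniform(size=(20, 2))
        wave = OpinionWave("w", x, ["G"] * 20, np.ones(20), ["a", "b"])
        lens_set = build_lens_set(wave)
        np.testing.assert_allclose(
            lens_set.lenses["G"].metric, lens_set.lenses["None"].metric, rtol=1e-12
        )

    def test_small_group_falls_back_to_population_lens(self, rng):
        x = rng.uniform(size=(12, 2))
        ids = ["A"] * 10 + ["B"] * 2
        wave = OpinionWave("w", x, ids, np.ones(12), ["a", "b"])
        lens_set = build_lens_set(wave, min_group_size=3)
        assert lens_set.fallbacks == ["B"]
        np.testing.assert_allclose(
            lens_set.lenses["B"].metric, lens_set.lenses["None"].metric
        )

    def test_unknown_group_lookup_falls_back(self, two_lenses_waves):
        lens_set = build_lens_set(two_lenses_waves)
        lens = lens_set.lens_for("newcomers")
        np.testing.assert_array_equal(lens.metric, lens_set.lenses["None"].metric)

    def test_json_round_trip_lossless(self, two_lenses_waves, tmp_path):
        lens_set = build_lens_set(two_lenses_waves)
        path = tmp_path / "lenses.json"
        lens_set.to_json(path)
        loaded = LensSet.from_json(path)
        assert loaded == lens_set
        for g in lens_set.lenses:
            np.testing.assert_array_equal(
                loaded.lenses[g].basis, lens_set.lenses[g].basis
            )
            np.testing.assert_array_equal(
                loaded.lenses[g].eigenvalues, lens_set.lenses[g].eigenvalues
            )
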