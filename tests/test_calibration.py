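import numpy as np
import pytest

from technome.calibration import (
    apply_calibration,
    best_subset_aic,
    fit_naive_glm,
    fit_naive_rf,
    fit_ravel_like,
    fit_technome_stabilisation,
    mrmr_rank,
    stabilisation_performance,
)
from technome.qualification import QualifiedSurrogateSets
from technome.tables import RadiomeMatrix, SurrogateMatrix


def _mats(r, s):
    n = r.shape[0]
    ids = [f"p{i}" for i in range(n)]
    snames = [f"s{l:02d}" for l in range(s.shape[1])]
    return (
        RadiomeMatrix(r, ids, [f"f{j}" for j in range(r.shape[1])]),
        SurrogateMatrix(s, ids, snames, {x: "cr" for x in snames}),
    )


def _sets(per_feature, n_features):
    return QualifiedSurrogateSets(
        [np.asarray(per_feature, dtype=int) for _ in range(n_features)], 1.0, None
    )


class TestTechnomeStabilisation:
    def test_empty_sets_give_identity_calibration(self, tiny_cohort):
        sets = _sets([], 2)
        model = fit_technome_stabilisation(tiny_cohort.radiome, tiny_cohort.surrogates, sets)
        assert model.is_identity
        out = apply_calibration(model, tiny_cohort.radiome, tiny_cohort.surrogates)
        np.testing.assert_array_equal(out.values, tiny_cohort.radiome.values)

    def test_exact_linear_relation_recovered(self, tiny_cohort):
        # fa = 2*air_mean + 5 by construction
        sets = QualifiedSurrogateSets([np.array([0]), np.array([], dtype=int)], 1.0, None)
        model = fit_technome_stabilisation(tiny_cohort.radiome, tiny_cohort.surrogates, sets)
        fit = model.fits[0]
        assert fit.coef[0] == pytest.approx(2.0, abs=1e-10)
        s_mean = tiny_cohort.surrogates.values[:, 0].mean()
        assert fit.intercept == pytest.approx(5.0 + 2.0 * s_mean, abs=1e-10)
        out = apply_calibration(model, tiny_cohort.radiome, tiny_cohort.surrogates)
        assert out.values[:, 0].var() == pytest.approx(0.0, abs=1e-16)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(8)
        r = rng.normal(size=(50, 3))
        s = rng.normal(size=(50, 10))
        radiome, surrogates = _mats(r, s)
        model = fit_technome_stabilisation(radiome, surrogates, _sets(range(10), 3))
        delta = s - s.mean(axis=0)
        design = np.column_stack([np.ones(50), delta])
        beta = np.linalg.solve(design.T @ design, design.T @ r)
        for j in range(3):
            np.testing.assert_allclose(model.fits[j].coef, beta[1:, j], atol=1e-8)

    def test_calibration_uses_training_means_on_new_rows(self):
        rng = np.random.default_rng(9)
        t = rng.normal(size=40)
        r = (3 * t)[:, None]
        s = t[:, None]
        radiome, surrogates = _mats(r, s)
        model = fit_technome_stabilisation(radiome, surrogates, _sets([0], 1))
        # new rows from the same law but with a shifted surrogate mean
        t2 = rng.normal(size=30) + 5.0
        r2, s2 = _mats((3 * t2)[:, None], t2[:, None])
        out = apply_calibration(model, r2, s2)
        expected = r2.values - (
            model.fits[0].intercept
            + (s2.values - model.surrogate_means) @ model.fits[0].coef[:, None]
        )
        np.testing.assert_allclose(out.values, expected, atol=1e-12)
        assert out.values.var() == pytest.approx(0.0, abs=1e-16)

    def test_rank_guard_rejects_oversized_sets(self):
        rng = np.random.default_rng(10)
        radiome, surrogates = _mats(rng.normal(size=(5, 1)), rng.normal(size=(5, 6)))
        with pytest.raises(ValueError):
            fit_technome_stabilisation(radiome, surrogates, _sets(range(6), 1))

    def test_collinear_columns_dropped_with_warning(self):
        rng = np.random.default_rng(11)
        s_base = rng.normal(size=(30, 2))
        s = np.column_stack([s_base, s_base[:, 0]])  # duplicated column
        r = s_base @ np.array([[1.0], [2.0]])
        radiome, surrogates = _mats(r, s)
        with pytest.warns(UserWarning, match="collinear"):
            model = fit_technome_stabilisation(radiome, surrogates, _sets(range(3), 1))
        out = apply_calibration(model, radiome, surrogates)
        assert out.values.var() == pytest.approx(0.0, abs=1e-16)


class TestAffineEquivariance:
    def test_scaled_shifted_feature_transforms_identically(self):
        rng = np.random.default_rng(12)
        t = rng.normal(size=60)
        r = (2 * t + rng.normal(scale=0.1, size=60))[:, None]
        s = t[:, None]
        radiome, surrogates = _mats(r, s)
        model = fit_technome_stabilisation(radiome, surrogates, _sets([0], 1))
        out = apply_calibration(model, radiome, surrogates)

        radiome2, _ = _mats(3.0 * r + 7.0, s)
        model2 = fit_technome_stabilisation(radiome2, surrogates, _sets([0], 1))
        out2 = apply_calibration(model2, radiome2, surrogates)
        # the fitted intercept absorbs the shift; the residual-like
        # calibrated feature scales with the feature
        np.testing.assert_allclose(out2.values, 3.0 * out.values, atol=1e-9)
        assert stabilisation_performance(radiome2, out2) == pytest.approx(
            stabilisation_performance(radiome, out), abs=1e-9
        )


class TestRavelLike:
    def test_rank_one_design_keeps_one_component(self):
        rng = np.random.default_rng(13)
        u = rng.normal(size=40)
        s = np.outer(u, np.array([1.0, -2.0, 0.5]))
        r = (4 * u)[:, None]
        radiome, surrogates = _mats(r, s)
        model = fit_ravel_like(radiome, surrogates, var_explained=0.95)
        assert model.ravel.n_components == 1
        out = apply_calibration(model, radiome, surrogates)
        assert stabilisation_performance(radiome, out) == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_noise_needs_most_components(self):
        rng = np.random.default_rng(14)
        radiome, surrogates = _mats(rng.normal(size=(400, 1)), rng.normal(size=(400, 10)))
        model = fit_ravel_like(radiome, surrogates, var_explained=0.95)
        assert model.ravel.n_components >= 9

    def test_saturated_fit_equals_full_least_squares(self):
        rng = np.random.default_rng(15)
        s = rng.normal(size=(50, 6))
        r = s @ rng.normal(size=(6, 2)) + rng.normal(scale=0.2, size=(50, 2))
        radiome, surrogates = _mats(r, s)
        model = fit_ravel_like(radiome, surrogates, var_explained=1.0)
        out = apply_calibration(model, radiome, surrogates)
        delta = s - s.mean(axis=0)
        design = np.column_stack([np.ones(50), delta])
        beta, *_ = np.linalg.lstsq(design, r, rcond=None)
        np.testing.assert_allclose(out.values, r - design @ beta, atol=1e-8)

    def test_label_protection_keeps_biological_contrast(self):
        rng = np.random.default_rng(16)
        b = np.repeat([0, 1], 30)
        t = rng.normal(size=60)
        r = (2.0 * b + 3.0 * t + rng.normal(scale=0.05, size=60))[:, None]
        s = np.column_stack([t + 0.01 * rng.normal(size=60), rng.normal(size=60)])
        radiome, surrogates = _mats(r, s)
        from technome.tables import CohortLabels

        labels = CohortLabels(b, radiome.patient_ids)
        model = fit_ravel_like(radiome, surrogates, labels=labels)
        out = apply_calibration(model, radiome, surrogates)
        gap = out.values[b == 1, 0].mean() - out.values[b == 0, 0].mean()
        assert gap == pytest.approx(2.0, abs=0.15)


class TestNaiveGlm:
    def test_perfect_surrogate_selected_alone(self):
        rng = np.random.default_rng(17)
        t = rng.normal(size=80)
        s = np.column_stack([t, rng.normal(size=80), rng.normal(size=80)])
        r = (2 * t + 0.05 * rng.normal(size=80))[:, None]
        radiome, surrogates = _mats(r, s)
        model = fit_naive_glm(radiome, surrogates, k_max=3)
        chosen = list(model.fits[0].surrogate_idx)
        assert 0 in chosen
        # agreement with an independent exhaustive-AIC enumeration
        import itertools

        delta = s - s.mean(axis=0)

        def aic_of(cols):
            design = np.column_stack([np.ones(80), delta[:, cols]]) if cols else np.ones((80, 1))
            beta, *_ = np.linalg.lstsq(design, r[:, 0], rcond=None)
            rss = np.sum((r[:, 0] - design @ beta) ** 2)
            return 80 * np.log(rss / 80) + 2 * (design.shape[1] + 1)

        oracle = min(
            (aic_of(list(c)), sorted(c))
            for k in range(4)
            for c in itertools.combinations(range(3), k)
        )[1]
        assert chosen == oracle

    def test_redundant_duplicate_ranked_behind_complementary_column(self):
        rng = np.random.default_rng(18)
        t = rng.normal(size=200)
        u = rng.normal(size=200)
        y = t + 0.5 * u
        s = np.column_stack([t, t + 0.005 * rng.normal(size=200), u])
        order = mrmr_rank(s, y, k=3, names=["s0", "s1", "s2"])
        # the duplicate of the first pick is fully redundant (score ~ rel - 1)
        # and must fall behind the complementary covariate
        assert order == [0, 2, 1]

    def test_pure_noise_candidate_usually_rejected(self):
        # AIC admits a useless column only when its chi-square improvement
        # exceeds 2, i.e. in roughly 16% of draws
        rng = np.random.default_rng(19)
        intercept_only = 0
        for _ in range(100):
            y = rng.normal(size=200)
            X = rng.normal(size=(200, 1))
            subset = best_subset_aic(y, X, [0])
            intercept_only += len(subset) == 0
        assert intercept_only >= 75

    def test_best_subset_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(20)
        X = rng.normal(size=(60, 4))
        y = X[:, 1] * 2 + X[:, 3] - 1 + rng.normal(scale=0.3, size=60)
        import itertools

        def aic_of(cols):
            design = np.column_stack([np.ones(60), X[:, cols]]) if cols else np.ones((60, 1))
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            rss = np.sum((y - design @ beta) ** 2)
            return 60 * np.log(rss / 60) + 2 * (design.shape[1] + 1)

        best = min(
            (aic_of(list(c)), list(c))
            for k in range(5)
            for c in itertools.combinations(range(4), k)
        )[1]
        assert sorted(best_subset_aic(y, X, list(range(4)))) == sorted(best)


class TestNaiveRf:
    def test_constant_feature_left_unchanged(self):
        rng = np.random.default_rng(21)
        radiome, surrogates = _mats(np.full((30, 1), 3.0), rng.normal(size=(30, 3)))
        model = fit_naive_rf(radiome, surrogates, seed=0, n_estimators=50)
        out = apply_calibration(model, radiome, surrogates)
        np.testing.assert_allclose(out.values, radiome.values, atol=1e-8)

    def test_nonlinear_confounding_favors_forest(self):
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            t = rng.uniform(-2, 2, size=300)
            r = (t**2 + 0.05 * rng.normal(size=300))[:, None]
            s = t[:, None]
            radiome, surrogates = _mats(r[:200], s[:200])
            test_r, test_s = _mats(r[200:], s[200:])
            rf = fit_naive_rf(radiome, surrogates, seed=seed, n_estimators=100)
            glm = fit_naive_glm(radiome, surrogates)
            perf_rf = stabilisation_performance(test_r, apply_calibration(rf, test_r, test_s))
            perf_glm = stabilisation_performance(test_r, apply_calibration(glm, test_r, test_s))
            wins += perf_rf > perf_glm
        assert wins >= 4


class TestStabilisationPerformance:
    def test_variance_reduction_arithmetic(self):
        rng = np.random.default_rng(22)
        before = rng.normal(scale=2.0, size=400)
        after = before * np.sqrt(0.1)  # variance ratio exactly 0.1
        b, _ = _mats(before[:, None], before[:, None])
        a, _ = _mats(after[:, None], after[:, None])
        assert stabilisation_performance(b, a) == pytest.approx(0.9, abs=1e-12)

    def test_unchanged_features_score_zero(self, tiny_cohort):
        assert stabilisation_performance(tiny_cohort.radiome, tiny_cohort.radiome) == 0.0

    def test_added_variance_goes_negative(self):
        rng = np.random.default_rng(23)
        before = rng.normal(size=500)
        after = before * np.sqrt(2.0)  # variance doubled exactly
        b, _ = _mats(before[:, None], before[:, None])
        a, _ = _mats(after[:, None], after[:, None])
        assert stabilisation_performance(b, a) == pytest.approx(-1.0, abs=1e-12)

    def test_zero_variance_feature_skipped_with_warning(self):
        r = np.column_stack([np.full(5, 1.0), np.arange(5.0)])
        b, _ = _mats(r, r)
        with pytest.warns(UserWarning):
            perf = stabilisation_performance(b, b)
        assert perf == 0.0
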