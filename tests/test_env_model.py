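"""Lag/window features, grid AIC selection, BCa bootstrap, LMG importance."""

import itertools

import numpy as np
import pandas as pd
import pytest

from plantservation import env_model as em
from plantservation import synthetic_field as sf

TRUE_SPEC = em.EnvFeatureSpec(4, (3, 5, 2), (1, 0, 4))
RESTRICTED = em.enumerate_grid((1, 4, 7), range(1, 8), range(0, 6))


def one_genotype_params(beta_p=-0.004, beta_c=0.010, beta_r=0.003):
    return pd.DataFrame({"genotype": [0], "beta0": [0.02],
                         "beta_p": [beta_p], "beta_c": [beta_c],
                         "beta_r": [beta_r]})


def make_response(env, spec=TRUE_SPEC, noise=0.0, seed=0, **betas):
    truth = sf.generate_pigment_truth(env, one_genotype_params(**betas), spec)
    y = truth["anthocyanin"].to_numpy()
    if noise > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0, noise * y[spec.burn_in:].std(), y.size)
    return y


class TestFillGaps:
    def test_complete_table_unchanged(self, env300):
        out = em.fill_gaps(env300)
        assert np.allclose(out["temp_C"], env300["temp_C"])
        assert not out["temp_C_filled"].any()

    def test_single_interior_gap_interpolates(self):
        df = pd.DataFrame({"date": pd.date_range("2018-01-01", periods=3),
                           "temp_C": [10.0, np.nan, 12.0]})
        out = em.fill_gaps(df)
        assert out["temp_C"].iloc[1] == pytest.approx(11.0)
        assert out["temp_C_filled"].tolist() == [False, True, False]

    def test_random_gaps_flagged_and_bounded(self, env300):
        rng = np.random.default_rng(0)
        df = env300.copy()
        holes = rng.choice(np.arange(1, 299), 30, replace=False)
        df.loc[holes, "temp_C"] = np.nan
        out = em.fill_gaps(df)
        assert set(np.flatnonzero(out["temp_C_filled"])) == set(holes)
        # interpolation stays within the local envelope of a smooth-ish series
        assert out["temp_C"].between(env300.temp_C.min() - 1,
                                     env300.temp_C.max() + 1).all()

    def test_all_missing_column_rejected(self):
        df = pd.DataFrame({"date": pd.date_range("2018-01-01", periods=3),
                           "temp_C": [np.nan] * 3})
        with pytest.raises(ValueError):
            em.fill_gaps(df)


class TestColdness:
    def test_warm_day_zero(self):
        assert em.daily_coldness(np.array([10.0]), 4)[0] == 0

    def test_cold_day_degree_days(self):
        assert em.daily_coldness(np.array([1.0]), 4)[0] == 3

    def test_monotone_in_threshold(self):
        temps = np.linspace(-10, 20, 61)
        prev = em.daily_coldness(temps, 1)
        for thr in (4, 7, 10, 13):
            cur = em.daily_coldness(temps, thr)
            assert np.all(cur >= prev)
            prev = cur


class TestMovingTotal:
    def test_unit_window_zero_lag_identity(self):
        x = np.arange(5.0)
        assert np.array_equal(em.moving_total(x, 1, 0), x)

    def test_constant_series_scales_with_window(self):
        out = em.moving_total(np.full(10, 2.0), 4, 0)
        assert np.allclose(out[3:], 8.0)
        assert np.isnan(out[:3]).all()

    def test_matches_brute_force_sums(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        w, l = 3, 2
        got = em.moving_total(x, w, l)
        for d in range(40):
            lo, hi = d - l - w + 1, d - l
            if lo < 0:
                assert np.isnan(got[d])
            else:
                assert got[d] == pytest.approx(x[lo:hi + 1].sum())

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            em.moving_total(np.ones(5), 0, 0)
        with pytest.raises(ValueError):
            em.moving_total(np.ones(5), 2, -1)


class TestGrid:
    def test_single_spec_grid(self):
        g = em.enumerate_grid((4,), (1,), (0,))
        assert g.count == 1
        assert list(g) == [em.EnvFeatureSpec(4, (1, 1, 1), (0, 0, 0))]

    def test_published_grid_cardinality(self):
        assert em.enumerate_grid().count == 46_305_000

    def test_small_grid_matches_explicit_enumeration(self):
        g = em.enumerate_grid((1, 4), (1, 2), (0, 1))
        specs = list(g)
        assert g.count == len(specs) == 2 * 8 * 8
        assert len(set(specs)) == len(specs)
        brute = [em.EnvFeatureSpec(t, (wp, wc, wr), (lp, lc, lr))
                 for t, wp, wc, wr, lp, lc, lr in itertools.product(
                     (1, 4), (1, 2), (1, 2), (1, 2), (0, 1), (0, 1), (0, 1))]
        assert specs == brute

    def test_spec_at_agrees_with_iteration_order(self):
        g = em.enumerate_grid((1, 4), (1, 2, 3), (0, 1))
        for i, spec in enumerate(g):
            assert g.spec_at(i) == spec

    def test_empty_ranges_rejected(self):
        with pytest.raises(ValueError):
            em.enumerate_grid((), (1,), (0,))

    def test_burn_in_is_max_window_plus_max_lag(self):
        assert em.enumerate_grid().burn_in == 28


class TestFitOne:
    def test_noiseless_response_fits_perfectly(self, env300):
        y = make_response(env300)
        fit = em.fit_one(y, env300, TRUE_SPEC)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_features_standardized(self, env300):
        y = make_response(env300, noise=0.2)
        fit = em.fit_one(y, env300, TRUE_SPEC)
        assert np.abs(fit.X.mean(axis=0)).max() < 1e-10
        assert np.allclose(fit.X.std(axis=0), 1.0)

    def test_burn_in_rows_make_features_complete(self, env300):
        grid = RESTRICTED
        temp = env300["temp_C"].to_numpy()
        for spec in [grid.spec_at(0), grid.spec_at(grid.count - 1)]:
            cold = em.daily_coldness(temp, spec.t_thr)
            feat = em.moving_total(cold, spec.windows[1], spec.lags[1])
            assert np.all(np.isfinite(feat[grid.burn_in:]))

    def test_noise_only_response_has_low_r2(self, env300):
        r2s = []
        for s in range(50):
            rng = np.random.default_rng(s)
            y = rng.normal(size=len(env300))
            r2s.append(em.fit_one(y, env300, TRUE_SPEC).r2)
        assert np.mean(r2s) < 0.1

    def test_zero_variance_feature_rejected(self):
        env = sf.generate_env_series(0, 60)
        env["precip"] = 0.0
        y = np.random.default_rng(0).normal(size=60)
        with pytest.raises(ValueError):
            em.fit_one(y, env, TRUE_SPEC)


class TestGridSelect:
    def test_single_spec_grid_returns_it(self, env300):
        y = make_response(env300, noise=0.3)
        g = em.enumerate_grid((4,), (3,), (1,))
        fit = em.grid_select(y, env300, g)
        assert fit.spec == em.EnvFeatureSpec(4, (3, 3, 3), (1, 1, 1))

    def test_noiseless_truth_recovered_exactly(self, env300):
        y = make_response(env300)
        fit = em.grid_select(y, env300, RESTRICTED)
        assert fit.spec == TRUE_SPEC

    def test_matches_per_spec_fit_enumeration(self, env300):
        # Gram-table engine vs naive fit_one loop on a small grid
        y = make_response(env300, noise=0.5, seed=4)
        g = em.enumerate_grid((1, 7), (2, 4), (0, 3))
        fit = em.grid_select(y, env300, g)
        aics = {spec: em.fit_one(y, env300, spec, burn_in=g.burn_in).aic
                for spec in g}
        assert fit.spec == min(aics, key=aics.get)
        assert fit.aic == pytest.approx(min(aics.values()), rel=1e-9)

    def test_parameter_recovery_under_noise(self):
        wins = 0
        for s in range(20):
            env = sf.generate_env_series(1000 + s, 300)
            y = make_response(env, noise=0.10, seed=100 + s)
            wins += em.grid_select(y, env, RESTRICTED).spec == TRUE_SPEC
        assert wins >= 16

    def test_selection_invariant_to_affine_response(self, env300):
        y = make_response(env300, noise=0.4, seed=7)
        a = em.grid_select(y, env300, RESTRICTED).spec
        b = em.grid_select(3.5 * y + 11.0, env300, RESTRICTED).spec
        assert a == b


class TestBca:
    def test_strong_effect_always_significant(self, env300):
        for s in range(20):
            y = make_response(env300, noise=0.10, seed=s)
            fit = em.fit_one(y, env300, TRUE_SPEC)
            em.bca_significance(fit, n_boot=400, seed=s)
            assert fit.significant[1]  # coldness drives the response

    def test_symmetric_limit_matches_percentile(self):
        # z0 ≈ 0 and a ≈ 0: feed an exactly symmetric bootstrap sample
        rng = np.random.default_rng(0)
        half = rng.normal(0, 1, 2000)
        boot = np.concatenate([half, -half])  # symmetric about 0 = theta_hat
        jack = np.concatenate([half[:50], -half[:50]])
        lo, hi = em._bca_interval(boot, 0.0, jack, alpha=0.05)
        perc = np.quantile(boot, [0.025, 0.975])
        width = perc[1] - perc[0]
        assert abs(lo - perc[0]) < 0.05 * width
        assert abs(hi - perc[1]) < 0.05 * width

    def test_matches_scipy_bca_oracle(self, env300):
        # independent cross-check: scipy's BCa on the same slope statistic
        from scipy import stats as sps

        y = make_response(env300, noise=0.3, seed=1)
        fit = em.fit_one(y, env300, TRUE_SPEC)
        em.bca_significance(fit, n_boot=3000, seed=0)

        def slope_k(k):
            def stat(*cols_and_y):
                X = np.column_stack(cols_and_y[:3])
                yy = np.asarray(cols_and_y[3])
                sd = X.std(axis=0)
                Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1)
                beta, _, _ = em._ols_centered(Z, yy)
                return beta[k]
            return stat

        data = (fit.X_raw[:, 0], fit.X_raw[:, 1], fit.X_raw[:, 2], fit.y)
        for k in range(3):
            res = sps.bootstrap(data, slope_k(k), paired=True, vectorized=False,
                                n_resamples=3000, method="BCa",
                                random_state=np.random.default_rng(1))
            width = res.confidence_interval.high - res.confidence_interval.low
            assert abs(fit.ci[k][0] - res.confidence_interval.low) < 0.2 * width
            assert abs(fit.ci[k][1] - res.confidence_interval.high) < 0.2 * width

    def test_null_coefficient_coverage(self):
        # β_p = 0 truth: the 95% interval should cover 0 in ≈95% of replicates
        spec = TRUE_SPEC
        cover = 0
        n_rep = 200
        for s in range(n_rep):
            env = sf.generate_env_series(5000 + s, 150)
            y = make_response(env, spec, noise=0.3, seed=s, beta_p=0.0)
            fit = em.fit_one(y, env, spec)
            em.bca_significance(fit, n_boot=600, seed=s)
            cover += (fit.ci[0, 0] <= 0 <= fit.ci[0, 1])
        assert abs(cover / n_rep - 0.95) <= 0.04

    def test_degenerate_bootstrap_rejected(self, env300):
        # a flat response gives zero slopes in every replicate
        y = np.full(len(env300), 0.02)
        fit = em.fit_one(y, env300, TRUE_SPEC)
        with pytest.raises(em.DegenerateBootstrapError):
            em.bca_significance(fit, n_boot=100, seed=0)


class TestLmg:
    def _fit_from_design(self, X, y):
        Xs = (X - X.mean(0)) / X.std(0)
        beta, rss, r2 = em._ols_centered(Xs, y)
        return em.EnvModelFit(spec=TRUE_SPEC, coef=beta, intercept=y.mean(),
                              aic=0.0, r2=r2, n=len(y), X=Xs, y=y, X_raw=X)

    def test_orthogonal_predictors_get_marginal_r2(self):
        rng = np.random.default_rng(0)
        n = 4000
        raw = rng.normal(size=(n, 3))
        X, _ = np.linalg.qr(raw - raw.mean(axis=0))  # centered orthogonal
        y = 1.0 * X[:, 0] + 2.0 * X[:, 1] + 0.5 * X[:, 2] \
            + rng.normal(0, np.sqrt(1 / n), n)
        fit = self._fit_from_design(X, y)
        shares = em.lmg_importance(fit)
        marginal = []
        for k in range(3):
            _, _, r2 = em._ols_centered(fit.X[:, [k]], y)
            marginal.append(r2)
        assert np.allclose(shares, marginal, atol=1e-6)

    def test_single_relevant_predictor_takes_all(self):
        rng = np.random.default_rng(1)
        raw = rng.normal(size=(300, 3))
        X, _ = np.linalg.qr(raw - raw.mean(axis=0))  # centered orthogonal
        y = 2.0 * X[:, 1]
        fit = self._fit_from_design(X, y)
        shares = em.lmg_importance(fit)
        assert shares[1] == pytest.approx(fit.r2, abs=1e-9)
        assert shares[0] == pytest.approx(0, abs=1e-9)

    def test_matches_all_orderings_enumeration(self):
        rng = np.random.default_rng(2)
        Z = rng.normal(size=(200, 3))
        X = Z @ np.array([[1, 0.5, 0.2], [0, 1, 0.4], [0, 0, 1]])  # correlated
        y = X @ np.array([1.0, -0.7, 0.3]) + rng.normal(0, 0.5, 200)
        fit = self._fit_from_design(X, y)
        shares = em.lmg_importance(fit)

        def r2_of(cols):
            if not cols:
                return 0.0
            return em._ols_centered(fit.X[:, list(cols)], y)[2]

        brute = np.zeros(3)
        for perm in itertools.permutations(range(3)):
            seen = []
            for p in perm:
                before = r2_of(tuple(seen))
                seen.append(p)
                brute[p] += r2_of(tuple(seen)) - before
        brute /= 6
        assert np.allclose(shares, brute, atol=1e-12)
        assert shares.sum() == pytest.approx(fit.r2, abs=1e-10)

    def test_shares_sum_to_r2_on_field_like_fit(self, env300):
        y = make_response(env300, noise=0.2, seed=3)
        fit = em.fit_one(y, env300, TRUE_SPEC)
        shares = em.lmg_importance(fit)
        assert shares.sum() == pytest.approx(fit.r2, abs=1e-10)
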