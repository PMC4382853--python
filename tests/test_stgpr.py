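"""Three-stage estimator: OLS, spatial-temporal smoothing, GP regression."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from hypothesis import given, settings, strategies as st

from covbench import stgpr
from covbench import synthetic as syn

YEARS = list(range(1990, 2011))
INV = lambda z: 1 / (1 + np.exp(-z))


def truth_logit_obs(truth, geo):
    """All truth cells as noiseless logit observations."""
    df = truth.p.to_series().rename("p").reset_index()
    df["province"] = df["district"].map(geo.province_of)
    df["source"] = "truth"
    df["logit_estimate"] = np.log(df["p"] / (1 - df["p"]))
    df["logit_variance"] = 1e-6
    return df


@pytest.fixture(scope="module")
def noiseless(small_geo):
    scn = syn.zero_noise_scenario(syn.Scenario(indicators=(
        syn.IndicatorSpec("ebf", "routine", beta0=-1.8, trend=0.18,
                          ind_effect=0.5, routine_level=0.4),)))
    truth = syn.generate_truth(small_geo, (1990, 2010), scn, seed=9)
    prov = truth.province_ind.rename(columns={"value": "value"})
    return truth, truth_logit_obs(truth, small_geo), truth.covariates, prov


class TestStage1:
    def test_exact_recovery_from_noiseless_truth(self, small_geo, noiseless):
        truth, obs, cov, prov = noiseless
        fit = stgpr.fit_stage1(obs.assign(indicator="ebf"), cov, prov, small_geo)
        np.testing.assert_allclose(fit.beta.to_numpy(),
                                   truth.betas.loc["ebf"].to_numpy(), atol=1e-6)

    def test_agrees_with_normal_equations_oracle(self, small_geo, noiseless):
        truth, obs, cov, prov = noiseless
        fit = stgpr.fit_stage1(obs.assign(indicator="ebf"), cov, prov, small_geo)
        merged = obs.merge(cov, on=["district", "year"]).merge(
            prov[prov["indicator"] == "ebf"].rename(columns={"value": "ind"}),
            on=["province", "year"])
        X = np.column_stack([np.ones(len(merged)), merged["year"] - 2000,
                             *(merged[c] for c in syn.COVARIATE_ORDER),
                             merged["ind"]])
        y = merged["logit_estimate"].to_numpy()
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fit.beta.to_numpy(), oracle, atol=1e-8)

    def test_residuals_sum_to_zero(self, small_geo, noiseless):
        truth, obs, cov, prov = noiseless
        rng = np.random.default_rng(0)
        noisy = obs.assign(indicator="ebf")
        noisy["logit_estimate"] = noisy["logit_estimate"] + rng.normal(0, 0.3, len(noisy))
        fit = stgpr.fit_stage1(noisy, cov, prov, small_geo)
        assert abs(fit.residuals["resid"].sum()) < 1e-8

    def test_duplication_invariance(self, small_geo, noiseless):
        truth, obs, cov, prov = noiseless
        obs = obs.assign(indicator="ebf")
        fit1 = stgpr.fit_stage1(obs, cov, prov, small_geo)
        dup = pd.concat([obs, obs.assign(source="copy")], ignore_index=True)
        fit2 = stgpr.fit_stage1(dup, cov, prov, small_geo)
        np.testing.assert_allclose(fit1.beta, fit2.beta, atol=1e-10)

    def test_collinear_columns_dropped_with_report(self, small_geo, noiseless):
        truth, obs, cov, prov = noiseless
        cov = cov.copy()
        for c in syn.COVARIATE_ORDER:
            cov[c] = 0.5                      # constants, collinear with intercept
        prov = prov.copy()
        prov["value"] = 0.7
        obs = obs.assign(indicator="ebf")
        fit = stgpr.fit_stage1(obs, cov, prov, small_geo)
        assert fit.dropped_columns                # something was dropped
        assert np.isfinite(fit.beta).all()
        # fitted values still reproduce the regression on the kept columns
        assert np.isfinite(fit.fitted["pred_logit"]).all()

    def test_too_few_observations_rejected(self, small_geo, noiseless):
        truth, obs, cov, prov = noiseless
        with pytest.raises(ValueError, match="at least 10"):
            stgpr.fit_stage1(obs.assign(indicator="ebf").head(5), cov, prov,
                             small_geo)


class TestSTWeights:
    def test_same_cell_weight_is_one(self, small_geo):
        d = small_geo.district_ids[0]
        assert stgpr.st_weights((d, 2000), (d, 2000), small_geo) == 1.0

    def test_cross_province_weight_is_zero(self, small_geo):
        by_prov = {}
        for d, p in small_geo.districts:
            by_prov.setdefault(p, []).append(d)
        (p1, ds1), (p2, ds2) = list(by_prov.items())[:2]
        assert stgpr.st_weights((ds1[0], 2000), (ds2[0], 2000), small_geo) == 0.0

    def test_same_province_scaled_by_zeta(self, small_geo):
        by_prov = {}
        for d, p in small_geo.districts:
            by_prov.setdefault(p, []).append(d)
        ds = next(v for v in by_prov.values() if len(v) >= 2)
        cfg = stgpr.STConfig(zeta=0.5)
        w = stgpr.st_weights((ds[0], 2000), (ds[1], 2000), small_geo, cfg)
        assert w == pytest.approx(0.5)

    def test_support_boundary(self, small_geo):
        d = small_geo.district_ids[0]
        cfg = stgpr.STConfig(lambda_years=10)
        assert stgpr.st_weights((d, 2000), (d, 2011), small_geo, cfg) == 0.0
        assert stgpr.st_weights((d, 2000), (d, 2010), small_geo, cfg) > 0.0

    def test_tricube_hand_value(self, small_geo):
        d = small_geo.district_ids[0]
        cfg = stgpr.STConfig(lambda_years=10)
        expected = (1 - (5 / 11) ** 3) ** 3
        assert stgpr.st_weights((d, 2000), (d, 2005), small_geo, cfg) == \
            pytest.approx(expected, abs=1e-12)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            stgpr.STConfig(lambda_years=0)
        with pytest.raises(ValueError):
            stgpr.STConfig(zeta=1.5)


class TestSmoothResiduals:
    def _fit_with_residuals(self, geo, rows):
        res = pd.DataFrame(rows, columns=["district", "province", "year",
                                          "source", "logit_estimate",
                                          "logit_variance", "resid"])
        fitted = pd.DataFrame([(d, y, 0.0) for d in geo.district_ids
                               for y in YEARS],
                              columns=["district", "year", "pred_logit"])
        return stgpr.Stage1Fit("x", pd.Series(dtype=float), fitted, res)

    def test_constant_residual_field(self, small_geo):
        rows = [(d, small_geo.province_of[d], y, "s", 0.0, 0.1, 0.7)
                for d in small_geo.district_ids for y in (1995, 2005)]
        fit = self._fit_with_residuals(small_geo, rows)
        out = stgpr.smooth_residuals(fit, small_geo, YEARS)
        has_support = out["smoothed"].notna() & (out["smoothed"] != 0)
        np.testing.assert_allclose(out.loc[has_support, "smoothed"], 0.7)

    def test_single_residual_dominates_own_cell(self, small_geo):
        d0 = small_geo.district_ids[0]
        rows = [(d0, small_geo.province_of[d0], 2000, "s", 0.0, 0.1, 1.3)]
        fit = self._fit_with_residuals(small_geo, rows)
        out = stgpr.smooth_residuals(fit, small_geo, YEARS)
        at = out[(out["district"] == d0) & (out["year"] == 2000)]
        assert at["smoothed"].iloc[0] == pytest.approx(1.3)

    def test_two_residuals_weighted_mean(self, small_geo):
        d0 = small_geo.district_ids[0]
        rows = [(d0, small_geo.province_of[d0], 2000, "s", 0.0, 0.1, 1.0),
                (d0, small_geo.province_of[d0], 2005, "s", 0.0, 0.1, -1.0)]
        fit = self._fit_with_residuals(small_geo, rows)
        cfg = stgpr.STConfig(lambda_years=10)
        out = stgpr.smooth_residuals(fit, small_geo, YEARS, cfg)
        w0 = (1 - (2 / 11) ** 3) ** 3     # |2002-2000|
        w1 = (1 - (3 / 11) ** 3) ** 3     # |2002-2005|
        expected = (w0 * 1.0 + w1 * -1.0) / (w0 + w1)
        at = out[(out["district"] == d0) & (out["year"] == 2002)]
        assert at["smoothed"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_no_support_falls_back_to_stage1(self, small_geo):
        """A district in a province with no residuals keeps its stage-1
        prediction."""
        d0 = small_geo.district_ids[0]
        rows = [(d0, small_geo.province_of[d0], 2000, "s", 0.0, 0.1, 1.0)]
        fit = self._fit_with_residuals(small_geo, rows)
        out = stgpr.smooth_residuals(fit, small_geo, YEARS)
        other_prov = [d for d, p in small_geo.districts
                      if p != small_geo.province_of[d0]]
        sub = out[out["district"].isin(other_prov)]
        np.testing.assert_allclose(sub["mean_logit"], sub["pred_logit"])


class TestMaternCovariance:
    def test_zero_lag_is_variance(self):
        cfg = stgpr.GPRConfig(amplitude=1.3)
        assert stgpr.matern_cov(0.0, cfg) == pytest.approx(1.69)

    def test_exponential_special_case(self):
        cfg = stgpr.GPRConfig(amplitude=1.0, length_scale=1.0, nu=0.5)
        assert stgpr.matern_cov(1.0, cfg) == pytest.approx(np.exp(-1), abs=1e-12)

    def test_three_halves_closed_form(self):
        cfg = stgpr.GPRConfig(amplitude=2.0, length_scale=5.0, nu=1.5)
        s = np.sqrt(3) * 2.0 / 5.0
        assert stgpr.matern_cov(2.0, cfg) == pytest.approx(4 * (1 + s) * np.exp(-s))

    @pytest.mark.parametrize("nu", [0.5, 1.5, 2.5])
    def test_strictly_decreasing_in_lag(self, nu):
        cfg = stgpr.GPRConfig(amplitude=1.0, length_scale=8.0, nu=nu)
        grid = np.linspace(0, 30, 100)
        vals = stgpr.matern_cov(grid, cfg)
        assert (np.diff(vals) < 0).all()

    def test_unsupported_smoothness_rejected(self):
        with pytest.raises(ValueError, match="0.5, 1.5, 2.5"):
            stgpr.GPRConfig(nu=2.0)


def flat_mean(districts, value=0.0):
    return pd.DataFrame([(d, y, value) for d in districts for y in YEARS],
                        columns=["district", "year", "mean_logit"])


def obs_frame(rows):
    return pd.DataFrame(rows, columns=["district", "year", "logit_estimate",
                                       "logit_variance"])


class TestGPRPosterior:
    CFG = stgpr.GPRConfig(amplitude=1.0, length_scale=5.0, nu=1.5, n_draws=10)

    def test_no_observations_returns_prior(self):
        mean = flat_mean(["A"], 0.3)
        post = stgpr.gpr_posterior(mean, obs_frame([]), self.CFG, "A")
        np.testing.assert_allclose(post.mean, 0.3)
        np.testing.assert_allclose(np.diag(post.cov), 1.0)

    def test_near_zero_noise_interpolates(self):
        mean = flat_mean(["A"])
        obs = obs_frame([("A", 2000, 1.5, 1e-10)])
        post = stgpr.gpr_posterior(mean, obs, self.CFG, "A")
        i = YEARS.index(2000)
        assert post.mean[i] == pytest.approx(1.5, abs=1e-6)

    def test_matches_dense_solve_oracle(self):
        """Posterior mean and covariance against explicit matrix inversion."""
        mean = flat_mean(["A"], -0.2)
        obs = obs_frame([("A", 1995, 0.5, 0.04), ("A", 2002, 1.0, 0.09),
                         ("A", 2008, 0.2, 0.02)])
        cfg = stgpr.GPRConfig(amplitude=0.8, length_scale=6.0, nu=1.5,
                              n_draws=10, jitter=0.0)
        post = stgpr.gpr_posterior(mean, obs, cfg, "A")
        yrs = np.array(YEARS, dtype=float)
        oy = np.array([1995.0, 2002.0, 2008.0])
        K = stgpr.matern_cov(yrs[:, None] - yrs[None, :], cfg)
        Koo = stgpr.matern_cov(oy[:, None] - oy[None, :], cfg) \
            + np.diag([0.04, 0.09, 0.02])
        Ks = stgpr.matern_cov(yrs[:, None] - oy[None, :], cfg)
        inv = np.linalg.inv(Koo)
        m_exp = -0.2 + Ks @ inv @ (np.array([0.5, 1.0, 0.2]) + 0.2)
        C_exp = K - Ks @ inv @ Ks.T
        np.testing.assert_allclose(post.mean, m_exp, atol=1e-8)
        np.testing.assert_allclose(post.cov, C_exp, atol=1e-8)

    def test_smaller_noise_never_raises_posterior_variance(self):
        mean = flat_mean(["A"])
        rows = [("A", y, 0.3, 0.2) for y in (1994, 1999, 2004, 2009)]
        post1 = stgpr.gpr_posterior(mean, obs_frame(rows), self.CFG, "A")
        rows10 = [(d, y, v, var / 10) for d, y, v, var in rows]
        post2 = stgpr.gpr_posterior(mean, obs_frame(rows10), self.CFG, "A")
        idx = [YEARS.index(y) for y in (1994, 1999, 2004, 2009)]
        assert (np.diag(post2.cov)[idx] <= np.diag(post1.cov)[idx] + 1e-12).all()

    def test_observation_outside_frame_rejected(self):
        mean = flat_mean(["A"])
        obs = obs_frame([("A", 1985, 0.5, 0.1)])
        with pytest.raises(ValueError, match="outside the frame"):
            stgpr.gpr_posterior(mean, obs, self.CFG, "A")


class TestDraws:
    def _posterior(self, var=0.0):
        yrs = np.array(YEARS, dtype=float)
        return stgpr.GPPosterior("A", yrs, np.full(len(yrs), 0.4),
                                 var * np.eye(len(yrs)))

    def test_draw_count_respected(self):
        cfg = stgpr.GPRConfig(amplitude=1.0, n_draws=1000)
        cube = stgpr.draw_estimates([self._posterior(0.01)], cfg)
        assert cube.sizes["draw"] == 1000

    def test_degenerate_posterior_gives_constant_draws(self):
        cfg = stgpr.GPRConfig(amplitude=1.0, n_draws=50, jitter=1e-12,
                              max_jitter=1e-12)
        cube = stgpr.draw_estimates([self._posterior(0.0)], cfg)
        np.testing.assert_allclose(cube.values, INV(0.4), atol=1e-4)

    def test_draw_mean_matches_posterior_mean(self):
        """Empirical mean of 1,000 logit draws within 4 standard errors of
        the analytic posterior mean, for every cell."""
        cfg = stgpr.GPRConfig(amplitude=1.0, n_draws=1000, seed=5)
        post = self._posterior(0.25)
        cube = stgpr.draw_estimates([post], cfg)
        logits = np.log(cube.values / (1 - cube.values))
        emp = logits.mean(axis=-1)[0]
        se = 0.5 / np.sqrt(1000)
        assert (np.abs(emp - 0.4) < 4 * se + 1e-9).all()

    def test_values_strictly_inside_unit_interval(self):
        cfg = stgpr.GPRConfig(amplitude=1.0, n_draws=200, seed=2)
        post = stgpr.GPPosterior("A", np.array(YEARS, float),
                                 np.full(len(YEARS), -12.0),
                                 4.0 * np.eye(len(YEARS)))
        cube = stgpr.draw_estimates([post], cfg)
        assert ((cube.values > 0) & (cube.values < 1)).all()

    def test_seeded_determinism(self):
        cfg = stgpr.GPRConfig(amplitude=1.0, n_draws=100, seed=9)
        a = stgpr.draw_estimates([self._posterior(0.1)], cfg)
        b = stgpr.draw_estimates([self._posterior(0.1)], cfg)
        assert np.array_equal(a.values, b.values)


class TestSummarize:
    def _cube(self, draws):
        return xr.DataArray(np.asarray(draws, dtype=float)[None, None, :],
                            coords={"district": ["A"], "year": [2000],
                                    "draw": np.arange(len(draws))},
                            dims=("district", "year", "draw"))

    def test_constant_draws(self):
        out = stgpr.summarize(self._cube([0.3] * 10))
        row = out.iloc[0]
        assert row["mean"] == pytest.approx(0.3, abs=1e-12)
        assert row["lower"] == pytest.approx(0.3, abs=1e-12)
        assert row["upper"] == pytest.approx(0.3, abs=1e-12)

    def test_percentiles_match_sorted_array_oracle(self):
        draws = np.arange(1, 1001) / 1001.0
        out = stgpr.summarize(self._cube(draws))
        srt = np.sort(draws)
        lo = np.quantile(srt, 0.025, method="linear")
        hi = np.quantile(srt, 0.975, method="linear")
        assert out.iloc[0]["lower"] == pytest.approx(lo, abs=1e-15)
        assert out.iloc[0]["upper"] == pytest.approx(hi, abs=1e-15)

    @given(st.permutations(list(np.arange(1, 21) / 21.0)))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_draw_permutation(self, perm):
        base = stgpr.summarize(self._cube(np.arange(1, 21) / 21.0))
        permuted = stgpr.summarize(self._cube(perm))
        pd.testing.assert_frame_equal(base, permuted)

    def test_needs_two_draws(self):
        with pytest.raises(ValueError):
            stgpr.summarize(self._cube([0.5]))


class TestRunSTGPR:
    def test_small_end_to_end_properties(self, small_geo, noiseless):
        truth, obs, cov, prov = noiseless
        obs = obs.assign(indicator="ebf")
        cfg = stgpr.GPRConfig(n_draws=100, seed=3)
        res = stgpr.run_stgpr(obs, cov, prov, small_geo, YEARS,
                              gpr_config=cfg)
        assert res.cube.sizes == {"indicator": 1,
                                  "district": len(small_geo.district_ids),
                                  "year": len(YEARS), "draw": 100}
        v = res.cube.values
        assert ((v > 0) & (v < 1)).all()
        s = res.summary
        assert (s["lower"] <= s["mean"] + 1e-12).all()
        assert (s["mean"] <= s["upper"] + 1e-12).all()

    def test_byte_identical_given_seed(self, small_geo, noiseless):
        truth, obs, cov, prov = noiseless
        obs = obs.assign(indicator="ebf")
        cfg = stgpr.GPRConfig(n_draws=50, seed=7)
        a = stgpr.run_stgpr(obs, cov, prov, small_geo, YEARS, gpr_config=cfg)
        b = stgpr.run_stgpr(obs, cov, prov, small_geo, YEARS, gpr_config=cfg)
        assert a.cube.values.tobytes() == b.cube.values.tobytes()

    def test_district_without_data_follows_mean_function(self, small_geo,
                                                         noiseless):
        truth, obs, cov, prov = noiseless
        d0 = small_geo.district_ids[0]
        obs = obs.assign(indicator="ebf")
        obs = obs[obs["district"] != d0]
        cfg = stgpr.GPRConfig(n_draws=100, seed=3)
        res = stgpr.run_stgpr(obs, cov, prov, small_geo, YEARS, gpr_config=cfg)
        m2 = res.stage2_mean
        m2 = m2[m2["district"] == d0].set_index("year")["mean_logit"]
        s = res.summary[res.summary["district"] == d0].set_index("year")
        # posterior mean in logit space equals the ST mean function
        post_logit = np.log(s["mean"] / (1 - s["mean"]))
        np.testing.assert_allclose(post_logit, m2.loc[s.index], atol=0.15)
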