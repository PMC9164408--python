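"""Random-intercept model families: estimation, conversions, predictions."""

import numpy as np
import pandas as pd
import pytest

import dlqivalue as dv
from dlqivalue.model import (
    FitResult,
    TTORandomIntercept,
    combine_scalable,
    explanatory_power_shares,
    fit_indices,
    scalable_transform,
)


def _toy_frame(y, groups, levels):
    """Long-format frame from raw vectors (levels: (n, 10) ints)."""
    df = pd.DataFrame(levels, columns=[f"q{i}" for i in range(1, 11)])
    df.insert(0, "respondent_id", groups)
    df.insert(1, "block_id", 1)
    df.insert(2, "state_id", [f"s{tuple(l)}" for l in levels])
    df["y"] = y
    df["t"] = 10 * (1 - df["y"])
    df["response_time_s"] = 30.0
    return df


@pytest.fixture(scope="module")
def trader_df(trader_cohort):
    return trader_cohort[0].data


@pytest.fixture(scope="module")
def final13(final_design):
    return final_design


class TestLinear:
    def test_noiseless_data_recovered_exactly(self):
        rng = np.random.default_rng(0)
        levels = rng.integers(0, 4, size=(60, 10))
        design = dv.DummyDesign.full().subset([(1, 1), (5, 3)])
        X = dv.design_matrix(levels, design)
        beta_true = np.array([-0.1, -0.2])
        y = 0.9 + X @ beta_true
        df = _toy_frame(y, np.repeat(np.arange(12), 5), levels)
        res = TTORandomIntercept.from_dataframe(df, design, family="linear").fit(compute_se=False)
        fr = res.as_fit_result()
        assert fr.alpha == pytest.approx(0.9, abs=1e-5)
        assert fr.beta[(1, 1)] == pytest.approx(-0.1, abs=1e-5)
        assert fr.beta[(5, 3)] == pytest.approx(-0.2, abs=1e-5)

    def test_zero_design_gives_grand_mean(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0.7, 0.1, size=50)
        levels = np.zeros((50, 10), dtype=int)
        design = dv.DummyDesign.full().subset([(1, 1)])
        df = _toy_frame(y, np.repeat(np.arange(10), 5), levels)
        res = TTORandomIntercept.from_dataframe(df, design, family="linear").fit(compute_se=False)
        assert res.as_fit_result().alpha == pytest.approx(y.mean(), abs=1e-4)

    def test_agrees_with_statsmodels_mixedlm(self, trader_df, final13):
        """Independent cross-check of the linear random-intercept ML fit."""
        import statsmodels.api as sm

        res = TTORandomIntercept.from_dataframe(trader_df, final13, family="linear").fit(
            compute_se=False)
        qcols = [f"q{i}" for i in range(1, 11)]
        X = sm.add_constant(dv.design_matrix(trader_df[qcols].to_numpy(np.int8), final13))
        mlm = sm.MixedLM(trader_df["y"], X, groups=trader_df["respondent_id"]).fit(reml=False)
        ours = np.r_[res.loc, res.beta_native]
        assert np.allclose(ours, mlm.params[: len(ours)], atol=2e-4)
        assert res.sigma_u**2 == pytest.approx(float(mlm.cov_re.iloc[0, 0]), rel=0.02)


class TestCensored:
    def test_matches_linear_without_boundary_observations(self, catalogue, blocks):
        p = dv.SimulationParams(rng_seed=3, p_careless=0.0,
                                p_nontrader_base=-30.0, p_nontrader_slope=0.0)
        df = dv.simulate_cohort(catalogue, blocks, 300, p).data
        interior = df[~df["respondent_id"].isin(
            df.loc[(df.y <= 0) | (df.y >= 1), "respondent_id"])]
        design = dv.DummyDesign.full().subset(list(dv.reference.FINAL_DUMMIES))
        lin = TTORandomIntercept.from_dataframe(interior, design, family="linear").fit(
            compute_se=False)
        cen = TTORandomIntercept.from_dataframe(interior, design, family="censored").fit(
            start_params=lin.params, compute_se=False)
        assert np.allclose(lin.params, cen.params, atol=1e-4)

    def test_all_boundary_rejected(self):
        levels = np.zeros((10, 10), dtype=int)
        df = _toy_frame(np.ones(10), np.repeat([1, 2], 5), levels)
        design = dv.DummyDesign.full().subset([(1, 1)])
        with pytest.raises(ValueError, match="censored"):
            TTORandomIntercept.from_dataframe(df, design, family="censored")

    def test_right_censoring_share_reported(self, trader_df, final13):
        res = TTORandomIntercept.from_dataframe(trader_df, final13, family="censored").fit(
            compute_se=False)
        share = res.share_right_censored()
        assert 0.0 < share < 0.5  # many mild states sit near the upper bound


class TestOrdinal:
    def test_consistent_with_censored_on_gridded_latent_data(self, trader_df, final13):
        """Interval- vs censored-likelihood treatments of the same grid data
        agree within 2 standard errors on every coefficient."""
        cen = TTORandomIntercept.from_dataframe(trader_df, final13, family="censored").fit()
        orx = TTORandomIntercept.from_dataframe(trader_df, final13, family="ordinal").fit(
            compute_se=False)
        fr_c, fr_o = cen.as_fit_result(), orx.as_fit_result()
        for d in final13.active:
            se = fr_c.se_beta[d]
            assert abs(fr_c.beta[d] - fr_o.beta[d]) < 2 * se
        assert abs(fr_c.alpha - fr_o.alpha) < 0.02

    def test_collapsed_categories_rejected(self):
        levels = np.zeros((10, 10), dtype=int)
        df = _toy_frame(np.full(10, 0.5), np.repeat([1, 2], 5), levels)
        design = dv.DummyDesign.full().subset([(1, 1)])
        with pytest.raises(ValueError, match="distinct"):
            TTORandomIntercept.from_dataframe(df, design, family="ordinal")

    def test_off_grid_outcomes_rejected(self):
        levels = np.zeros((10, 10), dtype=int)
        df = _toy_frame(np.linspace(0.31, 0.79, 10), np.repeat([1, 2], 5), levels)
        design = dv.DummyDesign.full().subset([(1, 1)])
        with pytest.raises(ValueError, match="grid"):
            TTORandomIntercept.from_dataframe(df, design, family="ordinal")


class TestBeta:
    def test_symmetric_null_data_gives_half_intercept(self):
        rng = np.random.default_rng(4)
        y = np.clip(rng.normal(0.5, 0.1, size=200), 0.05, 0.95)
        y = np.round(y * 20) / 20
        levels = np.zeros((200, 10), dtype=int)
        df = _toy_frame(y, np.repeat(np.arange(40), 5), levels)
        design = dv.DummyDesign.full().subset([(1, 1)])
        res = TTORandomIntercept.from_dataframe(df, design, family="beta").fit(compute_se=False)
        assert res.as_fit_result().alpha == pytest.approx(0.5, abs=0.02)

    def test_ape_close_to_censored_effects(self, trader_df, final13):
        """Beta average partial effects are on the same utility scale as the
        other families (loose agreement; the families differ)."""
        cen = TTORandomIntercept.from_dataframe(trader_df, final13, family="censored").fit(
            compute_se=False).as_fit_result()
        bet = TTORandomIntercept.from_dataframe(trader_df, final13, family="beta").fit(
            compute_se=False).as_fit_result()
        diffs = [abs(cen.beta[d] - bet.beta[d]) for d in final13.active]
        assert max(diffs) < 0.03


class TestScalable:
    def test_transform_arithmetic(self):
        levels = np.vstack([np.full((1, 10), 3), np.zeros((4, 10), dtype=int)] * 2)
        y = np.array([0.4, 0.7, 0.7, 0.7, 0.7, 0.5, 1.0, 0.9, 0.8, 0.75])
        df = _toy_frame(y, np.repeat([1, 2], 5), levels.astype(int))
        tr = scalable_transform(df)
        r1 = tr[tr.respondent_id == 1]
        assert r1["lambda_star"].iloc[0] == pytest.approx(0.6)
        assert r1["z_star"].iloc[0] == pytest.approx(1.0)  # worst state
        assert r1["z_star"].iloc[1] == pytest.approx(0.5)  # (1-0.7)/0.6
        r2 = tr[tr.respondent_id == 2]
        assert r2["z_star"].iloc[1] == pytest.approx(0.0)  # y = 1 on a milder state

    def test_transform_rejects_nontrading_worst(self):
        levels = np.vstack([np.full((1, 10), 3), np.zeros((4, 10), dtype=int)])
        df = _toy_frame(np.array([1.0, 0.9, 0.8, 0.85, 0.9]), np.ones(5, dtype=int),
                        levels.astype(int))
        with pytest.raises(ValueError, match="screened"):
            scalable_transform(df)
        assert scalable_transform(df, drop_zero_scale_range=True).empty

    def test_mean_lambda_star_equals_one_minus_mean_worst(self, screened):
        _, traders = screened
        tr = scalable_transform(traders, drop_zero_scale_range=True)
        lam = tr.groupby("respondent_id")["lambda_star"].first()
        qcols = [f"q{i}" for i in range(1, 11)]
        worst_y = tr[(tr[qcols] == 3).all(axis=1)]["y"]
        assert lam.mean() == pytest.approx(1.0 - worst_y.mean(), abs=1e-12)

    def test_degenerate_lambda_combination(self):
        design = dv.DummyDesign.full().subset([(2, 3), (9, 1)])
        zfit = FitResult(
            family="scalable_censored", alpha=0.3, beta={(2, 3): 0.08, (9, 1): 0.06},
            se_alpha=None, se_beta=None, sigma_u=0.1, sigma_v=0.2, phi=None,
            delta=None, scale="z", loglik=0.0, n_obs=10, n_respondents=2,
            converged=True, design=design)
        at_one = combine_scalable(zfit, lambda_star=np.array([1.0]), design=design)
        assert at_one.alpha == pytest.approx(0.7)
        assert at_one.beta[(2, 3)] == pytest.approx(-0.08)  # sign flip into utility
        at_half = combine_scalable(zfit, lambda_star=np.array([0.5]), design=design)
        assert at_half.beta[(2, 3)] == pytest.approx(-0.04)  # linear scaling, no clipping
        with pytest.raises(ValueError, match="empty"):
            combine_scalable(zfit, lambda_star=np.array([]), design=design)

    def test_left_censored_equals_linear_without_zeros(self, screened, final13):
        _, traders = screened
        tr = scalable_transform(traders, drop_zero_scale_range=True)
        keep = ~tr.groupby("respondent_id")["z_star"].transform(lambda s: (s <= 0).any())
        sub = tr[keep]
        lin = TTORandomIntercept.from_dataframe(sub, final13, family="scalable_linear").fit(
            compute_se=False)
        cen = TTORandomIntercept.from_dataframe(sub, final13, family="scalable_censored").fit(
            start_params=lin.params, compute_se=False)
        assert np.allclose(lin.params, cen.params, atol=1e-4)


class TestPredictionMonotonicity:
    @pytest.mark.parametrize("family", ["censored", "ordinal", "beta", "scalable_censored"])
    def test_monotone_with_nonpositive_coefficients(self, trader_df, final13, family):
        res = TTORandomIntercept.from_dataframe(trader_df, final13, family=family).fit(
            compute_se=False)
        # force the sign condition, then check the prediction map itself
        res.beta_native = -np.abs(res.beta_native) * (1 if family != "scalable_censored" else -1)
        rng = np.random.default_rng(0)
        for _ in range(20):
            lv = rng.integers(0, 4, size=10)
            item = rng.integers(0, 10)
            lv[item] = min(lv[item], 2)
            hi = lv.copy()
            hi[item] += 1
            X = dv.design_matrix(np.vstack([lv, hi]), final13)
            pred = res.predict_utility(X)
            assert pred[1] <= pred[0] + 1e-9


class TestFitIndices:
    def test_perfect_fit(self):
        levels = np.tile(np.eye(10, dtype=int)[:5] * 2, (4, 1))
        y = np.linspace(0.2, 0.9, 20)
        df = _toy_frame(y, np.repeat(np.arange(4), 5), levels)
        out = fit_indices(y, df)
        assert out["corr_individual"] == pytest.approx(1.0)
        assert out["mad_individual"] == 0.0

    def test_constant_fit_guarded(self):
        levels = np.zeros((10, 10), dtype=int)
        df = _toy_frame(np.linspace(0.2, 0.9, 10), np.repeat([1, 2], 5), levels)
        out = fit_indices(np.full(10, 0.5), df)
        assert out["corr_individual"] == 0.0
        assert out["mad_individual"] == pytest.approx(np.mean(np.abs(df.y - 0.5)))

    def test_toy_state_means_and_medians(self):
        levels = np.repeat(np.eye(10, dtype=int)[:3], 4, axis=0)
        y = np.array([0.2, 0.4, 0.6, 0.8, 0.3, 0.3, 0.5, 0.9, 1.0, 0.9, 0.8, 0.7])
        df = _toy_frame(y, np.tile([1, 2, 3, 4], 3), levels)
        fitted = np.repeat([0.5, 0.5, 0.85], 4)
        out = fit_indices(fitted, df)
        # hand-computed per-state means: 0.5, 0.5, 0.85; medians: 0.5, 0.4, 0.85
        assert out["mad_mean"] == pytest.approx(0.0, abs=1e-12)
        assert out["mad_median"] == pytest.approx(abs(0.5 - 0.4) / 3, abs=1e-12)


class TestExplanatoryPower:
    def test_share_arithmetic(self):
        out = explanatory_power_shares(0.2, 0.4, 0.1)
        assert out["relative_performance"] == pytest.approx(0.5)
        assert out["incremental_share"] == pytest.approx(1 / 3)
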