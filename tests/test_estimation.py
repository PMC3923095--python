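"""Marginal ratios, ratio-estimator totals, crude and standardized rates."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from hliest import (
    crude_rates,
    estimate_table,
    marginal_ratio,
    national_totals,
    period_summary,
    prediction_grid,
    standardized_rates,
)
from hliest.data_io import european_standard_weights


def _with_sigmas(fit, s1, s2):
    return dataclasses.replace(fit, sigma1=s1, sigma2=s2)


class TestMarginalRatio:
    def test_zero_variance_equals_conditional(self, small_fit):
        """With sigma1 = sigma2 = 0 the marginal ratio is exp(x'beta)."""
        from hliest.estimate import grid_design_matrix

        grid = prediction_grid([2006])
        fit0 = _with_sigmas(small_fit, 0.0, 0.0)
        alpha = marginal_ratio(fit0, grid)["alpha_hat"].to_numpy()
        X = grid_design_matrix(fit0, grid)
        np.testing.assert_allclose(alpha, np.exp(X @ fit0.params.to_numpy()))

    def test_lognormal_correction_factor(self, small_fit):
        """sigma1=.27, sigma2=.10 multiply the ratio by exp(.04145) ~ 1.0423."""
        grid = prediction_grid([2006])
        a0 = marginal_ratio(_with_sigmas(small_fit, 0.0, 0.0), grid)["alpha_hat"]
        a1 = marginal_ratio(_with_sigmas(small_fit, 0.27, 0.10), grid)["alpha_hat"]
        factor = (a1 / a0).to_numpy()
        expected = np.exp((0.27**2 + 0.10**2) / 2.0)
        assert expected == pytest.approx(1.0423, abs=2e-4)
        np.testing.assert_allclose(factor, expected, rtol=1e-12)

    def test_monte_carlo_oracle(self, small_fit, rng):
        """alpha_hat equals the MC mean of exp(x'beta + b_k + b_ijk)."""
        from hliest.estimate import grid_design_matrix

        grid = prediction_grid([2006]).sample(5, random_state=1)
        alpha = marginal_ratio(small_fit, grid)["alpha_hat"].to_numpy()
        X = grid_design_matrix(small_fit, grid)
        xb = X @ small_fit.params.to_numpy()
        n = 200_000
        u = rng.normal(0, small_fit.sigma1, n) + rng.normal(0, small_fit.sigma2, n)
        eu = np.exp(u)
        mc_mean, mc_se = eu.mean(), eu.std(ddof=1) / np.sqrt(n)
        for a, lin in zip(alpha, xb):
            assert abs(a - np.exp(lin) * mc_mean) < 3 * np.exp(lin) * mc_se

    def test_extrapolation_warns(self, small_fit):
        with pytest.warns(UserWarning, match="extrapolat"):
            marginal_ratio(small_fit, prediction_grid([2030]))


class TestTotalsAndRates:
    def _unit_ratios(self, national):
        grid = national[["sex", "age_cat", "year"]].copy()
        grid["alpha_hat"] = 1.0
        return grid

    def test_identity_ratio_returns_national_stays(self, default_dataset):
        nat = default_dataset.national
        tot = national_totals(self._unit_ratios(nat), nat)
        np.testing.assert_allclose(tot["total"], tot["national_stay_count"])

    def test_additivity_and_linearity(self, default_dataset):
        nat = default_dataset.national
        tot = national_totals(self._unit_ratios(nat), nat)
        by_sex = tot.groupby(["sex", "year"])["total"].sum()
        overall = tot.groupby("year")["total"].sum()
        np.testing.assert_allclose(by_sex.groupby("year").sum(), overall)
        doubled = nat.assign(national_stay_count=nat["national_stay_count"] * 2)
        tot2 = national_totals(self._unit_ratios(nat), doubled)
        np.testing.assert_allclose(tot2["total"], 2 * tot["total"])

    def test_missing_stratum_reported(self, default_dataset):
        nat = default_dataset.national
        with pytest.raises(ValueError, match="missing strata"):
            national_totals(self._unit_ratios(nat), nat.iloc[:-1])

    def test_crude_rate_printed_pair_consistency(self):
        """The printed 2004 total (2,383k) and rate (48.4/1,000) cohere.

        The denominator implied by the printed pair, fed back through the
        rate computation, returns the printed rate.
        """
        total, printed_rate = 2_383_000.0, 48.4
        population = 1000.0 * total / printed_rate  # ~49.24 M adults
        df = pd.DataFrame(
            {"sex": [1], "age_cat": [1], "year": [2004],
             "total": [total], "population": [population]}
        )
        out = crude_rates(
            df[["sex", "age_cat", "year", "total"]],
            df[["sex", "age_cat", "year", "population"]],
        )
        assert round(float(out["rate"].iloc[0]), 1) == printed_rate

    def test_crude_rate_scale_equivariance(self, default_dataset):
        nat = default_dataset.national
        tot = national_totals(self._unit_ratios(nat), nat)
        r1 = crude_rates(tot, default_dataset.population)
        pop2 = default_dataset.population.assign(
            population=default_dataset.population["population"] * 2
        )
        r2 = crude_rates(tot, pop2)
        np.testing.assert_allclose(r1["rate"], 2 * r2["rate"])
        zero_total = tot.assign(total=0.0)
        assert (crude_rates(zero_total, default_dataset.population)["rate"] == 0).all()


class TestStandardization:
    def test_constant_rate_identity(self):
        w = european_standard_weights()
        rates = pd.DataFrame({"age_cat": np.arange(1, 16), "rate": 7.3})
        assert standardized_rates(rates, w) == pytest.approx(7.3)

    def test_degenerate_weights_pick_one_band(self):
        w = pd.DataFrame({"age_cat": np.arange(1, 16), "weight": 0.0})
        w.loc[w["age_cat"] == 15, "weight"] = 1.0
        rates = pd.DataFrame(
            {"age_cat": np.arange(1, 16), "rate": np.arange(1.0, 16.0)}
        )
        # degenerate weights are not a valid standard (>0 invariant) but the
        # convex-combination arithmetic must still behave
        assert standardized_rates(rates, w) == pytest.approx(15.0)

    def test_bounds_property(self, rng):
        w = european_standard_weights()
        rates = pd.DataFrame(
            {"age_cat": np.arange(1, 16), "rate": rng.uniform(10, 200, 15)}
        )
        s = standardized_rates(rates, w)
        assert rates["rate"].min() <= s <= rates["rate"].max()

    def test_weight_grid_mismatch(self):
        w = european_standard_weights().iloc[:-1]
        rates = pd.DataFrame({"age_cat": np.arange(1, 16), "rate": 1.0})
        with pytest.raises(ValueError, match="do not match|sum"):
            standardized_rates(rates, w)

    def test_published_sex_ratio(self):
        """Published period standardized rates give the published 1.45 ratio."""
        assert round(57.6 / 39.8, 2) == 1.45


class TestPeriodSummary:
    def test_published_all_persons_period_rate(self):
        yearly = [47.2, 49.1, 49.4, 49.1, 48.8]
        assert round(period_summary(yearly), 1) == 48.7

    def test_published_women_period_rate(self):
        yearly = [39.0, 40.1, 40.2, 40.0, 39.7]
        assert round(period_summary(yearly), 1) == 39.8

    def test_mean_of_constants(self):
        assert period_summary([3.3, 3.3, 3.3]) == pytest.approx(3.3)

    def test_needs_two_years(self):
        with pytest.raises(ValueError):
            period_summary([1.0])


@pytest.fixture(scope="module")
def tables(default_fit, default_dataset):
    ds = default_dataset
    return estimate_table(default_fit, ds.national, ds.population, ds.weights)


class TestEstimateTable:
    def test_conservation_exact(self, tables):
        s = tables.summary.set_index(["scope", "year"])
        for year in list(range(2004, 2009)) + ["period"]:
            men = s.loc[("men", year), "total"]
            women = s.loc[("women", year), "total"]
            assert men + women == pytest.approx(s.loc[("all", year), "total"], rel=1e-12)

    def test_cis_ordered_and_positive(self, tables):
        s = tables.summary
        for kind in ("total", "crude_rate", "std_rate"):
            assert (s[f"{kind}_ci_low"] <= s[kind]).all()
            assert (s[kind] <= s[f"{kind}_ci_high"]).all()
            assert (s[f"{kind}_ci_low"] >= 0).all()

    def test_std_rate_within_age_specific_range(self, tables):
        s = tables.summary.set_index(["scope", "year"])
        age = tables.age_specific
        for sex, scope in ((1, "men"), (2, "women")):
            sub = age[(age["sex"] == sex) & (age["year"] == 2006)]
            std = s.loc[(scope, 2006), "std_rate"]
            assert sub["rate"].min() <= std <= sub["rate"].max()

    def test_monotone_in_alpha(self, default_fit, default_dataset):
        """Inflating the ratio in one stratum raises the matching aggregates."""
        ds = default_dataset
        base = estimate_table(default_fit, ds.national, ds.population, ds.weights)
        bumped_nat = ds.national.copy()
        sel = (
            (bumped_nat["sex"] == 1)
            & (bumped_nat["age_cat"] == 5)
            & (bumped_nat["year"] == 2006)
        )
        bumped_nat.loc[sel, "national_stay_count"] *= 2
        bumped = estimate_table(default_fit, bumped_nat, ds.population, ds.weights)
        b, a = bumped.summary.set_index(["scope", "year"]), base.summary.set_index(
            ["scope", "year"]
        )
        assert b.loc[("men", 2006), "total"] > a.loc[("men", 2006), "total"]
        assert b.loc[("all", 2006), "std_rate"] > a.loc[("all", 2006), "std_rate"]
        assert b.loc[("women", 2006), "total"] == a.loc[("women", 2006), "total"]

    def test_period_pooling_flag(self, default_fit, default_dataset):
        ds = default_dataset
        pooled = estimate_table(
            default_fit, ds.national, ds.population, ds.weights,
            period_pooling="pooled",
        )
        mean = estimate_table(default_fit, ds.national, ds.population, ds.weights)
        pm = pooled.summary.set_index(["scope", "year"])
        mm = mean.summary.set_index(["scope", "year"])
        # identical yearly rows, near-identical (not identical) period rates
        np.testing.assert_allclose(
            pm.loc[("all", 2006), "std_rate"], mm.loc[("all", 2006), "std_rate"]
        )
        assert pm.loc[("all", "period"), "std_rate"] == pytest.approx(
            mm.loc[("all", "period"), "std_rate"], rel=0.02
        )
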