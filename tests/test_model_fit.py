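"""Design construction, PQL estimation, time contrasts and diagnostics."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from hliest import (
    FitControl,
    SimulationConfig,
    assess_time_effect,
    build_design,
    fit_pql,
    model_diagnostics,
    simulate_network,
)
from hliest.model import ConvergenceError, FIXED_EFFECT_NAMES

from conftest import small_config


class TestBuildDesign:
    def test_columns_and_shape(self, default_design):
        assert default_design.X.shape == (900, 7)
        assert default_design.columns == FIXED_EFFECT_NAMES
        np.testing.assert_array_equal(default_design.X[:, 0], 1.0)

    def test_men_reference_coding(self, default_design):
        men = default_design.frame["sex"].to_numpy() == 1
        assert np.all(default_design.X[men, 1] == 0.0)
        assert np.all(default_design.X[men, 6] == 0.0)
        women = ~men
        np.testing.assert_allclose(
            default_design.X[women, 6], default_design.X[women, 5]
        )

    def test_zero_stay_rows_dropped_with_warning(self, default_dataset):
        counts = default_dataset.counts.copy()
        counts.loc[counts.index[0], ["stay_count", "hli_count"]] = 0
        with pytest.warns(UserWarning, match="zero stays"):
            design = build_design(counts)
        assert design.n == len(counts) - 1

    def test_all_zero_design_is_error(self, default_dataset):
        counts = default_dataset.counts.copy()
        counts["stay_count"] = 0
        counts["hli_count"] = 0
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="empty design"):
                build_design(counts)


class TestFitPQL:
    def test_glm_limit(self):
        """No random effects in truth: PQL agrees with a plain offset GLM."""
        cfg = small_config(sigma1=0.0, sigma2=0.0, sigma_e=0.0,
                           size_min=200, size_max=2000)
        ds = simulate_network(cfg, seed=101)
        design = build_design(ds.counts)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # boundary variance warnings expected
            fit = fit_pql(design)
        glm = sm.GLM(
            design.y, design.X, family=sm.families.Poisson(), offset=design.offset
        ).fit()
        se = glm.bse
        assert np.all(np.abs(fit.params.to_numpy() - glm.params) < 3 * se)
        assert fit.sigma1 < 0.03 and fit.sigma2 < 0.03

    def test_row_order_invariance(self, small_dataset):
        counts = small_dataset.counts
        fit_a = fit_pql(build_design(counts))
        shuffled = counts.sample(frac=1.0, random_state=3).reset_index(drop=True)
        fit_b = fit_pql(build_design(shuffled))
        np.testing.assert_allclose(
            fit_a.params.to_numpy(), fit_b.params.to_numpy(), atol=1e-8
        )
        assert fit_a.sigma1 == pytest.approx(fit_b.sigma1, abs=1e-8)

    def test_offset_scaling_shifts_ratio_exactly(self, small_dataset):
        """Multiplying all stays by c divides every fitted ratio by c."""
        from hliest.estimate import marginal_ratio, prediction_grid

        c = 4
        counts = small_dataset.counts
        scaled = counts.assign(stay_count=counts["stay_count"] * c)
        fit_a = fit_pql(build_design(counts))
        fit_b = fit_pql(build_design(scaled))
        grid = prediction_grid([2006])
        ra = marginal_ratio(fit_a, grid)["alpha_hat"].to_numpy()
        rb = marginal_ratio(fit_b, grid)["alpha_hat"].to_numpy()
        np.testing.assert_allclose(ra, rb * c, rtol=1e-4)

    def test_single_hospital_not_identifiable(self, small_dataset):
        one = small_dataset.counts.query("hospital_id == 'H1'")
        with pytest.raises(ConvergenceError, match="2 hospitals"):
            fit_pql(build_design(one))

    def test_covariance_symmetric_psd(self, default_fit):
        V = default_fit.cov_fixed
        np.testing.assert_allclose(V, V.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(V) > 0)
        assert np.all(default_fit.se > 0)

    def test_variance_component_cis_bracket_estimates(self, default_fit):
        lo, hi = default_fit.sigma1_ci
        assert 0 < lo < default_fit.sigma1 < hi
        lo2, hi2 = default_fit.rho_ci
        assert -1 < lo2 < default_fit.rho < hi2 < 1

    def test_glmmpql_oracle(self, default_design, default_fit, tmp_path):
        """Independent cross-check against MASS::glmmPQL on identical data.

        glmmPQL solves the same working model but with ML inner fits, so
        fixed effects must agree closely and variance components to ~15%.
        """
        d = default_design
        df = pd.DataFrame(
            {
                "hli": d.y.astype(int),
                "stay": np.exp(d.offset).round().astype(int),
                "sexw": d.X[:, 1], "t": d.X[:, 2],
                "B1": d.X[:, 3], "B2": d.X[:, 4], "B3": d.X[:, 5],
                "sexB3": d.X[:, 6],
                "hospital": d.hospital, "unit": d.unit,
                "year": d.year.astype(int),
            }
        )
        csv = tmp_path / "design.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages({{library(MASS); library(nlme)}})
            d <- read.csv("{csv}")
            d$hospital <- factor(d$hospital); d$unit <- factor(d$unit)
            f <- glmmPQL(hli ~ sexw + t + B1 + B2 + B3 + sexB3 + offset(log(stay)),
                         random = ~1 | hospital/unit, family = quasipoisson,
                         correlation = corAR1(form = ~ year | hospital/unit),
                         data = d, verbose = FALSE)
            vc <- VarCorr(f)
            cat(fixef(f), as.numeric(vc[2, 2]), as.numeric(vc[4, 2]),
                coef(f$modelStruct$corStruct, unconstrained = FALSE),
                f$sigma^2, sep = "\\n")
            """
        )
        r = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert r.returncode == 0, r.stderr
        vals = [float(x) for x in r.stdout.strip().split()]
        beta_r, sigma1_r, sigma2_r, rho_r, phi_r = (
            np.array(vals[:7]), vals[7], vals[8], vals[9], vals[10]
        )
        tol = np.maximum(0.5 * default_fit.se.to_numpy(), 1e-3)
        assert np.all(np.abs(default_fit.params.to_numpy() - beta_r) < tol)
        assert default_fit.sigma1 == pytest.approx(sigma1_r, rel=0.15)
        assert default_fit.sigma2 == pytest.approx(sigma2_r, rel=0.15)
        assert default_fit.rho == pytest.approx(rho_r, abs=0.05)
        assert default_fit.dispersion == pytest.approx(phi_r, rel=0.10)


class TestTimeContrasts:
    def test_linear_truth_keeps_only_linear(self, default_design):
        """Under a purely linear generative trend the higher orders are noise."""
        report = assess_time_effect(default_design)
        assert list(report["degree"]) == [1, 2, 3, 4]
        assert report.loc[report["degree"] == 1, "retained"].item()

    def test_quadratic_injection_detected(self):
        """A strong quadratic year effect shows up in the degree-2 contrast."""
        cfg = small_config()
        ds = simulate_network(cfg, seed=55)
        counts = ds.counts.copy()
        bump = np.exp(0.35 * (counts["year"] - 2006) ** 2)
        counts["hli_count"] = np.round(counts["hli_count"] * bump).astype(int)
        report = assess_time_effect(build_design(counts))
        assert report.loc[report["degree"] == 2, "p_value"].item() < 0.01
        assert report.loc[report["degree"] == 2, "retained"].item()

    def test_two_years_rejected(self, default_dataset):
        counts = default_dataset.counts.query("year in (2007, 2008)")
        with pytest.raises(ValueError, match="3 distinct years"):
            assess_time_effect(build_design(counts))


class TestDiagnostics:
    def test_bundle_shapes(self, default_fit, default_design):
        diag = model_diagnostics(default_fit, default_design)
        assert set(diag) == {
            "ratio", "residuals", "acf", "qq_hospital", "qq_unit",
            "qq_residuals", "by_hospital",
        }
        assert len(diag["ratio"]) == default_design.n
        assert len(diag["qq_hospital"]) == 8
        assert len(diag["by_hospital"]) == 8
        assert diag["acf"].loc[0, "acf"] == pytest.approx(1.0)

    def test_residuals_centered_when_well_specified(self, default_fit, default_design):
        diag = model_diagnostics(default_fit, default_design)
        r = diag["residuals"]["pearson_residual"]
        assert abs(r.mean()) < 0.1
        # dispersion-scaled residuals have roughly unit spread
        assert 0.7 < r.std() < 1.3

    def test_residual_acf_flags_unmodelled_ar1(self):
        """Serially correlated level-1 noise shows in the residual ACF.

        Conditional residuals carry a mechanical negative lag-1 correlation
        (unit-level shrinkage), so the check is comparative: with a strong
        AR(1) process in the data and rho forced to 0 in the fit, the lag-1
        ACF must sit clearly above the ACF obtained from serially
        uncorrelated data, and the freely estimated rho must be positive.
        """

        def lag1_acf(rho_data, seed):
            cfg = SimulationConfig(rho=rho_data, sigma_e=0.2)
            ds = simulate_network(cfg, seed=seed)
            design = build_design(ds.counts)
            fit = fit_pql(design, FitControl(fix_rho=0.0, compute_vc_cov=False))
            return model_diagnostics(fit, design)["acf"].loc[1, "acf"]

        assert lag1_acf(0.6, seed=1) > lag1_acf(0.0, seed=1) + 0.1

        cfg = SimulationConfig(rho=0.6, sigma_e=0.2)
        ds = simulate_network(cfg, seed=1)
        free = fit_pql(build_design(ds.counts), FitControl(compute_vc_cov=False))
        assert free.rho > 0.2
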