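"""Separate ratio estimation of national HLI totals and incidence rates.

The fitted mixed model yields, for every sex x age band x year stratum, the
marginal expected number of ED-treated HLIs per injury-related hospital stay

    alpha_hat_ij(t) = exp(x_ij(t)' beta + sigma1^2/2 + sigma2^2/2),

the lognormal correction arising from averaging the conditional ratio over
the two normal random-intercept distributions.  Multiplying by the known
national stay totals gives stratum totals I_hat_ij(t) = alpha_hat * S_ij(t);
sums of those are the national totals, and dividing by population
person-years gives crude and directly age-standardized incidence rates
(European standard population truncated to ages 15+).  All aggregates are
linear in the stratum totals, so their delta-method variances come from the
machinery in :mod:`hliest.uncertainty`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import N_AGE_BANDS, SEXES
from .model import FittedModel, age_centers, natural_cubic_basis
from . import uncertainty as unc

__all__ = [
    "EstimateTables",
    "prediction_grid",
    "grid_design_matrix",
    "marginal_ratio",
    "national_totals",
    "crude_rates",
    "standardized_rates",
    "period_summary",
    "estimate_table",
]

SCOPES = ("men", "women", "all")
_SCOPE_SEXES = {"men": (1,), "women": (2,), "all": (1, 2)}


def prediction_grid(years) -> pd.DataFrame:
    """Full sex x age-band x year grid in canonical row order."""
    years = sorted(int(y) for y in years)
    return pd.DataFrame(
        [(s, j, y) for s in SEXES for j in range(1, N_AGE_BANDS + 1) for y in years],
        columns=["sex", "age_cat", "year"],
    )


def grid_design_matrix(fit: FittedModel, grid: pd.DataFrame) -> np.ndarray:
    """Fixed-effect rows x_ij(t) for grid strata, on the fit's basis/origin."""
    basis = natural_cubic_basis(fit.internal_knots, fit.boundary_knots)
    B = basis(age_centers(grid["age_cat"].to_numpy()))
    women = (grid["sex"].to_numpy() == 2).astype(float)
    t = grid["year"].to_numpy(dtype=float) - fit.year_origin
    return np.column_stack([np.ones(len(grid)), women, t, B, women * B[:, 2]])


def marginal_ratio(
    fit: FittedModel,
    grid: pd.DataFrame,
    extrapolation_window: float = 0.0,
) -> pd.DataFrame:
    """Marginal expected HLIs per stay for each stratum of ``grid``.

    alpha_hat = exp(x'beta + sigma1^2/2 + sigma2^2/2); with both variance
    components zero the conditional and marginal ratios coincide.  Years
    outside the fitted range (plus ``extrapolation_window``) trigger a
    warning, not an error.
    """
    if not fit.converged:
        raise ValueError("marginal ratios require a converged fit")
    X = grid_design_matrix(fit, grid)
    correction = 0.5 * (fit.sigma1**2 + fit.sigma2**2)
    eta = X @ fit.params.to_numpy() + correction
    if not np.all(np.isfinite(eta)):
        raise FloatingPointError("non-finite linear predictor on the grid")
    t = np.abs(grid["year"].to_numpy(dtype=float) - fit.year_origin)
    max_fit_span = 2.0 + extrapolation_window  # fitted years span +/-2 of origin
    if np.any(t > max_fit_span):
        import warnings

        warnings.warn(
            "prediction grid extends beyond the fitted years; "
            "ratios are extrapolated",
            stacklevel=2,
        )
    out = grid.copy()
    out["alpha_hat"] = np.exp(eta)
    return out


def national_totals(ratios: pd.DataFrame, national: pd.DataFrame) -> pd.DataFrame:
    """Stratum totals I_hat_ij(t) = alpha_hat x national stay count."""
    merged = ratios.merge(national, on=["sex", "age_cat", "year"], how="left")
    if merged["national_stay_count"].isna().any():
        gaps = merged.loc[
            merged["national_stay_count"].isna(), ["sex", "age_cat", "year"]
        ].to_dict("records")
        raise ValueError(f"national stay table is missing strata: {gaps[:5]}")
    merged["total"] = merged["alpha_hat"] * merged["national_stay_count"]
    return merged


def crude_rates(totals: pd.DataFrame, population: pd.DataFrame) -> pd.DataFrame:
    """Stratum rates per 1,000 person-years (total / population x 1000)."""
    merged = totals.merge(population, on=["sex", "age_cat", "year"], how="left")
    if merged["population"].isna().any() or (merged["population"] <= 0).any():
        raise ValueError("population must be present and strictly positive")
    merged["rate"] = 1000.0 * merged["total"] / merged["population"]
    return merged


def standardized_rates(age_specific_rates: pd.DataFrame, weights: pd.DataFrame) -> float:
    """Direct standardization: sum_j w_j x rate_j over age bands 1..15."""
    w = weights.set_index("age_cat")["weight"]
    r = age_specific_rates.set_index("age_cat")["rate"]
    if set(r.index) != set(w.index):
        raise ValueError(
            f"age bands of rates {sorted(r.index)} do not match weights "
            f"{sorted(w.index)}"
        )
    if not np.isclose(w.sum(), 1.0):
        raise ValueError(f"weights sum to {w.sum():.6f}, expected 1")
    return float((w * r).sum())


def period_summary(yearly: pd.Series | np.ndarray) -> float:
    """Period value = unweighted mean of the yearly values."""
    vals = np.asarray(yearly, dtype=float)
    if len(vals) < 2:
        raise ValueError("a period summary needs at least 2 years")
    return float(vals.mean())


# ---------------------------------------------------------------------------
# full estimate table with delta-method uncertainty
# ---------------------------------------------------------------------------

@dataclass
class EstimateTables:
    """National estimates: per-scope summaries, age-specific detail, ratio."""

    summary: pd.DataFrame       # scope x (years + period): totals and rates + CIs
    age_specific: pd.DataFrame  # sex x age band x (years + period) totals/rates
    rate_ratio: dict            # period standardized men/women ratio with CI


def _weight_vectors(g: pd.DataFrame, weights: pd.DataFrame, scope: str, years):
    """Per-row combination coefficients for total / crude / standardized."""
    espw = weights.set_index("age_cat")["weight"]
    sexes = _SCOPE_SEXES[scope]
    in_scope = g["sex"].isin(sexes).to_numpy()
    # population of the scope per (age_cat, year): summed over scope sexes
    pop_scope = (
        g[g["sex"].isin(sexes)]
        .groupby(["age_cat", "year"])["population"]
        .sum()
    )
    n_years = len(years)
    out = {}
    for year in list(years) + ["period"]:
        if year == "period":
            sel = in_scope
            time_w = 1.0 / n_years
        else:
            sel = in_scope & (g["year"] == year).to_numpy()
            time_w = 1.0
        w_tot = np.where(sel, time_w, 0.0)
        pop_total_by_year = pop_scope.groupby("year").sum()
        w_crude = np.where(
            sel,
            time_w * 1000.0 / g["year"].map(pop_total_by_year).to_numpy(),
            0.0,
        )
        band_pop = pd.MultiIndex.from_frame(g[["age_cat", "year"]]).map(pop_scope)
        w_std = np.where(
            sel,
            time_w
            * 1000.0
            * g["age_cat"].map(espw).to_numpy()
            / np.asarray(band_pop, dtype=float),
            0.0,
        )
        out[year] = {"total": w_tot, "crude_rate": w_crude, "std_rate": w_std}
    return out


def estimate_table(
    fit: FittedModel,
    national: pd.DataFrame,
    population: pd.DataFrame,
    weights: pd.DataFrame,
    years=None,
    inflate_dispersion: bool = True,
    period_pooling: str = "mean",
) -> EstimateTables:
    """Compute the full national estimate table with 95% CIs.

    One summary row per scope (men / women / all) and period (each year plus
    the multi-year period, pooled as the unweighted mean of yearly values by
    default, or by pooling person-years with ``period_pooling="pooled"``).
    Every variance is the delta-method quadratic form in the augmented
    parameter covariance; totals are reported in counts, rates per 1,000
    person-years.
    """
    if years is None:
        years = sorted(national["year"].unique())
    years = [int(y) for y in years]
    if period_pooling not in ("mean", "pooled"):
        raise ValueError(f"unknown period_pooling {period_pooling!r}")

    grid = prediction_grid(years)
    ratios = marginal_ratio(fit, grid)
    totals = national_totals(ratios, national)
    g = crude_rates(totals, population)
    X_ext = unc.extend_rows(grid_design_matrix(fit, g[["sex", "age_cat", "year"]]))
    aug = unc.assemble_cov(fit, inflate_dispersion=inflate_dispersion)
    tot = g["total"].to_numpy()

    rows = []
    grads_std_period = {}
    for scope in SCOPES:
        wvecs = _weight_vectors(g, weights, scope, years)
        for year, wv in wvecs.items():
            if year == "period" and period_pooling == "pooled":
                # person-year pooling: rates use summed population across years
                sel = wv["total"] > 0
                scale = wv["total"].copy()  # 1/n_years in scope
                pop_map = g.loc[sel].groupby(["sex", "age_cat"])["population"].sum()
                # crude: 1000 * sum(tot) / sum(pop); std: per-band pooled
                espw = weights.set_index("age_cat")["weight"]
                pop_scope = (
                    g.loc[sel].groupby("age_cat")["population"].sum()
                )
                wv = dict(wv)
                wv["crude_rate"] = np.where(
                    sel, 1000.0 / float(g.loc[sel, "population"].sum()), 0.0
                )
                wv["std_rate"] = np.where(
                    sel,
                    1000.0
                    * g["age_cat"].map(espw).to_numpy()
                    / g["age_cat"].map(pop_scope).to_numpy(),
                    0.0,
                )
                del scale, pop_map
            row = {"scope": scope, "year": year}
            for kind in ("total", "crude_rate", "std_rate"):
                c = wv[kind]
                value = float(np.sum(c * tot))
                var = unc.delta_var_total(aug, X_ext, tot, c)
                lo, hi = unc.wald_ci(value, var)
                row[kind] = value
                row[f"{kind}_var"] = var
                row[f"{kind}_se"] = float(np.sqrt(var))
                row[f"{kind}_ci_low"] = lo
                row[f"{kind}_ci_high"] = hi
            rows.append(row)
            if year == "period":
                grads_std_period[scope] = unc.delta_gradient(
                    X_ext, tot, wvecs["period"]["std_rate"]
                )
    summary = pd.DataFrame(rows)

    men_row = summary[(summary["scope"] == "men") & (summary["year"] == "period")]
    women_row = summary[(summary["scope"] == "women") & (summary["year"] == "period")]
    ratio = unc.rate_ratio(
        float(men_row["std_rate"].iloc[0]),
        float(women_row["std_rate"].iloc[0]),
        aug,
        grads_std_period["men"],
        grads_std_period["women"],
    )

    # age-specific detail: totals and rates per sex x band x year, plus the
    # period value (mean of yearly rates / totals)
    age_rows = []
    for sex in SEXES:
        for j in range(1, N_AGE_BANDS + 1):
            sub = g[(g["sex"] == sex) & (g["age_cat"] == j)]
            for year in years + ["period"]:
                if year == "period":
                    mask = ((g["sex"] == sex) & (g["age_cat"] == j)).to_numpy()
                    c = np.where(mask, 1.0 / len(years), 0.0)
                    pop_by_year = sub.set_index("year")["population"]
                    c_rate = np.where(
                        mask,
                        c * 1000.0 / g["year"].map(pop_by_year).to_numpy(),
                        0.0,
                    )
                    value_tot = float(np.sum(c * tot))
                    value_rate = float(np.sum(c_rate * tot))
                else:
                    mask = (
                        (g["sex"] == sex) & (g["age_cat"] == j) & (g["year"] == year)
                    ).to_numpy()
                    c = mask.astype(float)
                    pop = float(g.loc[mask, "population"].iloc[0])
                    c_rate = c * 1000.0 / pop
                    value_tot = float(np.sum(c * tot))
                    value_rate = float(np.sum(c_rate * tot))
                var_tot = unc.delta_var_total(aug, X_ext, tot, c)
                var_rate = unc.delta_var_total(aug, X_ext, tot, c_rate)
                tlo, thi = unc.wald_ci(value_tot, var_tot)
                rlo, rhi = unc.wald_ci(value_rate, var_rate)
                age_rows.append(
                    {
                        "sex": sex,
                        "age_cat": j,
                        "year": year,
                        "total": value_tot,
                        "total_ci_low": tlo,
                        "total_ci_high": thi,
                        "rate": value_rate,
                        "rate_ci_low": rlo,
                        "rate_ci_high": rhi,
                    }
                )
    age_specific = pd.DataFrame(age_rows)
    return EstimateTables(summary=summary, age_specific=age_specific, rate_ratio=ratio)
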