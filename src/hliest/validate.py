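"""Leave-one-hospital-out cross-validation of the national estimates.

With a sentinel network of only a handful of hospitals, the obvious worry is
that a single hospital drives the national extrapolation.  The check refits
the whole pipeline once per hospital with that hospital's rows removed
(national auxiliary data, population and standardization weights unchanged)
and compares the period standardized rate against the full-sample estimate,
in the form of a forest-plot table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    ConvergenceError,
    FitControl,
    build_design,
    fit_pql,
    natural_cubic_basis,
)
from .estimate import estimate_table

__all__ = ["CVResult", "leave_one_hospital_out", "forest_table"]

FULL_SAMPLE_LABEL = "(full sample)"


@dataclass
class CVResult:
    """Parameters and period estimates of one reduced (or the full) fit."""

    excluded_hospital: str
    sigma1: float
    sigma2: float
    rho: float
    period_total: float
    period_std_rate: float
    rate_ci_low: float
    rate_ci_high: float
    relative_difference_pct: float
    failed: bool = False


def _period_row(tables) -> pd.Series:
    s = tables.summary
    return s[(s["scope"] == "all") & (s["year"] == "period")].iloc[0]


def leave_one_hospital_out(
    counts: pd.DataFrame,
    national: pd.DataFrame,
    population: pd.DataFrame,
    weights: pd.DataFrame,
    control: FitControl | None = None,
    internal_knots=None,
    boundary_knots=None,
    year_origin=None,
    hospitals=None,
) -> list[CVResult]:
    """Refit and re-estimate with each hospital excluded in turn.

    The spline knots and year origin of the full-sample fit are reused for
    every reduced fit so all rows estimate the same quantity.  A reduced fit
    that fails is reported as a flagged row, not dropped.  Returns one
    :class:`CVResult` per hospital plus the full-sample reference (last).
    ``hospitals`` restricts the exclusions; naming a hospital absent from
    the counts is an error, not a no-op.
    """
    present = list(pd.unique(counts["hospital_id"].astype(str)))
    if len(present) < 3:
        raise ValueError(f"need at least 3 hospitals for cross-validation, got {len(present)}")
    if hospitals is None:
        hospitals = present
    else:
        hospitals = [str(h) for h in hospitals]
        unknown = sorted(set(hospitals) - set(present))
        if unknown:
            raise ValueError(f"hospital(s) {unknown} not present in the counts table")

    from .model import DEFAULT_INTERNAL_KNOTS, DEFAULT_BOUNDARY_KNOTS, DEFAULT_YEAR_ORIGIN

    internal_knots = internal_knots or DEFAULT_INTERNAL_KNOTS
    boundary_knots = boundary_knots or DEFAULT_BOUNDARY_KNOTS
    year_origin = year_origin or DEFAULT_YEAR_ORIGIN
    basis = natural_cubic_basis(internal_knots, boundary_knots)

    def run(sub_counts):
        design = build_design(sub_counts, basis=basis, year_origin=year_origin)
        fit = fit_pql(design, control)
        tables = estimate_table(fit, national, population, weights)
        return fit, _period_row(tables)

    full_fit, full_row = run(counts)
    full_rate = float(full_row["std_rate"])

    results: list[CVResult] = []
    for h in hospitals:
        sub = counts[counts["hospital_id"].astype(str) != h]
        try:
            fit, row = run(sub)
            rate = float(row["std_rate"])
            results.append(
                CVResult(
                    excluded_hospital=h,
                    sigma1=fit.sigma1,
                    sigma2=fit.sigma2,
                    rho=fit.rho,
                    period_total=float(row["total"]),
                    period_std_rate=rate,
                    rate_ci_low=float(row["std_rate_ci_low"]),
                    rate_ci_high=float(row["std_rate_ci_high"]),
                    relative_difference_pct=100.0 * (rate - full_rate) / full_rate,
                )
            )
        except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
            import warnings

            warnings.warn(f"reduced fit without {h!r} failed: {exc}", stacklevel=2)
            results.append(
                CVResult(
                    excluded_hospital=h,
                    sigma1=np.nan, sigma2=np.nan, rho=np.nan,
                    period_total=np.nan, period_std_rate=np.nan,
                    rate_ci_low=np.nan, rate_ci_high=np.nan,
                    relative_difference_pct=np.nan,
                    failed=True,
                )
            )
    results.append(
        CVResult(
            excluded_hospital=FULL_SAMPLE_LABEL,
            sigma1=full_fit.sigma1,
            sigma2=full_fit.sigma2,
            rho=full_fit.rho,
            period_total=float(full_row["total"]),
            period_std_rate=full_rate,
            rate_ci_low=float(full_row["std_rate_ci_low"]),
            rate_ci_high=float(full_row["std_rate_ci_high"]),
            relative_difference_pct=0.0,
        )
    )
    return results


def forest_table(cv: list[CVResult]) -> pd.DataFrame:
    """Plot-ready forest table; one row per exclusion, full sample last."""
    if not cv:
        raise ValueError("empty cross-validation result list")
    rows = [
        {
            "excluded_hospital": r.excluded_hospital,
            "sigma1": r.sigma1,
            "sigma2": r.sigma2,
            "rho": r.rho,
            "total": r.period_total,
            "rate": r.period_std_rate,
            "ci_low": r.rate_ci_low,
            "ci_high": r.rate_ci_high,
            "relative_difference_pct": r.relative_difference_pct,
            "failed": r.failed,
        }
        for r in cv
    ]
    df = pd.DataFrame(rows)
    # keep input order but force the full-sample reference row last
    is_full = df["excluded_hospital"] == FULL_SAMPLE_LABEL
    return pd.concat([df[~is_full], df[is_full]], ignore_index=True)
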