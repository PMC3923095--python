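"""Quasi-Poisson mixed model for the HLI-to-stay ratio.

The working model describes the number of ED-treated home-and-leisure
injuries I_ijk(t) in sex i, age band j, hospital k, year t as conditionally
Poisson with log-mean

    eta = log S_ijk(t) + beta0 + alpha_i + delta*(t - origin)
          + beta1*B1(a_j) + beta2*B2(a_j) + (beta3 + gamma_i)*B3(a_j)
          + b_k + b_ijk

where S is the injury-stay offset, B1..B3 is a 3-df natural cubic spline in
the age-band center a_j (internal knots 40 and 64), b_k ~ N(0, sigma1^2) is a
hospital intercept, b_ijk ~ N(0, sigma2^2) a sex-age-unit-within-hospital
intercept, and the level-1 (yearly) observations within a unit carry an AR(1)
correlation rho.  Men are the reference sex (alpha_1 = gamma_1 = 0).

Estimation is penalized quasi-likelihood (PQL): iteratively reweighted fits
of a linear mixed model to the working response z = eta - offset +
(y - mu)/mu with weights mu, the inner LMM solved by REML with the nested
random intercepts and AR(1) within-unit residual correlation.  The residual
scale of the working LMM plays the role of the quasi-Poisson dispersion phi,
so the fixed-effect covariance returned by the final weighted fit is already
dispersion-inflated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, linalg, optimize, stats

from .data_io import N_AGE_BANDS

__all__ = [
    "FIXED_EFFECT_NAMES",
    "SplineBasis",
    "DesignData",
    "FitControl",
    "FittedModel",
    "ConvergenceError",
    "age_centers",
    "natural_cubic_basis",
    "build_design",
    "fit_pql",
    "assess_time_effect",
    "model_diagnostics",
]

FIXED_EFFECT_NAMES = (
    "intercept",
    "sex_women",
    "year_c",
    "age_b1",
    "age_b2",
    "age_b3",
    "sex_women:age_b3",
)

DEFAULT_INTERNAL_KNOTS = (40.0, 64.0)
DEFAULT_BOUNDARY_KNOTS = (17.5, 87.5)
DEFAULT_YEAR_ORIGIN = 2006


class ConvergenceError(RuntimeError):
    """PQL outer loop or inner REML optimization failed to converge."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


def age_centers(age_cat) -> np.ndarray:
    """Center of the 5-year age band: 17.5, 22.5, ..., 82.5, and 87.5 for 85+.

    The open top band has no midpoint; 87.5 continues the 5-year spacing of
    the neighboring bands (the fit is insensitive to this convention).
    """
    j = np.asarray(age_cat)
    if np.any((j < 1) | (j > N_AGE_BANDS)):
        raise ValueError(f"age_cat outside 1..{N_AGE_BANDS}")
    return 12.5 + 5.0 * j


# ---------------------------------------------------------------------------
# natural cubic spline basis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplineBasis:
    """3-column natural cubic spline basis (C2, linear beyond the boundary).

    Built like R's ``splines::ns``: a cubic B-spline design on the augmented
    knot sequence, the leading column dropped (absorbed by the model
    intercept), then projected onto the null space of the second-derivative
    constraints at the two boundary knots.  Evaluation outside the boundary
    uses the first-order Taylor extension, which is exact for a natural
    spline.
    """

    internal_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]
    _aug_knots: np.ndarray
    _proj: np.ndarray  # (n_bsplines - 1, 3) null-space projection

    @property
    def n_columns(self) -> int:
        return self._proj.shape[1]

    def _bspline_design(self, x: np.ndarray, deriv: int = 0) -> np.ndarray:
        t = self._aug_knots
        n_basis = len(t) - 4
        out = np.empty((len(x), n_basis))
        eye = np.eye(n_basis)
        for i in range(n_basis):
            spl = interpolate.BSpline(t, eye[i], 3, extrapolate=False)
            if deriv:
                spl = spl.derivative(deriv)
            vals = spl(x)
            out[:, i] = np.nan_to_num(vals)
        return out

    def __call__(self, ages) -> np.ndarray:
        x = np.atleast_1d(np.asarray(ages, dtype=float))
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite age passed to spline basis")
        lo, hi = self.boundary_knots
        inner = np.clip(x, lo, hi)
        design = self._bspline_design(inner)[:, 1:] @ self._proj
        outside = (x < lo) | (x > hi)
        if outside.any():
            d1 = self._bspline_design(inner[outside], deriv=1)[:, 1:] @ self._proj
            design[outside] += (x[outside] - inner[outside])[:, None] * d1
        return design

    def derivative2(self, ages) -> np.ndarray:
        """Second derivative of each basis column (0 at/beyond the boundary)."""
        x = np.atleast_1d(np.asarray(ages, dtype=float))
        lo, hi = self.boundary_knots
        out = np.zeros((len(x), self.n_columns))
        inside = (x >= lo) & (x <= hi)
        out[inside] = self._bspline_design(x[inside], deriv=2)[:, 1:] @ self._proj
        # at the boundary knots themselves the natural constraint forces 0
        at_boundary = np.isclose(x, lo) | np.isclose(x, hi)
        out[at_boundary] = 0.0
        return out


def natural_cubic_basis(
    internal_knots=DEFAULT_INTERNAL_KNOTS,
    boundary_knots=DEFAULT_BOUNDARY_KNOTS,
) -> SplineBasis:
    """Construct the natural cubic spline basis for the age effect.

    ``len(internal_knots) + 1`` columns; the defaults (internal knots at ages
    40 and 64, boundaries at the extreme age-band centers 17.5 and 87.5) give
    the 3-df basis used by the final model.
    """
    internal = tuple(float(k) for k in internal_knots)
    lo, hi = (float(b) for b in boundary_knots)
    knots_all = (lo,) + internal + (hi,)
    if any(a >= b for a, b in zip(knots_all, knots_all[1:])):
        raise ValueError(f"knots must be strictly increasing, got {knots_all}")
    aug = np.array([lo] * 4 + list(internal) + [hi] * 4)
    n_basis = len(aug) - 4

    # second-derivative constraint rows at both boundary knots
    eye = np.eye(n_basis)
    const = np.empty((2, n_basis))
    for i in range(n_basis):
        d2 = interpolate.BSpline(aug, eye[i], 3).derivative(2)
        const[0, i] = d2(lo)
        const[1, i] = d2(hi)
    const = const[:, 1:]  # first B-spline column is dropped from the design
    q, _ = np.linalg.qr(const.T, mode="complete")
    proj = q[:, 2:]
    return SplineBasis(
        internal_knots=internal,
        boundary_knots=(lo, hi),
        _aug_knots=aug,
        _proj=proj,
    )


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

@dataclass
class DesignData:
    """Response, offset, fixed-effect matrix and grouping for the PQL fit."""

    y: np.ndarray          # HLI counts
    offset: np.ndarray     # log stay counts
    X: np.ndarray          # n x 7 fixed-effect matrix
    columns: tuple[str, ...]
    hospital: np.ndarray   # hospital id per row
    unit: np.ndarray       # sex-age unit id within hospital, per row
    year: np.ndarray       # calendar year per row (time order within unit)
    basis: SplineBasis
    year_origin: float
    frame: pd.DataFrame    # the retained input rows, for diagnostics

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]


def build_design(
    counts: pd.DataFrame,
    basis: SplineBasis | None = None,
    year_origin: float = DEFAULT_YEAR_ORIGIN,
) -> DesignData:
    """Build the fixed-effect design from a sentinel strata-count table.

    Columns are exactly (intercept, 1{women}, centered year, B1, B2, B3,
    1{women}*B3) with the log stay count as offset.  Rows with zero stays are
    dropped (log-offset undefined) with a warning.
    """
    if basis is None:
        basis = natural_cubic_basis()
    df = counts.copy()
    zero = df["stay_count"] == 0
    if zero.any():
        warnings.warn(
            f"dropping {int(zero.sum())} strata with zero stays (offset undefined)",
            stacklevel=2,
        )
        df = df[~zero]
    if len(df) == 0:
        raise ValueError("empty design: all rows have zero stays")
    df = df.sort_values(["hospital_id", "sex", "age_cat", "year"], kind="mergesort")
    df = df.reset_index(drop=True)

    ages = age_centers(df["age_cat"].to_numpy())
    B = basis(ages)
    women = (df["sex"].to_numpy() == 2).astype(float)
    t = df["year"].to_numpy(dtype=float) - year_origin
    X = np.column_stack([np.ones(len(df)), women, t, B, women * B[:, 2]])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("fixed-effect design matrix is rank deficient")

    unit = (
        df["hospital_id"].astype(str)
        + "/s" + df["sex"].astype(str)
        + "a" + df["age_cat"].astype(str)
    ).to_numpy()
    return DesignData(
        y=df["hli_count"].to_numpy(dtype=float),
        offset=np.log(df["stay_count"].to_numpy(dtype=float)),
        X=X,
        columns=FIXED_EFFECT_NAMES,
        hospital=df["hospital_id"].astype(str).to_numpy(),
        unit=unit,
        year=df["year"].to_numpy(dtype=float),
        basis=basis,
        year_origin=float(year_origin),
        frame=df,
    )


# ---------------------------------------------------------------------------
# inner weighted LMM (REML) with nested intercepts + AR(1)
# ---------------------------------------------------------------------------

def _hospital_blocks(design: DesignData):
    """Row indices per hospital, with unit slices and year vectors per block."""
    blocks = []
    hospitals = pd.unique(design.hospital)
    for h in hospitals:
        idx = np.flatnonzero(design.hospital == h)
        units = []
        for u in pd.unique(design.unit[idx]):
            uidx = idx[design.unit[idx] == u]
            uidx = uidx[np.argsort(design.year[uidx], kind="mergesort")]
            units.append(uidx)
        blocks.append((h, np.concatenate(units), units))
    return blocks


class _WorkingLMM:
    """REML machinery for one weighted working response.

    The covariance is parameterized as sigma_e^2 * V0(g1, g2, rho) with
    g1 = sigma1/sigma_e, g2 = sigma2/sigma_e; sigma_e^2 (the quasi-Poisson
    dispersion phi) is profiled out of the REML criterion.
    """

    def __init__(self, design: DesignData, z: np.ndarray, w: np.ndarray):
        self.design = design
        self.z = z
        self.invw = 1.0 / w
        self.blocks = _hospital_blocks(design)
        self.n, self.p = design.X.shape
        # precomputed block structure: unit-block mask, within-unit year-gap
        # matrix and sd outer product, so V0 assembly is pure array algebra:
        # V0 = g1sq + g2sq * mask + sd_outer * rho**gaps
        self._struct = []
        for _, rows, units in self.blocks:
            m = len(rows)
            mask = np.zeros((m, m))
            gaps = np.zeros((m, m))
            sd_outer = np.zeros((m, m))
            pos = 0
            yrs = design.year
            for uidx in units:
                k = len(uidx)
                sl = slice(pos, pos + k)
                t = yrs[uidx]
                sd = np.sqrt(self.invw[uidx])
                mask[sl, sl] = 1.0
                gaps[sl, sl] = np.abs(t[:, None] - t[None, :])
                sd_outer[sl, sl] = sd[:, None] * sd[None, :]
                pos += k
            # integer gaps keep rho**gaps well-defined for negative rho
            self._struct.append((mask, np.round(gaps).astype(int), sd_outer))

    def _assemble(self, theta):
        lg1, lg2, psi = theta
        g1sq = np.exp(2.0 * lg1)
        g2sq = np.exp(2.0 * lg2)
        rho = np.tanh(psi)
        X, z = self.design.X, self.z
        logdet = 0.0
        XtVX = np.zeros((self.p, self.p))
        XtVz = np.zeros(self.p)
        ztVz = 0.0
        chols = []
        for (_, rows, units), (mask, gaps, sd_outer) in zip(self.blocks, self._struct):
            V = g1sq + g2sq * mask + sd_outer * (rho**gaps if rho != 0.0 else (gaps == 0))
            L, low = linalg.cho_factor(V, lower=True, check_finite=False)
            logdet += 2.0 * np.sum(np.log(np.diag(L)))
            Xb, zb = X[rows], z[rows]
            Vi_X = linalg.cho_solve((L, low), Xb, check_finite=False)
            Vi_z = linalg.cho_solve((L, low), zb, check_finite=False)
            XtVX += Xb.T @ Vi_X
            XtVz += Xb.T @ Vi_z
            ztVz += zb @ Vi_z
            chols.append((rows, units, (L, low)))
        return logdet, XtVX, XtVz, ztVz, chols, (g1sq, g2sq, rho)

    def neg2_reml(self, theta) -> float:
        try:
            logdet, XtVX, XtVz, ztVz, _, _ = self._assemble(theta)
            cf = linalg.cho_factor(XtVX, check_finite=False)
        except (np.linalg.LinAlgError, linalg.LinAlgError):
            return 1e12
        beta = linalg.cho_solve(cf, XtVz, check_finite=False)
        rss = ztVz - beta @ XtVz
        if rss <= 0:
            return 1e12
        nmp = self.n - self.p
        s2 = rss / nmp
        logdet_xvx = 2.0 * np.sum(np.log(np.diag(cf[0])))
        return nmp * np.log(s2) + logdet + logdet_xvx + nmp

    def neg2_reml_full(self, theta4) -> float:
        """Unprofiled criterion in (log sigma1, log sigma2, psi, log sigma_e)."""
        ls1, ls2, psi, lse = theta4
        theta = (ls1 - lse, ls2 - lse, psi)
        try:
            logdet, XtVX, XtVz, ztVz, _, _ = self._assemble(theta)
            cf = linalg.cho_factor(XtVX, check_finite=False)
        except (np.linalg.LinAlgError, linalg.LinAlgError):
            return 1e12
        beta = linalg.cho_solve(cf, XtVz, check_finite=False)
        rss = ztVz - beta @ XtVz
        s2 = np.exp(2.0 * lse)
        nmp = self.n - self.p
        logdet_xvx = 2.0 * np.sum(np.log(np.diag(cf[0])))
        return nmp * np.log(s2) + logdet + logdet_xvx + rss / s2

    def fit(self, theta0, maxiter=200, fix_rho: float | None = None):
        if fix_rho is None:
            objective, x0 = self.neg2_reml, np.asarray(theta0)
        else:
            psi0 = float(np.arctanh(fix_rho))
            objective = lambda th2: self.neg2_reml(np.append(th2, psi0))  # noqa: E731
            x0 = np.asarray(theta0)[:2]
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"maxiter": maxiter * 4, "xatol": 1e-6, "fatol": 1e-8},
        )
        theta = res.x if fix_rho is None else np.append(res.x, np.arctanh(fix_rho))
        logdet, XtVX, XtVz, ztVz, chols, (g1sq, g2sq, rho) = self._assemble(theta)
        cf = linalg.cho_factor(XtVX, check_finite=False)
        beta = linalg.cho_solve(cf, XtVz, check_finite=False)
        rss = ztVz - beta @ XtVz
        s2 = rss / (self.n - self.p)  # = phi, the quasi-dispersion
        cov_beta = linalg.cho_solve(cf, np.eye(self.p), check_finite=False) * s2
        cov_beta = 0.5 * (cov_beta + cov_beta.T)

        # BLUPs of both random-effect levels (relative scale cancels sigma_e^2)
        resid = self.z - self.design.X @ beta
        b_hosp: dict[str, float] = {}
        b_unit: dict[str, float] = {}
        for (h, rows, units), (_, _, chol) in zip(self.blocks, chols):
            Vi_r = linalg.cho_solve(chol, resid[rows], check_finite=False)
            b_hosp[h] = g1sq * float(np.sum(Vi_r))
            pos = 0
            for uidx in units:
                k = len(uidx)
                u_name = self.design.unit[uidx[0]]
                b_unit[u_name] = g2sq * float(np.sum(Vi_r[pos:pos + k]))
                pos += k
        return {
            "theta": theta,
            "beta": beta,
            "cov_beta": cov_beta,
            "sigma_e2": s2,
            "sigma1": float(np.sqrt(g1sq * s2)),
            "sigma2": float(np.sqrt(g2sq * s2)),
            "rho": float(rho),
            "b_hosp": b_hosp,
            "b_unit": b_unit,
            "converged": bool(res.success),
            "neg2_reml": float(res.fun),
        }


# ---------------------------------------------------------------------------
# PQL outer loop
# ---------------------------------------------------------------------------

@dataclass
class FitControl:
    """Tolerances of the PQL outer loop and the inner REML optimizer."""

    tol: float = 1e-6
    max_iter: int = 50
    inner_maxiter: int = 200
    boundary_tol: float = 1e-3  # sigma below this (relative) flags a boundary fit
    compute_vc_cov: bool = True
    fix_rho: float | None = None  # hold the AR(1) parameter fixed (e.g. 0)


@dataclass
class FittedModel:
    """Result of the PQL fit: Table-1-style parameters plus covariances."""

    params: pd.Series
    cov_fixed: np.ndarray
    sigma1: float
    sigma2: float
    rho: float
    dispersion: float                 # quasi-dispersion phi (working-scale REML)
    pearson_dispersion: float
    sigma1_ci: tuple[float, float]
    sigma2_ci: tuple[float, float]
    rho_ci: tuple[float, float]
    var_log_sigma1: float
    var_log_sigma2: float
    b_hospital: dict[str, float]
    b_unit: dict[str, float]
    converged: bool
    n_iter: int
    trace: list[float]
    boundary: dict[str, bool]
    internal_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]
    year_origin: float
    n_obs: int
    fitted_eta: np.ndarray = field(repr=False, default=None)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_fixed)), index=self.params.index)

    def wald_table(self) -> pd.DataFrame:
        se = self.se
        z = self.params / se
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": se,
                "z": z,
                "p_value": 2.0 * stats.norm.sf(np.abs(z)),
            }
        )

    def to_dict(self) -> dict:
        return {
            "fixed_effects": {k: float(v) for k, v in self.params.items()},
            "fixed_effects_se": {k: float(v) for k, v in self.se.items()},
            "cov_fixed": np.asarray(self.cov_fixed).tolist(),
            "sigma1": self.sigma1,
            "sigma2": self.sigma2,
            "rho": self.rho,
            "dispersion": self.dispersion,
            "pearson_dispersion": self.pearson_dispersion,
            "sigma1_ci": list(self.sigma1_ci),
            "sigma2_ci": list(self.sigma2_ci),
            "rho_ci": list(self.rho_ci),
            "var_log_sigma1": self.var_log_sigma1,
            "var_log_sigma2": self.var_log_sigma2,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "trace": [float(x) for x in self.trace],
            "boundary": {k: bool(v) for k, v in self.boundary.items()},
            "internal_knots": list(self.internal_knots),
            "boundary_knots": list(self.boundary_knots),
            "year_origin": self.year_origin,
            "n_obs": self.n_obs,
        }


def _check_grouping(design: DesignData) -> None:
    hospitals = pd.unique(design.hospital)
    if len(hospitals) < 2:
        raise ConvergenceError(
            "at least 2 hospitals are required: the hospital variance "
            "sigma1 is not identifiable from a single hospital"
        )
    for h in hospitals:
        if len(pd.unique(design.unit[design.hospital == h])) < 2:
            raise ConvergenceError(
                f"hospital {h!r} contributes fewer than 2 sex-age units; "
                "sigma2 is not identifiable"
            )


def fit_pql(design: DesignData, control: FitControl | None = None) -> FittedModel:
    """Fit the quasi-Poisson GLMM by penalized quasi-likelihood.

    Alternates (a) linearization of the Poisson log-link around the current
    conditional mean (working response z and weights mu) with (b) a REML fit
    of the weighted LMM with hospital and unit random intercepts and AR(1)
    within-unit correlation, until the fixed effects stabilize.
    """
    control = control or FitControl()
    _check_grouping(design)
    y, off, X = design.y, design.offset, design.X

    mu = np.maximum(y, 0.5) + 0.1
    eta = np.log(mu)
    beta_old = None
    theta = np.array([np.log(0.2), np.log(0.1), 0.2])  # cold start
    trace: list[float] = []
    fit = None
    lmm = None
    for it in range(1, control.max_iter + 1):
        w = mu.copy()
        z = eta - off + (y - mu) / mu
        lmm = _WorkingLMM(design, z, w)
        fit = lmm.fit(theta, maxiter=control.inner_maxiter, fix_rho=control.fix_rho)
        theta = fit["theta"]  # warm start the next outer iteration
        beta = fit["beta"]
        eta = (
            off
            + X @ beta
            + np.array([fit["b_hosp"][h] for h in design.hospital])
            + np.array([fit["b_unit"][u] for u in design.unit])
        )
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        if beta_old is not None:
            delta = float(np.max(np.abs(beta - beta_old)))
            trace.append(delta)
            if delta < control.tol:
                break
        beta_old = beta
    else:
        raise ConvergenceError(
            f"PQL did not converge in {control.max_iter} iterations "
            f"(last max |dbeta| = {trace[-1]:.3g})",
            trace=trace,
        )

    phi = float(fit["sigma_e2"])
    pearson = float(np.sum((y - mu) ** 2 / mu) / (design.n - design.p))
    sigma1, sigma2, rho = fit["sigma1"], fit["sigma2"], fit["rho"]

    boundary = {
        "sigma1": sigma1 < control.boundary_tol * np.sqrt(phi),
        "sigma2": sigma2 < control.boundary_tol * np.sqrt(phi),
    }
    if any(boundary.values()):
        warnings.warn(
            f"variance component(s) at the boundary: "
            f"{[k for k, v in boundary.items() if v]}",
            stacklevel=2,
        )

    # variance-component uncertainty from the unprofiled REML Hessian in
    # (log sigma1, log sigma2, atanh rho, log sigma_e)
    z95 = 1.959964
    var_ls1 = var_ls2 = var_psi = np.nan
    if control.compute_vc_cov and control.fix_rho is None and not any(boundary.values()):
        theta4 = np.array(
            [np.log(sigma1), np.log(sigma2), np.arctanh(rho), 0.5 * np.log(phi)]
        )
        H = _numeric_hessian(lmm.neg2_reml_full, theta4)
        try:
            cov_theta4 = 2.0 * np.linalg.inv(H)
            d = np.diag(cov_theta4)
            if np.all(d[:3] > 0):
                var_ls1, var_ls2, var_psi = d[0], d[1], d[2]
        except np.linalg.LinAlgError:
            pass
    if np.isfinite(var_ls1):
        sigma1_ci = (sigma1 * np.exp(-z95 * np.sqrt(var_ls1)),
                     sigma1 * np.exp(z95 * np.sqrt(var_ls1)))
        sigma2_ci = (sigma2 * np.exp(-z95 * np.sqrt(var_ls2)),
                     sigma2 * np.exp(z95 * np.sqrt(var_ls2)))
        psi = np.arctanh(rho)
        rho_ci = (float(np.tanh(psi - z95 * np.sqrt(var_psi))),
                  float(np.tanh(psi + z95 * np.sqrt(var_psi))))
    else:
        sigma1_ci = sigma2_ci = rho_ci = (np.nan, np.nan)

    return FittedModel(
        params=pd.Series(fit["beta"], index=list(design.columns)),
        cov_fixed=fit["cov_beta"],
        sigma1=sigma1,
        sigma2=sigma2,
        rho=rho,
        dispersion=phi,
        pearson_dispersion=pearson,
        sigma1_ci=sigma1_ci,
        sigma2_ci=sigma2_ci,
        rho_ci=rho_ci,
        var_log_sigma1=float(var_ls1),
        var_log_sigma2=float(var_ls2),
        b_hospital=fit["b_hosp"],
        b_unit=fit["b_unit"],
        converged=True,
        n_iter=it,
        trace=trace,
        boundary=boundary,
        internal_knots=design.basis.internal_knots,
        boundary_knots=design.basis.boundary_knots,
        year_origin=design.year_origin,
        n_obs=design.n,
        fitted_eta=eta,
    )


def _numeric_hessian(f, x0, h=1e-4):
    k = len(x0)
    H = np.empty((k, k))
    f0 = f(x0)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            if i == j:
                H[i, i] = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (
                    f(x0 + ei + ej) - f(x0 + ei - ej)
                    - f(x0 - ei + ej) + f(x0 - ei - ej)
                ) / (4 * h**2)
    return H


# ---------------------------------------------------------------------------
# time-trend contrast assessment
# ---------------------------------------------------------------------------

def _orthogonal_poly_contrasts(levels: np.ndarray) -> np.ndarray:
    """Orthonormal polynomial contrast matrix over ordered factor levels."""
    x = np.asarray(levels, dtype=float)
    T = len(x)
    V = np.vander(x - x.mean(), N=T, increasing=True)
    Q, R = np.linalg.qr(V)
    Q = Q * np.sign(np.diag(R))  # fix signs so the linear column increases
    return Q[:, 1:]  # drop the constant column


def assess_time_effect(design: DesignData, control: FitControl | None = None) -> pd.DataFrame:
    """Wald tests of orthogonal-polynomial time contrasts up to degree T-1.

    Refits the PQL model with calendar year entered as an ordered factor
    under orthonormal polynomial contrasts.  Returns one row per polynomial
    degree with estimate, se, z and p-value, plus a ``retained`` flag: the
    linear trend is kept regardless (adjustment for secular trend), higher
    degrees only when significant at 5%.
    """
    years = np.unique(design.year)
    if len(years) < 3:
        raise ValueError(f"need at least 3 distinct years, got {len(years)}")
    contrasts = _orthogonal_poly_contrasts(years)
    level_of = {yr: i for i, yr in enumerate(years)}
    P = contrasts[[level_of[yr] for yr in design.year], :]

    X_base = np.delete(design.X, 2, axis=1)  # drop the linear-year column
    X = np.column_stack([X_base[:, :2], P, X_base[:, 2:]])
    names = (
        list(FIXED_EFFECT_NAMES[:2])
        + [f"year_poly{d}" for d in range(1, len(years))]
        + list(FIXED_EFFECT_NAMES[3:])
    )
    design_poly = DesignData(
        y=design.y, offset=design.offset, X=X, columns=tuple(names),
        hospital=design.hospital, unit=design.unit, year=design.year,
        basis=design.basis, year_origin=design.year_origin, frame=design.frame,
    )
    ctl = control or FitControl()
    ctl = FitControl(tol=ctl.tol, max_iter=ctl.max_iter,
                     inner_maxiter=ctl.inner_maxiter, compute_vc_cov=False)
    fit = fit_pql(design_poly, ctl)
    rows = []
    for d in range(1, len(years)):
        name = f"year_poly{d}"
        est = float(fit.params[name])
        se = float(fit.se[name])
        z = est / se
        p = float(2.0 * stats.norm.sf(abs(z)))
        rows.append(
            {"degree": d, "estimate": est, "se": se, "z": z, "p_value": p,
             "retained": d == 1 or p < 0.05}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def _qq_frame(values: np.ndarray) -> pd.DataFrame:
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    return pd.DataFrame({"theoretical": theo, "sample": v})


def model_diagnostics(fit: FittedModel, design: DesignData) -> dict:
    """Plot-ready diagnostic tables for the fitted model.

    Returns a dict with: ``ratio`` (observed vs fitted I/S ratio),
    ``residuals`` (Pearson residuals vs fitted means), ``acf`` (residual
    autocorrelation by lag within sex-age units), ``qq_hospital`` /
    ``qq_unit`` / ``qq_residuals`` (normal-quantile data), and
    ``by_hospital`` (per-hospital residual five-number summaries with the
    predicted random intercept).
    """
    mu = np.exp(fit.fitted_eta)
    y = design.y
    S = np.exp(design.offset)
    pearson = (y - mu) / np.sqrt(fit.dispersion * mu)

    ratio = pd.DataFrame(
        {
            "hospital_id": design.hospital,
            "sex": design.frame["sex"].to_numpy(),
            "age_cat": design.frame["age_cat"].to_numpy(),
            "year": design.frame["year"].to_numpy(),
            "observed_ratio": y / S,
            "fitted_ratio": mu / S,
        }
    )
    residuals = pd.DataFrame(
        {"fitted": mu, "pearson_residual": pearson, "hospital_id": design.hospital}
    )

    # pooled within-unit ACF of Pearson residuals over year lags
    max_lag = int(np.ptp(design.year))
    acf_rows = []
    var0 = float(np.mean(pearson**2))
    for lag in range(0, max_lag + 1):
        prods, npairs = 0.0, 0
        for u in pd.unique(design.unit):
            uidx = np.flatnonzero(design.unit == u)
            uidx = uidx[np.argsort(design.year[uidx])]
            yrs = design.year[uidx]
            for a in range(len(uidx)):
                b = np.flatnonzero(yrs == yrs[a] + lag)
                for bb in b:
                    prods += pearson[uidx[a]] * pearson[uidx[bb]]
                    npairs += 1
        acf_rows.append(
            {"lag": lag, "acf": prods / (npairs * var0) if npairs else np.nan,
             "n_pairs": npairs}
        )
    acf = pd.DataFrame(acf_rows)

    by_h = []
    for h in pd.unique(design.hospital):
        r = pearson[design.hospital == h]
        by_h.append(
            {
                "hospital_id": h,
                "n": len(r),
                "min": float(r.min()),
                "q1": float(np.quantile(r, 0.25)),
                "median": float(np.median(r)),
                "q3": float(np.quantile(r, 0.75)),
                "max": float(r.max()),
                "random_intercept": fit.b_hospital[h],
            }
        )

    return {
        "ratio": ratio,
        "residuals": residuals,
        "acf": acf,
        "qq_hospital": _qq_frame(np.array(list(fit.b_hospital.values()))),
        "qq_unit": _qq_frame(np.array(list(fit.b_unit.values()))),
        "qq_residuals": _qq_frame(pearson),
        "by_hospital": pd.DataFrame(by_h),
    }
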