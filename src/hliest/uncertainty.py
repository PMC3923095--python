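"""Delta-method uncertainty for the extrapolated totals and rates.

Every reported aggregate is a linear combination sum_ij c_ij * I_hat_ij(t) of
stratum totals I_hat = exp(x'beta + sigma1^2/2 + sigma2^2/2) * S_national.
Writing the augmented parameter vector theta = (beta, sigma1^2, sigma2^2)
and the extended regressor row X = (x, 1/2, 1/2), the gradient of the
aggregate with respect to theta_m is sum_ij X_ijm * c_ij * I_hat_ij(t), and
the first-order (delta-method) variance is the quadratic form of that
gradient in V(theta).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import FittedModel

__all__ = [
    "Z95",
    "AugmentedCov",
    "assemble_cov",
    "extend_rows",
    "delta_gradient",
    "delta_var_total",
    "wald_ci",
    "rate_ratio",
]

Z95 = 1.959964  # two-sided 95% normal quantile

_PSD_WARN_TOL = 1e-8
_PSD_HARD_TOL = 1e-3


@dataclass(frozen=True)
class AugmentedCov:
    """Covariance of (beta_0..gamma_2, sigma1^2, sigma2^2), 9 x 9."""

    V: np.ndarray
    names: tuple[str, ...]

    @property
    def dim(self) -> int:
        return self.V.shape[0]


def _project_psd(V: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(V)
    worst = vals.min()
    scale = max(vals.max(), 1.0)
    if worst < -_PSD_HARD_TOL * scale:
        raise np.linalg.LinAlgError(
            f"assembled parameter covariance is far from PSD (min eig {worst:.3g})"
        )
    if worst < 0:
        if worst < -_PSD_WARN_TOL * scale:
            warnings.warn(
                f"projecting parameter covariance to PSD (min eig {worst:.3g})",
                stacklevel=3,
            )
        V = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
    return 0.5 * (V + V.T)


def assemble_cov(fit: FittedModel, inflate_dispersion: bool = True) -> AugmentedCov:
    """Build V(theta) for theta = (fixed effects, sigma1^2, sigma2^2).

    The fixed-effect block comes from the final weighted working fit and is
    already scaled by the quasi-dispersion phi; ``inflate_dispersion=False``
    removes that inflation.  The variance-component block is transformed
    from the log-sigma scale (where the REML Hessian is computed) to the
    sigma^2 scale by the univariate delta method: Var(sigma^2) = (2 sigma^2)^2
    Var(log sigma).  The cross block is set to zero (REML orthogonality
    approximation).
    """
    p = len(fit.params)
    V = np.zeros((p + 2, p + 2))
    block = np.asarray(fit.cov_fixed, dtype=float)
    if not inflate_dispersion:
        block = block / fit.dispersion
    V[:p, :p] = block
    for i, (sigma, var_log) in enumerate(
        [(fit.sigma1, fit.var_log_sigma1), (fit.sigma2, fit.var_log_sigma2)]
    ):
        if np.isfinite(var_log):
            V[p + i, p + i] = (2.0 * sigma**2) ** 2 * var_log
        else:
            # boundary fit: no usable curvature; treat the component as fixed
            V[p + i, p + i] = 0.0
    V = _project_psd(V)
    return AugmentedCov(V=V, names=tuple(fit.params.index) + ("sigma1_sq", "sigma2_sq"))


def extend_rows(X: np.ndarray) -> np.ndarray:
    """Append the (1/2, 1/2) variance-component slots to regressor rows."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    half = np.full((X.shape[0], 2), 0.5)
    return np.hstack([X, half])


def delta_gradient(X_ext: np.ndarray, totals: np.ndarray, weights=None) -> np.ndarray:
    """Gradient of sum c_ij * I_hat_ij w.r.t. the augmented parameters.

    ``weights`` are the combination coefficients c_ij (1 for a plain total,
    1000 * standardization weight / population for a rate); default 1.
    """
    X_ext = np.atleast_2d(X_ext)
    totals = np.asarray(totals, dtype=float)
    c = np.ones_like(totals) if weights is None else np.asarray(weights, dtype=float)
    if X_ext.shape[0] != len(totals) or len(c) != len(totals):
        raise ValueError(
            f"dimension mismatch: {X_ext.shape[0]} rows, {len(totals)} totals, "
            f"{len(c)} weights"
        )
    return X_ext.T @ (c * totals)


def delta_var_total(
    aug: AugmentedCov, X_ext: np.ndarray, totals: np.ndarray, weights=None
) -> float:
    """Delta-method variance of a linear combination of stratum totals."""
    g = delta_gradient(X_ext, totals, weights)
    if len(g) != aug.dim:
        raise ValueError(f"gradient length {len(g)} != covariance dim {aug.dim}")
    return float(g @ aug.V @ g)


def wald_ci(
    estimate: float,
    variance: float,
    level: float = 0.95,
    floor_zero: bool = True,
) -> tuple[float, float]:
    """Symmetric normal-theory interval, floored at 0 for counts and rates."""
    if variance < 0:
        raise ValueError(f"negative variance {variance!r}")
    from scipy import stats

    z = Z95 if level == 0.95 else float(stats.norm.ppf(0.5 + level / 2.0))
    half = z * np.sqrt(variance)
    lo, hi = estimate - half, estimate + half
    if floor_zero:
        lo = max(lo, 0.0)
    return (float(lo), float(hi))


def rate_ratio(
    rate_men: float,
    rate_women: float,
    aug: AugmentedCov,
    grad_men: np.ndarray,
    grad_women: np.ndarray,
    level: float = 0.95,
) -> dict:
    """Men/women standardized-rate ratio with a log-scale delta-method CI.

    Both rates are functions of the same parameter vector, so their
    covariance is carried through the shared V(theta):
    Var(log ratio) = g' V g with g = grad_men/rate_men - grad_women/rate_women.
    """
    if rate_women <= 0 or rate_men <= 0:
        raise ValueError("rates must be strictly positive for a ratio")
    ratio = rate_men / rate_women
    g = np.asarray(grad_men, dtype=float) / rate_men - np.asarray(
        grad_women, dtype=float
    ) / rate_women
    var_log = float(g @ aug.V @ g)
    if var_log < 0:
        var_log = 0.0
    from scipy import stats

    z = Z95 if level == 0.95 else float(stats.norm.ppf(0.5 + level / 2.0))
    half = z * np.sqrt(var_log)
    return {
        "ratio": float(ratio),
        "var_log": var_log,
        "ci_low": float(ratio * np.exp(-half)),
        "ci_high": float(ratio * np.exp(half)),
    }
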