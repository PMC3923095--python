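# Methods

## Problem and estimator

A small sentinel network of hospital emergency departments (EDs) records,
exhaustively, the home-and-leisure injuries (HLIs) it treats.  The goal is a
national yearly number and incidence rate of ED-treated HLIs in adults
(15+), with honest confidence intervals, although the network covers only a
few percent of the population.  The bridge to the national level is an
auxiliary variable observed both in the network and nationwide: the number
of injury-related hospital stays in the discharge database (principal or
associated ICD-10 diagnosis in S00–T98; an extended code set is also
implemented and the choice between the two is made by the log–log Pearson
correlation between HLI counts and stay counts across strata).

The estimator is a *separate ratio estimator*: for sex i, 5-year age band j
(15–19, …, 85+), year t,

    I_hat_ij.(t) = alpha_hat_ij.(t) * S_ij.(t),

where S_ij.(t) is the known national stay total and alpha_hat the modelled
ratio of HLIs to stays.  National totals are sums of stratum totals; rates
divide by census person-years (per 1,000); standardized rates use the
European Standard Population (1976) truncated to ages 15+ and renormalized
(weights 7/78, …, 1/78).

## The ratio model

Counts in hospital k are conditionally Poisson with log link and offset:

    log mu_ijk(t) = log S_ijk(t) + beta0 + alpha_i + delta (t - 2006)
                    + beta1 B1(a_j) + beta2 B2(a_j)
                    + (beta3 + gamma_i) B3(a_j) + b_k + b_ijk,

* B1..B3: natural cubic spline (3 df) in the age-band center a_j (17.5,
  22.5, …, 87.5), internal knots at 40 and 64 years, boundary knots at the
  extreme centers 17.5 and 87.5.  The basis reproduces R's `splines::ns`
  exactly (B-spline design, leading column dropped, null-space projection of
  the boundary second-derivative constraints).
* Men are the reference sex (alpha_1 = gamma_1 = 0); the sex-by-age
  interaction enters only through the third basis column, i.e. the
  male/female ratio profiles may diverge above the second internal knot.
* b_k ~ N(0, sigma1^2): hospital intercept; b_ijk ~ N(0, sigma2^2):
  sex-age-unit-within-hospital intercept; repeated yearly observations
  within a unit carry AR(1) correlation rho (on the year gaps, so
  unbalanced panels are handled).
* Year enters linearly, centered at 2006.  `assess_time_effect` refits with
  year as an ordered factor under orthonormal polynomial contrasts (up to
  degree #years − 1) and Wald-tests each degree; the linear trend is
  retained regardless as a secular-trend adjustment, higher degrees only
  when significant at 5%.

### Estimation: penalized quasi-likelihood

PQL alternates (a) linearization of the log link around the current
conditional mean — working response z = eta − offset + (y − mu)/mu, weights
mu — with (b) a REML fit of the weighted linear mixed model with the two
nested intercepts and AR(1) within-unit residual correlation.  The inner
covariance is parameterized as

    V = sigma_e^2 [ g1^2 J_hospital + g2^2 J_unit + D^{1/2} R(rho) D^{1/2} ],

D = diag(1/mu); sigma_e^2 is profiled out and *is* the quasi-Poisson
dispersion phi (for a log-Poisson model Var(z | b) = phi / mu).  The
fixed-effect covariance from the final weighted fit is therefore already
dispersion-inflated; `assemble_cov(..., inflate_dispersion=False)` removes
the inflation.  Free parameters (log g1, log g2, atanh rho) are optimized by
Nelder–Mead per outer iteration with warm starts; outer convergence is
max |change in beta| < 1e-6, at most 50 iterations (hard error beyond).  A
Pearson-residual dispersion on the response scale is reported alongside.
Variance-component uncertainty comes from the numerical Hessian of the
unprofiled REML criterion in (log sigma1, log sigma2, atanh rho,
log sigma_e); CIs are Wald on the transformed scale, back-transformed —
which is why they are asymmetric about the point estimates.

Degenerate inputs: rows with zero stays are dropped with a warning (log
offset undefined; a stratum with no stays contributes nothing to the
ratio); a single hospital (sigma1 unidentifiable) is a hard error; a
variance component collapsing to ~0 is flagged as a boundary fit (warning,
CIs suppressed) rather than an error.

### Marginal ratio and delta-method uncertainty

Averaging the conditional ratio over both normal random intercepts gives
the lognormal-mean correction

    alpha_hat_ij.(t) = exp(x_ij(t)' beta + sigma1^2/2 + sigma2^2/2).

Every reported aggregate (totals by sex/overall, crude rates, standardized
rates, period summaries) is a linear combination sum c_ij I_hat_ij(t), so
one delta-method routine covers them all: with the augmented parameter
vector theta = (beta, sigma1^2, sigma2^2) and extended regressor rows
X = (x, 1/2, 1/2), the gradient is sum_ij X_ijm c_ij I_hat_ij(t) and
Var = g' V(theta) g.  V(theta) is block-diagonal: the (dispersion-inflated)
fixed-effect block, the variance components transformed from the log-sigma
scale by the univariate delta method, and a zero cross block (REML
orthogonality approximation; the bootstrap comparison below quantifies the
cost).  Count and rate CIs are symmetric Wald intervals floored at 0; the
men/women standardized-rate ratio CI is built on the log scale through the
shared parameter covariance (the two rates are functions of the same
parameters, so their covariance does not vanish).

Period (multi-year) summaries are unweighted means of yearly values; a
person-year-pooled variant is available (`period_pooling="pooled"`).  Both
are linear in the stratum totals, so period CIs come from the same delta
machinery, not from averaging yearly CIs.

## Synthetic-data generator

No microdata from either source system are publicly deposited, so the
package ships a first-class generator that emulates the published study:

* 8 hospitals, years 2004–2008, unbalanced participation (four hospitals
  all five years; the others 4, 3, 2 and 1 trailing years) — 900 strata.
* Generative parameters default to the published fits: beta0 = 1.59,
  alpha2 = .068, delta = .009, beta1 = −.680, beta2 = −1.37, beta3 = −.394,
  gamma2 = −.227, sigma1 = .27, sigma2 = .10, rho = .38.
* Level-1 noise is a stationary log-scale Gaussian AR(1) process per unit
  with marginal s.d. sigma_e.  The published analysis specifies AR(1) on
  working residuals, not a generative law; a log-scale process makes rho a
  recoverable quantity and induces overdispersion.  sigma_e has no
  published counterpart (the dispersion was not reported); the default 0.05
  targets phi ~ 2 at the network's typical fitted count (phi ~ 1 + mu
  sigma_e^2), a typical surveillance-count overdispersion.
* Baseline stays: hospital scales log-uniform over one order of magnitude
  (200 down to 20 expected stays per stratum-year), a mild log-quadratic
  age shape with minimum near 45, women +10%; stay counts are Poisson
  draws around the profile.  National totals are noise-free expected
  network stays scaled by the coverage factor 37 (≈ 2.7% network coverage)
  on the full grid — the national auxiliary is treated as a known constant,
  as the estimator assumes.  Populations follow a fixed mid-2000s French
  adult pyramid (~49 M, male share declining with age).

What a green synthetic test does *not* establish: the generator draws from
the same family the model fits (up to the level-1 variance shape, which is
constant on the log scale where the quasi-model assumes variance
proportional to the mean), so it validates the estimation machinery, not
model adequacy for real surveillance data; and the real selection of
hospitals is not random, so representativeness is out of reach by
construction — the leave-one-hospital-out check probes sensitivity, not
bias.

Fitted rho is attenuated relative to the generative rho: the model places
the AR(1) structure on the whole working residual, while only the
log-scale noise share sigma_e^2 / (sigma_e^2 + 1/mu) of it is serially
correlated.  With the default sigma_e this attenuation is substantial; rho
is a nuisance parameter for the estimand, and fixed-effect recovery and
coverage are unaffected (verified by the acceptance suite).

## Numerical choices

* z-quantile fixed at 1.959964 for all 95% intervals.
* PQL initialization mu = max(y, 0.5) + 0.1; eta clipped to ±30.
* Assembled covariances are projected to the nearest PSD matrix when
  eigenvalues dip below −1e−8 (relative), and rejected beyond −1e−3.
* Ties in the selection-algorithm choice go to the more restrictive
  (smaller) code set.
* ICD-10 membership is prefix-based after stripping dots, so subdivided
  codes inherit from their 3-character block.
* The open 85+ band's center is set to 87.5 (continuing the 5-year
  spacing); a test verifies fitted ratios barely move when the convention
  changes.
* Cross-validation reuses the full-sample knots and year origin for every
  reduced fit, keeping the estimand fixed across forest-plot rows.

## Known limitations

* PQL is first-order: fixed effects carry O(1/mu) bias (negligible at the
  count sizes simulated here) and Wald coverage with 8 hospitals leans on a
  normal approximation for beta0 whose effective sample size is the number
  of hospitals.
* The delta-method variance ignores fixed-effect/variance-component
  cross-covariance and the uncertainty of rho and phi.
* The lognormal correction assumes exactly normal random intercepts.
* Pediatric estimation is out of scope (the ratio is far more dispersed in
  children); predictions outside the fitted year range are flagged, not
  refused.
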