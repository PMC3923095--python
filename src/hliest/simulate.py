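"""Synthetic sentinel-network studies with known ground truth.

No public microdata exist for either the sentinel ED surveillance network or
the national hospital-discharge system, so every downstream stage is
exercised on simulated studies drawn from the same generative mechanism the
model assumes: conditionally Poisson HLI counts with a log link, an injury-
stay offset, fixed sex/age-spline/year effects, nested Gaussian random
intercepts (hospital, sex-age unit within hospital) and a stationary AR(1)
Gaussian process on the log scale for the yearly level-1 perturbations.

Defaults reproduce the published study design: 8 hospitals over 2004-2008
with unbalanced participation (four hospitals with all five years, the
others joining progressively: 4, 3, 2 and 1 years), 2 sexes x 15 five-year
age bands from 15-19 to 85+, and the published parameter estimates as the
generative truth.  The level-1 marginal s.d. ``sigma_e`` has no published
counterpart (the dispersion was not reported); the default 0.05 targets a
quasi-Poisson dispersion of about 2 at the network's typical count size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data_io import (
    N_AGE_BANDS,
    SEXES,
    StayRecord,
    european_standard_weights,
    validate_table,
)
from .model import (
    DEFAULT_BOUNDARY_KNOTS,
    DEFAULT_INTERNAL_KNOTS,
    DEFAULT_YEAR_ORIGIN,
    age_centers,
    natural_cubic_basis,
)

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_random_effects",
    "simulate_network",
    "simulate_stay_records",
    "config_from_fit",
]

#: Published GLMM estimates, used as the generative truth by default.
DEFAULT_FIXED_EFFECTS = {
    "intercept": 1.59,
    "sex_women": 0.068,
    "year_c": 0.009,
    "age_b1": -0.680,
    "age_b2": -1.37,
    "age_b3": -0.394,
    "sex_women:age_b3": -0.227,
}

# Adult population profile (both sexes, person-years) by 5-year band 15-19 ..
# 85+, shaped like the mid-2000s French metropolitan pyramid (~49 M adults),
# and the male share per band (declining at old ages).
_POPULATION_BOTH = np.array(
    [4.00, 4.00, 4.00, 4.20, 4.40, 4.30, 4.20, 4.20,
     4.20, 3.40, 2.80, 2.40, 2.30, 1.70, 1.30]
) * 1e6
_MALE_SHARE = np.array(
    [0.51, 0.51, 0.50, 0.50, 0.50, 0.50, 0.50, 0.49,
     0.49, 0.48, 0.47, 0.46, 0.44, 0.40, 0.30]
)


def _default_participation(n_hospitals: int, years: tuple[int, ...]) -> dict[str, tuple[int, ...]]:
    """4 fully observed hospitals, later entrants contribute trailing years."""
    out: dict[str, tuple[int, ...]] = {}
    for k in range(n_hospitals):
        name = f"H{k + 1}"
        if k < 4:
            out[name] = tuple(years)
        else:
            start = min(k - 3, len(years) - 1)
            out[name] = tuple(years[start:])
    return out


@dataclass
class SimulationConfig:
    """Generative truth and study design of one synthetic network."""

    n_hospitals: int = 8
    years: tuple[int, ...] = (2004, 2005, 2006, 2007, 2008)
    participation: dict[str, tuple[int, ...]] | None = None
    fixed_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FIXED_EFFECTS)
    )
    sigma1: float = 0.27          # hospital intercept s.d.
    sigma2: float = 0.10          # sex-age-unit-within-hospital s.d.
    rho: float = 0.38             # AR(1) lag-1 correlation of level-1 noise
    sigma_e: float = 0.05         # marginal s.d. of the log-scale AR(1) noise
    internal_knots: tuple[float, ...] = DEFAULT_INTERNAL_KNOTS
    boundary_knots: tuple[float, float] = DEFAULT_BOUNDARY_KNOTS
    year_origin: float = DEFAULT_YEAR_ORIGIN
    # baseline expected injury-stay profile: hospital sizes log-uniform over
    # one order of magnitude, log-quadratic age shape, small sex offset
    size_max: float = 200.0
    size_min: float = 20.0
    age_curvature: float = 0.0005
    age_center: float = 45.0
    sex_offset: float = 0.10      # women have slightly more injury stays
    national_scale: float = 37.0  # national stays / expected network stays
    population_both: np.ndarray = field(
        default_factory=lambda: _POPULATION_BOTH.copy()
    )
    male_share: np.ndarray = field(default_factory=lambda: _MALE_SHARE.copy())

    def __post_init__(self) -> None:
        if self.sigma1 < 0 or self.sigma2 < 0 or self.sigma_e < 0:
            raise ValueError("variance components must be non-negative")
        if not abs(self.rho) < 1:
            raise ValueError(f"|rho| must be < 1, got {self.rho}")
        if self.national_scale < 1:
            raise ValueError("national-to-network scale factor must be >= 1")
        if self.participation is None:
            self.participation = _default_participation(self.n_hospitals, self.years)
        extra = set(self.fixed_effects) - set(DEFAULT_FIXED_EFFECTS)
        if extra:
            raise ValueError(f"unknown fixed effects {sorted(extra)}")

    @property
    def hospital_ids(self) -> tuple[str, ...]:
        return tuple(self.participation)

    def hospital_sizes(self) -> np.ndarray:
        """Baseline stay scale per hospital, log-uniformly spaced."""
        return np.geomspace(self.size_max, self.size_min, self.n_hospitals)

    def expected_stays(self) -> pd.DataFrame:
        """Noise-free expected yearly injury stays per hospital/sex/age."""
        sizes = self.hospital_sizes()
        a = age_centers(np.arange(1, N_AGE_BANDS + 1))
        age_shape = np.exp(self.age_curvature * (a - self.age_center) ** 2)
        rows = []
        for k, h in enumerate(self.hospital_ids):
            for sex in SEXES:
                sex_f = np.exp(self.sex_offset) if sex == 2 else 1.0
                for j in range(1, N_AGE_BANDS + 1):
                    rows.append(
                        (h, sex, j, sizes[k] * age_shape[j - 1] * sex_f)
                    )
        return pd.DataFrame(
            rows, columns=["hospital_id", "sex", "age_cat", "expected_stays"]
        )

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["population_both"] = list(map(float, d["population_both"]))
        d["male_share"] = list(map(float, d["male_share"]))
        d["participation"] = {h: list(ys) for h, ys in d["participation"].items()}
        return d


@dataclass
class SyntheticDataset:
    """One complete simulated study with its generative ground truth."""

    counts: pd.DataFrame       # sentinel strata counts (strata_counts schema)
    national: pd.DataFrame     # national auxiliary stays (national_stays schema)
    population: pd.DataFrame   # person-years (population schema)
    weights: pd.DataFrame      # standardization weights (standard_weights schema)
    truth: dict                # parameters exactly as used
    b_hospital: dict[str, float]
    b_unit: dict[str, float]
    e_series: dict[str, np.ndarray]

    def write(self, outdir) -> None:
        from pathlib import Path
        from .data_io import write_table

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(self.counts, out / "strata_counts.csv", "strata_counts")
        write_table(self.national, out / "national_stays.csv", "national_stays")
        write_table(self.population, out / "population.csv", "population")
        write_table(self.weights, out / "standard_weights.csv", "standard_weights")
        (out / "ground_truth.json").write_text(json.dumps(self.truth, indent=2))


def simulate_random_effects(config: SimulationConfig, seed) -> tuple[dict, dict, dict]:
    """Draw the hospital and unit intercepts and the level-1 AR(1) series.

    Returns ``(b_hospital, b_unit, e_series)``: b_k ~ N(0, sigma1^2) per
    hospital, b_ijk ~ N(0, sigma2^2) per sex-age unit within hospital, and a
    stationary Gaussian AR(1) series with marginal s.d. sigma_e and lag-1
    correlation rho over each unit's participation years.
    """
    rng = np.random.default_rng(seed)
    b_hosp = {
        h: float(rng.normal(0.0, config.sigma1)) for h in config.hospital_ids
    }
    b_unit: dict[str, float] = {}
    e_series: dict[str, np.ndarray] = {}
    rho, se = config.rho, config.sigma_e
    for h in config.hospital_ids:
        years = config.participation[h]
        for sex in SEXES:
            for j in range(1, N_AGE_BANDS + 1):
                u = f"{h}/s{sex}a{j}"
                b_unit[u] = float(rng.normal(0.0, config.sigma2))
                e = np.empty(len(years))
                if se == 0.0:
                    e[:] = 0.0
                else:
                    e[0] = rng.normal(0.0, se)
                    for t in range(1, len(years)):
                        gap = years[t] - years[t - 1]
                        r = rho**gap
                        e[t] = r * e[t - 1] + rng.normal(
                            0.0, se * np.sqrt(1.0 - r * r)
                        )
                e_series[u] = e
    return b_hosp, b_unit, e_series


def simulate_network(config: SimulationConfig | None = None, seed=0) -> SyntheticDataset:
    """Simulate one complete study from the generative mechanism.

    Stay counts are Poisson draws around the baseline profile; HLI counts are
    Poisson with mean S * exp(fixed predictor + b_k + b_ijk + e_t); national
    auxiliary totals are the noise-free expected network stays scaled up by
    the coverage factor on the full sex x age x year grid; populations follow
    the configured pyramid.  Bit-reproducible for a given seed.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    b_hosp, b_unit, e_series = simulate_random_effects(
        config, rng.integers(2**31 - 1)
    )

    basis = natural_cubic_basis(config.internal_knots, config.boundary_knots)
    a = age_centers(np.arange(1, N_AGE_BANDS + 1))
    B = basis(a)
    fe = config.fixed_effects
    expected = config.expected_stays().set_index(
        ["hospital_id", "sex", "age_cat"]
    )["expected_stays"]

    rows = []
    for h in config.hospital_ids:
        for sex in SEXES:
            for j in range(1, N_AGE_BANDS + 1):
                u = f"{h}/s{sex}a{j}"
                women = 1.0 if sex == 2 else 0.0
                xb = (
                    fe["intercept"]
                    + fe["sex_women"] * women
                    + fe["age_b1"] * B[j - 1, 0]
                    + fe["age_b2"] * B[j - 1, 1]
                    + (fe["age_b3"] + fe["sex_women:age_b3"] * women) * B[j - 1, 2]
                )
                m = expected.loc[(h, sex, j)]
                for ti, year in enumerate(config.participation[h]):
                    S = int(rng.poisson(m))
                    eta_ratio = (
                        xb
                        + fe["year_c"] * (year - config.year_origin)
                        + b_hosp[h]
                        + b_unit[u]
                        + e_series[u][ti]
                    )
                    with np.errstate(over="ignore"):
                        mu = S * np.exp(eta_ratio)
                    if not np.isfinite(mu):
                        raise FloatingPointError(
                            f"non-finite conditional mean in stratum "
                            f"({h}, sex={sex}, age_cat={j}, year={year})"
                        )
                    I = int(rng.poisson(mu)) if S > 0 else 0
                    rows.append((h, sex, j, year, I, S))
    counts = validate_table(
        pd.DataFrame(
            rows,
            columns=["hospital_id", "sex", "age_cat", "year", "hli_count", "stay_count"],
        ),
        "strata_counts",
    )

    # national auxiliary totals: scale x expected network stays, noise-free,
    # on the full grid (all hospitals treated as if participating every year)
    per_stratum = expected.groupby(["sex", "age_cat"]).sum()
    nat_rows = []
    pop_rows = []
    for year in config.years:
        for sex in SEXES:
            for j in range(1, N_AGE_BANDS + 1):
                nat = config.national_scale * per_stratum.loc[(sex, j)]
                nat_rows.append((sex, j, year, int(round(nat))))
                share = config.male_share[j - 1]
                pop = config.population_both[j - 1] * (
                    share if sex == 1 else 1.0 - share
                )
                pop_rows.append((sex, j, year, pop))
    national = validate_table(
        pd.DataFrame(
            nat_rows, columns=["sex", "age_cat", "year", "national_stay_count"]
        ),
        "national_stays",
    )
    population = validate_table(
        pd.DataFrame(pop_rows, columns=["sex", "age_cat", "year", "population"]),
        "population",
    )

    truth = {
        "fixed_effects": dict(fe),
        "sigma1": config.sigma1,
        "sigma2": config.sigma2,
        "rho": config.rho,
        "sigma_e": config.sigma_e,
        "year_origin": config.year_origin,
        "internal_knots": list(config.internal_knots),
        "boundary_knots": list(config.boundary_knots),
        "national_scale": config.national_scale,
        "seed": int(seed) if np.isscalar(seed) else None,
    }
    return SyntheticDataset(
        counts=counts,
        national=national,
        population=population,
        weights=european_standard_weights(),
        truth=truth,
        b_hospital=b_hosp,
        b_unit=b_unit,
        e_series=e_series,
    )


def config_from_fit(fit, template: SimulationConfig | None = None) -> SimulationConfig:
    """Generative configuration matching a fitted model (parametric bootstrap).

    Copies the fitted fixed effects, variance components and AR(1)
    correlation into a :class:`SimulationConfig`; the level-1 marginal s.d.
    is backed out of the quasi-dispersion via the small-noise relation
    phi ~ 1 + mu * sigma_e^2 at the mean fitted count.  Design fields
    (hospitals, participation, stay profile, populations) come from
    ``template``.
    """
    template = template or SimulationConfig()
    mu_bar = float(np.mean(np.exp(fit.fitted_eta)))
    sigma_e = float(np.sqrt(max(0.0, (fit.dispersion - 1.0) / mu_bar)))
    cfg = SimulationConfig(
        n_hospitals=template.n_hospitals,
        years=template.years,
        participation=dict(template.participation),
        fixed_effects={k: float(v) for k, v in fit.params.items()},
        sigma1=fit.sigma1,
        sigma2=fit.sigma2,
        rho=fit.rho,
        sigma_e=sigma_e,
        internal_knots=tuple(fit.internal_knots),
        boundary_knots=tuple(fit.boundary_knots),
        year_origin=fit.year_origin,
        size_max=template.size_max,
        size_min=template.size_min,
        age_curvature=template.age_curvature,
        age_center=template.age_center,
        sex_offset=template.sex_offset,
        national_scale=template.national_scale,
        population_both=template.population_both.copy(),
        male_share=template.male_share.copy(),
    )
    return cfg


# algorithm-1 blocks used for generated principal diagnoses; a handful of
# common chapter-19 injury codes is enough for counting purposes
_ALGO1_CODES = ("S060", "S525", "S720", "S934", "T140", "T179", "S010", "T98")
_ALGO2_ONLY_CODES = ("H264", "H059", "J689", "L550", "H720", "J700", "L589")
_NONQUALIFYING_CODES = ("Z000", "I109", "K297", "M545")


def simulate_stay_records(
    prescribed: pd.DataFrame,
    seed=0,
    frac_algorithm2_only: float = 0.0,
    frac_nonqualifying: float = 0.0,
) -> list[StayRecord]:
    """Emit line-level stay records realizing prescribed algorithm-1 counts.

    ``prescribed`` needs columns (hospital_id, sex, age_cat, year,
    stay_count).  Exactly ``stay_count`` records per stratum carry a
    chapter-19 code; on top of those, a fraction carries only the extended
    (algorithm-2-specific) codes and a fraction only non-qualifying codes,
    so the two selection algorithms disagree by a constructed margin.
    """
    if (prescribed["stay_count"] < 0).any():
        raise ValueError("prescribed stay counts must be non-negative")
    if frac_algorithm2_only < 0 or frac_nonqualifying < 0:
        raise ValueError("fractions must be non-negative")
    rng = np.random.default_rng(seed)
    records: list[StayRecord] = []
    for row in prescribed.itertuples(index=False):
        j = int(row.age_cat)
        lo = 15 + 5 * (j - 1)
        hi = lo + 5 if j < N_AGE_BANDS else 95
        n1 = int(row.stay_count)
        n2 = int(round(frac_algorithm2_only * n1))
        n0 = int(round(frac_nonqualifying * n1))
        for pool, n in (
            (_ALGO1_CODES, n1),
            (_ALGO2_ONLY_CODES, n2),
            (_NONQUALIFYING_CODES, n0),
        ):
            for _ in range(n):
                codes = [str(rng.choice(pool))]
                if rng.random() < 0.3:  # occasional associated diagnosis
                    codes.append(str(rng.choice(_NONQUALIFYING_CODES)))
                records.append(
                    StayRecord(
                        hospital_id=str(row.hospital_id),
                        sex=int(row.sex),
                        age=float(rng.uniform(lo, hi)),
                        year=int(row.year),
                        diagnosis_codes=tuple(codes),
                    )
                )
    return records
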