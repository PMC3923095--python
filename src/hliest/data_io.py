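"""Tabular input/output and auxiliary-stay selection.

The pipeline consumes four delimited-text tables:

* sentinel strata counts -- injury visits (HLIs) and injury-related hospital
  stays per (hospital, sex, 5-year age band, year) in the surveillance network;
* national auxiliary stay totals per (sex, age band, year);
* population person-years per (sex, age band, year);
* direct-standardization weights per age band.

All tables are plain CSV with a header, UTF-8, "." decimal separator, and are
held in memory as :class:`pandas.DataFrame` objects validated against the
schemas below.  This module also implements the two ICD-10 stay-selection
algorithms used to build the auxiliary variable from line-level discharge
records, and the log-log correlation criterion used to choose between them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SCHEMAS",
    "AGE_BAND_LABELS",
    "ESP_WEIGHTS_15PLUS",
    "StayRecord",
    "SchemaError",
    "IntegrityError",
    "ValidationError",
    "InsufficientDataError",
    "read_table",
    "write_table",
    "validate_table",
    "european_standard_weights",
    "age_to_band",
    "code_in_algorithm",
    "select_injury_stays",
    "compare_selection_algorithms",
]

N_AGE_BANDS = 15
SEXES = (1, 2)  # 1 = men, 2 = women

#: Column layout of each canonical table.  Key columns identify a row; count
#: columns must be non-negative integers; value columns strictly positive.
SCHEMAS: dict[str, dict[str, list[str]]] = {
    "strata_counts": {
        "keys": ["hospital_id", "sex", "age_cat", "year"],
        "counts": ["hli_count", "stay_count"],
        "values": [],
    },
    "national_stays": {
        "keys": ["sex", "age_cat", "year"],
        "counts": ["national_stay_count"],
        "values": [],
    },
    "population": {
        "keys": ["sex", "age_cat", "year"],
        "counts": [],
        "values": ["population"],
    },
    "standard_weights": {
        "keys": ["age_cat"],
        "counts": [],
        "values": ["weight"],
    },
}

AGE_BAND_LABELS = tuple(
    f"{15 + 5 * (j - 1)}-{19 + 5 * (j - 1)}" if j < 15 else "85+"
    for j in range(1, 16)
)

# European Standard Population (1976), 5-year groups from 15-19 upward with an
# open 85+ band, per 100,000 of the full standard.  Truncation to ages 15+
# keeps these 15 entries and renormalizes them to sum to one.
_ESP_RAW_15PLUS = np.array(
    [7000] * 8 + [6000, 5000, 4000, 3000, 2000, 1000, 1000], dtype=float
)
ESP_WEIGHTS_15PLUS = _ESP_RAW_15PLUS / _ESP_RAW_15PLUS.sum()


class SchemaError(ValueError):
    """Header does not match the requested table schema."""


class IntegrityError(ValueError):
    """Duplicate keys or incomplete grid."""


class ValidationError(ValueError):
    """Cell values violate a type invariant."""


class InsufficientDataError(ValueError):
    """Too few usable observations for the requested computation."""


@dataclass(frozen=True)
class StayRecord:
    """One hospital discharge with its ICD-10 diagnosis codes.

    ``diagnosis_codes[0]`` is the principal diagnosis; the remainder are
    associated diagnoses.  Selection treats principal and associated codes
    identically.
    """

    hospital_id: str
    sex: int
    age: float
    year: int
    diagnosis_codes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValidationError(f"negative age {self.age!r}")
        if not self.diagnosis_codes:
            raise ValidationError("a stay record needs at least one diagnosis code")
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be 1 (men) or 2 (women), got {self.sex!r}")


# ---------------------------------------------------------------------------
# table validation and I/O
# ---------------------------------------------------------------------------

def validate_table(df: pd.DataFrame, schema: str) -> pd.DataFrame:
    """Validate ``df`` against a canonical schema and return it normalized.

    Normalization sorts rows by key columns and casts count columns to int64.
    Raises :class:`SchemaError`, :class:`IntegrityError` or
    :class:`ValidationError` on the corresponding violation.
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    spec = SCHEMAS[schema]
    expected = spec["keys"] + spec["counts"] + spec["values"]
    missing = [c for c in expected if c not in df.columns]
    extra = [c for c in df.columns if c not in expected]
    if missing or extra:
        raise SchemaError(
            f"schema {schema!r}: missing columns {missing}, unexpected columns {extra}"
        )
    df = df[expected].copy()

    dup = df.duplicated(subset=spec["keys"])
    if dup.any():
        keys = df.loc[dup, spec["keys"]].to_dict("records")[:5]
        raise IntegrityError(f"duplicate key rows in {schema}: {keys}")

    for col in spec["counts"]:
        vals = df[col]
        if vals.isna().any():
            raise ValidationError(f"{schema}.{col}: missing values")
        if (vals < 0).any():
            raise ValidationError(f"{schema}.{col}: negative counts")
        if not np.allclose(vals, np.round(vals)):
            raise ValidationError(f"{schema}.{col}: non-integer counts")
        df[col] = vals.astype(np.int64)
    for col in spec["values"]:
        vals = df[col].astype(float)
        if vals.isna().any():
            raise ValidationError(f"{schema}.{col}: missing values")
        if (vals <= 0).any():
            raise ValidationError(f"{schema}.{col}: values must be strictly positive")
        df[col] = vals

    if "sex" in df.columns and not df["sex"].isin(SEXES).all():
        raise ValidationError(f"{schema}.sex: values outside {{1, 2}}")
    if "age_cat" in df.columns:
        if not df["age_cat"].between(1, N_AGE_BANDS).all():
            raise ValidationError(f"{schema}.age_cat: values outside 1..{N_AGE_BANDS}")
        df["age_cat"] = df["age_cat"].astype(np.int64)
    if "year" in df.columns:
        df["year"] = df["year"].astype(np.int64)
    if "sex" in df.columns:
        df["sex"] = df["sex"].astype(np.int64)

    # national stays and populations must cover the complete sex x age x year grid
    if schema in ("national_stays", "population"):
        years = df["year"].unique()
        expected_n = len(SEXES) * N_AGE_BANDS * len(years)
        if len(df) != expected_n:
            raise IntegrityError(
                f"{schema}: expected complete grid of {expected_n} rows "
                f"(2 sexes x {N_AGE_BANDS} age bands x {len(years)} years), got {len(df)}"
            )
    if schema == "standard_weights":
        if sorted(df["age_cat"]) != list(range(1, N_AGE_BANDS + 1)):
            raise IntegrityError("standard_weights: need exactly age bands 1..15")
        if not np.isclose(df["weight"].sum(), 1.0, atol=1e-8):
            raise ValidationError(
                f"standard_weights: weights sum to {df['weight'].sum():.6f}, expected 1"
            )

    return df.sort_values(spec["keys"], kind="mergesort").reset_index(drop=True)


def read_table(path, schema: str) -> pd.DataFrame:
    """Read one canonical CSV table and validate it against ``schema``."""
    df = pd.read_csv(path)
    return validate_table(df, schema)


def write_table(df: pd.DataFrame, path, schema: str) -> None:
    """Validate and write a canonical table; column order is the schema order."""
    validate_table(df, schema).to_csv(path, index=False)


def european_standard_weights() -> pd.DataFrame:
    """Bundled ESP(1976) weights truncated to ages 15+ and renormalized."""
    return pd.DataFrame(
        {"age_cat": np.arange(1, N_AGE_BANDS + 1), "weight": ESP_WEIGHTS_15PLUS}
    )


# ---------------------------------------------------------------------------
# ICD-10 stay selection
# ---------------------------------------------------------------------------

_CODE_RE = re.compile(r"^[A-Z][0-9]{2,}$")

# algorithm 2 = algorithm 1 (ICD-10 chapter 19, S00-T98) plus disorders
# strongly related to injuries: eyes H05/H16/H26/H27/H40, ears H72,
# respiratory J68-J70, skin L55-L59.
_ALGO2_EXTRA_PREFIXES = (
    "H05", "H16", "H26", "H27", "H40", "H72",
    "J68", "J69", "J70",
    "L55", "L56", "L57", "L58", "L59",
)


def _normalize_code(code: str) -> str:
    c = code.strip().upper().replace(".", "")
    if not _CODE_RE.match(c):
        raise ValidationError(f"malformed ICD-10 code {code!r}")
    return c


def code_in_algorithm(code: str, algorithm: int) -> bool:
    """Membership of one ICD-10 code in a selection algorithm's code set.

    Membership is decided on the 3-character block prefix after stripping
    dots, so subdivided codes ("S72.0", "T983") inherit from their block.
    Algorithm 1 is the chapter-19 range S00-T98; algorithm 2 adds the
    injury-related eye/ear/respiratory/skin blocks.
    """
    if algorithm not in (1, 2):
        raise ValueError(f"algorithm must be 1 or 2, got {algorithm!r}")
    c = _normalize_code(code)
    block = c[:3]
    if block[0] == "S":
        return True
    if block[0] == "T" and int(block[1:3]) <= 98:
        return True
    if algorithm == 2 and block in _ALGO2_EXTRA_PREFIXES:
        return True
    return False


def age_to_band(age: float) -> int | None:
    """Map an age in years to band 1..15 (15-19 ... 85+); None below 15."""
    if age < 15:
        return None
    return min(int((age - 15) // 5) + 1, N_AGE_BANDS)


def select_injury_stays(records, algorithm: int) -> pd.DataFrame:
    """Count injury-related stays per (hospital, sex, age band, year).

    A stay is counted once iff any of its diagnosis codes (principal or
    associated) belongs to the algorithm's code set; patients under 15 are
    excluded.  Returns a strata table with a ``stay_count`` column.
    """
    rows = []
    for rec in records:
        band = age_to_band(rec.age)
        hit = any(code_in_algorithm(c, algorithm) for c in rec.diagnosis_codes)
        if band is None or not hit:
            continue
        rows.append((rec.hospital_id, rec.sex, band, rec.year))
    counts = pd.DataFrame(rows, columns=["hospital_id", "sex", "age_cat", "year"])
    out = (
        counts.groupby(["hospital_id", "sex", "age_cat", "year"], as_index=False)
        .size()
        .rename(columns={"size": "stay_count"})
    )
    return out.sort_values(["hospital_id", "sex", "age_cat", "year"]).reset_index(drop=True)


def compare_selection_algorithms(
    hli: pd.DataFrame, stays_by_algorithm: dict[int, pd.DataFrame]
) -> dict:
    """Choose the selection algorithm whose stays track the HLI counts best.

    For each algorithm, the HLI table and the algorithm's stay counts are
    joined on (hospital, sex, age band, year) and the Pearson correlation of
    log(hli) vs log(stays) is computed; log-scaling stabilizes the variance of
    Poisson-like counts.  Cells where either count is zero are dropped (log
    undefined).  Returns ``{"correlations": {algo: r}, "selected": algo}``;
    ties go to the smaller (more restrictive) algorithm.
    """
    hli_cells = hli[["hospital_id", "sex", "age_cat", "year", "hli_count"]]
    correlations: dict[int, float] = {}
    for algo, stays in stays_by_algorithm.items():
        merged = hli_cells.merge(
            stays[["hospital_id", "sex", "age_cat", "year", "stay_count"]],
            on=["hospital_id", "sex", "age_cat", "year"],
            how="inner",
        )
        merged = merged[(merged["hli_count"] > 0) & (merged["stay_count"] > 0)]
        if len(merged) < 3:
            raise InsufficientDataError(
                f"algorithm {algo}: only {len(merged)} usable cells after dropping zeros"
            )
        r = float(
            np.corrcoef(np.log(merged["hli_count"]), np.log(merged["stay_count"]))[0, 1]
        )
        correlations[algo] = r
    # max correlation; ties broken toward the smaller algorithm id
    selected = min(correlations, key=lambda a: (-correlations[a], a))
    return {"correlations": correlations, "selected": selected}
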