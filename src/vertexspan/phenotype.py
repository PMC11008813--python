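"""Birth-weight and covariate harmonization rules.

Multi-cohort birth-weight (BW) studies pool registry, parent-report and
self-report weights recorded in mixed units, so the analysis sample depends
on a small set of deterministic harmonization rules: pounds/ounces to grams
conversion with a missing-ounces convention, reconciliation of repeated
reports with a 10% discrepancy exclusion, an education recoding dictionary,
a BW plausibility window (2.5-5.0 kg) for sensitivity reruns, and
within-cohort standardization of the continuous covariates that enter the
vertex models.  Each rule here is pure, idempotent where applicable, and
logged by the callers that apply it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GRAMS_PER_LB",
    "GRAMS_PER_OZ",
    "BWReport",
    "ScalingRecord",
    "lbs_oz_to_grams",
    "reconcile_repeated_bw",
    "ukb_education_to_years",
    "resolve_education",
    "apply_sensitivity_filters",
    "standardize_covariates",
    "main_analysis_view",
    "EXCLUDED",
]

GRAMS_PER_LB = 453.59237
GRAMS_PER_OZ = 28.349523125

#: Sentinel returned when repeated BW reports disagree beyond tolerance.
EXCLUDED = "excluded"

_UKB_EDUCATION_YEARS = {1: 16.0, 2: 13.0, 3: 11.0, 4: 11.0, 5: 11.0, 6: 12.0, -7: 10.0}


@dataclass(frozen=True)
class BWReport:
    """One participant's reported birth weights in grams, with their source."""

    values: tuple[float, ...]
    source: str = "self"

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise ValueError("a BWReport needs at least one value")
        if any(v <= 0 for v in self.values):
            raise ValueError("birth weights must be positive")
        if self.source not in ("registry", "self", "parent"):
            raise ValueError(f"unknown source {self.source!r}")


def lbs_oz_to_grams(lbs: float | None, oz: float | None) -> float | None:
    """Convert a pounds/ounces birth-weight report to grams.

    Missing ounces count as 0 so the pounds field alone contributes; a
    missing pounds field makes the whole report missing (the participant is
    excluded downstream).
    """
    lbs_missing = lbs is None or (isinstance(lbs, float) and math.isnan(lbs))
    oz_missing = oz is None or (isinstance(oz, float) and math.isnan(oz))
    if lbs_missing:
        return None
    if oz_missing:
        oz = 0.0
    if lbs < 0 or oz < 0:
        raise ValueError("pounds and ounces must be non-negative")
    return lbs * GRAMS_PER_LB + oz * GRAMS_PER_OZ


def reconcile_repeated_bw(report: BWReport, tolerance: float = 0.10):
    """Collapse repeated birth-weight reports to one value or exclude.

    The discrepancy is (max - min) / mean of the reported values; above
    ``tolerance`` the participant is excluded (returns the ``EXCLUDED``
    sentinel), otherwise the arithmetic mean is entered.  A single report is
    returned unchanged.  The mean denominator is a documented convention;
    pass a different callable-based rule upstream if needed.
    """
    vals = np.asarray(report.values, dtype=float)
    if len(vals) == 1:
        return float(vals[0])
    discrepancy = (vals.max() - vals.min()) / vals.mean()
    if discrepancy > tolerance:
        return EXCLUDED
    return float(vals.mean())


def ukb_education_to_years(code: int | list[int]) -> float | None:
    """Recode UK-Biobank-style education codes to years of education.

    Mapping: 1 -> 16, 2 -> 13, 3/4/5 -> 11, 6 -> 12, -7 -> 10, -3 -> missing
    ("prefer not to answer").  Given several codes for one person the highest
    resulting years wins.
    """
    codes = code if isinstance(code, (list, tuple, set)) else [code]
    years: list[float] = []
    for c in codes:
        c = int(c)
        if c == -3:
            continue
        if c not in _UKB_EDUCATION_YEARS:
            raise ValueError(f"unknown education code {c}")
        years.append(_UKB_EDUCATION_YEARS[c])
    return max(years) if years else None


def resolve_education(own: float | None, parental_mean: float | None) -> float | None:
    """Own education if recorded, else the average of parental education
    (the fallback used for participants too young to have completed their
    own schooling)."""
    own_missing = own is None or (isinstance(own, float) and math.isnan(own))
    return parental_mean if own_missing else own


def main_analysis_view(table: pd.DataFrame, allow_single_for_twins: bool = True) -> pd.DataFrame:
    """Rows for subjects with longitudinal data (>= 2 observations).

    Twins may contribute single-time-point observations to the discordance
    analysis, so rows carrying a twin-pair id are retained by default.
    """
    n_obs = table.groupby("subject_id")["subject_id"].transform("size")
    keep = n_obs >= 2
    if allow_single_for_twins and "twin_pair_id" in table:
        keep = keep | table["twin_pair_id"].notna()
    return table[keep].reset_index(drop=True)


def apply_sensitivity_filters(table: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Subset the cohort table for a sensitivity analysis.

    ``bw_range`` keeps 2.5 kg <= bw <= 5.0 kg (inclusive bounds, excluding
    implausibly low and high birth weights); ``gestational_subsample`` keeps
    rows with a recorded gestational length and marks it as an added
    covariate via the ``gestational_covariate`` table attribute.  After
    filtering, subjects left with fewer than two observations are dropped
    from the main-analysis view (twins exempt as usual).
    """
    if mode == "none":
        return table
    if mode == "bw_range":
        out = table[(table["bw"] >= 2.5) & (table["bw"] <= 5.0)]
    elif mode == "gestational_subsample":
        if "gestational_length" not in table or table["gestational_length"].isna().all():
            warnings.warn("no gestational_length recorded; gestational subsample is empty")
            out = table.iloc[0:0]
        else:
            out = table[table["gestational_length"].notna()]
    else:
        raise ValueError(f"unknown sensitivity-filter mode {mode!r}")
    out = main_analysis_view(out.reset_index(drop=True))
    if mode == "gestational_subsample":
        out.attrs["gestational_covariate"] = True
    return out


@dataclass
class ScalingRecord:
    """Per-cohort means/SDs used to standardize covariates.

    Retained so effect sizes estimated per 1 SD of a predictor can be put
    back in natural units (e.g. grams of birth weight per SD).
    """

    scales: dict = field(default_factory=dict)  # {(cohort, column): (mean, sd)}

    def record(self, cohort: str, column: str, mean: float, sd: float) -> None:
        self.scales[(cohort, column)] = (float(mean), float(sd))

    def sd(self, cohort: str, column: str) -> float:
        return self.scales[(cohort, column)][1]

    def back_transform(self, cohort: str, column: str, z: np.ndarray) -> np.ndarray:
        mean, sd = self.scales[(cohort, column)]
        return np.asarray(z) * sd + mean

    def bw_sd_grams(self, cohort: str) -> float:
        """Grams of birth weight corresponding to 1 SD (bw column is kg)."""
        return self.sd(cohort, "bw") * 1000.0


def standardize_covariates(
    table: pd.DataFrame, columns: list[str], *, within: str | None = "cohort"
) -> tuple[pd.DataFrame, ScalingRecord]:
    """Standardize columns to mean 0 / SD 1 within cohort, across observations.

    Returns the transformed table (columns replaced in place, originals kept
    under ``<col>_raw``) and the scaling record needed to back-transform.
    Zero-variance columns raise, naming the column.  ``within=None`` pools
    all rows into one scaling group (used for the pooled twin subsample,
    whose per-cohort contingents can be tiny); the pooled record is stored
    under the cohort label ``"all"``.
    """
    out = table.copy()
    record = ScalingRecord()
    if within is None:
        grouping = {"all": out.index}
    else:
        grouping = out.groupby(within, observed=True).groups
    for col in columns:
        if col not in out:
            raise KeyError(f"column {col!r} not in table")
        if not np.issubdtype(out[col].dtype, np.number):
            raise TypeError(f"column {col!r} is not numeric")
        out[f"{col}_raw"] = out[col]
        for cohort, idx in grouping.items():
            x = out.loc[idx, col].astype(float)
            mean, sd = x.mean(), x.std(ddof=1)
            if not np.isfinite(sd) or sd <= max(abs(mean), 1.0) * 1e-12:
                raise ValueError(f"column {col!r} has zero variance in cohort {cohort!r}")
            out.loc[idx, col] = (x - mean) / sd
            record.record(str(cohort), col, mean, sd)
    return out, record
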