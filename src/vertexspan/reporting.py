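"""Effect-size translation: what does a 1-SD birth-weight difference mean?

Vertex maps answer *where*; this module answers *how much*.  The birth-
weight (BW) effect on the total (vertex-summed) measure is re-expressed
three ways: natural units per 1 SD of BW (with the cohort's grams-per-SD
scaling attached), as a percent of the cohort's mean total measure, and —
for volume — as the number of years of estimated aging change producing an
equal difference.  The reference worked example: a 1-SD-lower BW effect of
6708 mm^3 against an estimated 895 mm^3 yearly reduction from age 50 to 60
is equivalent to 7.5 years of aging; 8466 mm^3 against 1402 mm^3/year gives
6 years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import VertexData
from .lme import fit_mass_lme
from .models import ModelSpec, build_design

__all__ = [
    "TotalEffect",
    "EquivalenceResult",
    "total_measure_effect",
    "annual_change",
    "aging_equivalence",
    "round_equivalence",
]


@dataclass
class TotalEffect:
    """BW effect on the total (vertex-summed) measure for one cohort."""

    effect_per_sd: float  # |beta| in natural units per 1 SD of BW
    beta: float  # signed estimate
    se: float
    mean_total: float  # cohort mean total measure at baseline
    percent_of_total: float  # 100 * effect_per_sd / mean_total
    bw_sd_grams: float | None = None  # grams per 1 SD, if a scaling record given


def total_measure_effect(
    data: VertexData,
    table: pd.DataFrame,
    spec: ModelSpec,
    *,
    bw_sd_grams: float | None = None,
) -> TotalEffect:
    """Fit the mixed model on the vertex-summed measure and report the
    contrast in natural units per 1 SD of the (standardized) predictor."""
    table = table.reset_index(drop=True)
    total = data.matrix.sum(axis=1)
    X, _, ci = build_design(table, spec)
    res = fit_mass_lme(X, total[:, None], table["subject_id"].to_numpy())
    beta = float(res.beta[ci, 0])
    se = float(res.se[ci, 0])
    # baseline rows: each subject's earliest scan (robust to the time
    # column having been standardized)
    time_col = table["time_raw"] if "time_raw" in table else table["time"]
    baseline = time_col == time_col.groupby(table["subject_id"]).transform("min")
    mean_total = float(total[baseline.to_numpy()].mean())
    return TotalEffect(
        effect_per_sd=abs(beta),
        beta=beta,
        se=se,
        mean_total=mean_total,
        percent_of_total=100.0 * abs(beta) / mean_total,
        bw_sd_grams=bw_sd_grams,
    )


def annual_change(
    data: VertexData,
    table: pd.DataFrame,
    age_window: tuple[float, float],
    *,
    covariates: tuple[str, ...] = ("sex", "site"),
) -> tuple[float, float]:
    """Yearly change of the total measure for subjects whose baseline age
    falls in ``age_window``.

    Returns (slope, SE) in natural units per year, from the mixed model's
    coefficient on *unstandardized* time.  Requires longitudinal rows in the
    window; an entirely cross-sectional selection raises.
    """
    lo, hi = age_window
    if hi <= lo:
        raise ValueError("age window must have hi > lo")
    table = table.reset_index(drop=True)
    in_window = (table["baseline_age"] >= lo) & (table["baseline_age"] <= hi)
    if not in_window.any():
        raise ValueError(f"no subjects with baseline age in [{lo}, {hi}]")
    sub = table[in_window].reset_index(drop=True)
    if sub.groupby("subject_id")["time"].nunique().max() < 2:
        raise ValueError("no within-subject time variation in the age window")
    total = data.matrix[in_window.to_numpy()].sum(axis=1)
    keep = [c for c in covariates if sub[c].nunique() > 1]
    spec = ModelSpec(contrast="time", covariates=tuple(keep) + ("baseline_age",))
    X, _, ci = build_design(sub, spec)
    res = fit_mass_lme(X, total[:, None], sub["subject_id"].to_numpy())
    return float(res.beta[ci, 0]), float(res.se[ci, 0])


def round_equivalence(raw: float) -> float:
    """Rounding convention for reporting years of aging equivalence.

    Values are reported to one decimal below 10 years, except that a value
    above 5 within 0.1 of an integer reads as that integer (7.495 -> 7.5 but
    6.04 -> 6); at or above 10 years the nearest integer is used.  The raw
    value is always carried alongside.
    """
    if raw >= 10:
        return float(round(raw))
    if raw > 5 and abs(raw - round(raw)) < 0.1:
        return float(round(raw))
    return float(round(raw, 1))


@dataclass
class EquivalenceResult:
    """Aging-equivalence of a 1-SD BW effect on the total measure."""

    effect_per_sd: float
    annual_slope: float
    equivalence_years: float  # raw ratio effect / |slope|
    equivalence_years_rounded: float
    bw_sd_grams: float | None = None
    percent_of_total: float | None = None
    age_window: tuple[float, float] | None = None


def aging_equivalence(
    effect_per_sd: float,
    annual_slope: float,
    *,
    bw_sd_grams: float | None = None,
    percent_of_total: float | None = None,
    age_window: tuple[float, float] | None = None,
) -> EquivalenceResult:
    """Years of estimated aging change equal to a 1-SD BW effect.

    equivalence_years = effect_per_sd / |annual_slope| exactly; a zero slope
    is undefined and raises.
    """
    if annual_slope == 0:
        raise ZeroDivisionError("aging equivalence undefined for zero annual slope")
    raw = effect_per_sd / abs(annual_slope)
    return EquivalenceResult(
        effect_per_sd=float(effect_per_sd),
        annual_slope=float(annual_slope),
        equivalence_years=float(raw),
        equivalence_years_rounded=round_equivalence(raw),
        bw_sd_grams=bw_sd_grams,
        percent_of_total=percent_of_total,
        age_window=age_window,
    )
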