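"""Residual-based outlier screening of whole scan observations.

Before any birth-weight model is fitted, each cohort is screened with a
smooth-age-trend model: at every vertex the measure is regressed on a
nonlinear function of age at scan (natural cubic spline basis inside a
subject-random-intercept mixed model), and an observation is excluded when
the absolute conditional residual exceeds ``k`` times the per-vertex
residual standard error at more than a threshold number of vertices.  The
reference rule is k = 4 and 6000 vertices out of 163,842; on smaller meshes
the count is reinterpreted as the same fraction of vertices (about 3.66%),
rounded.  Both criteria are strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import VertexData
from .lme import MassLMEResult, fit_mass_lme

__all__ = [
    "REFERENCE_VERTEX_COUNT",
    "REFERENCE_OUTLIER_COUNT",
    "OutlierReport",
    "natural_cubic_basis",
    "fit_smooth_trend",
    "flag_outlier_observations",
    "default_vertex_count_threshold",
]

REFERENCE_VERTEX_COUNT = 163_842
REFERENCE_OUTLIER_COUNT = 6_000


def natural_cubic_basis(
    x: np.ndarray, df: int = 5, knots: np.ndarray | None = None
) -> np.ndarray:
    """Natural cubic spline basis (linear beyond the boundary knots).

    Returns ``df`` columns (intercept excluded): the identity column plus
    ``df - 1`` curvature terms built from ``df + 1`` knots placed at
    quantiles.  Spans linear functions exactly for any df >= 1.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("spline df must be >= 1")
    if df == 1 or len(np.unique(x)) <= 2:
        return (x - x.mean())[:, None]
    if knots is None:
        n_knots = df + 1
        knots = np.quantile(np.unique(x), np.linspace(0, 1, n_knots))
        knots = np.unique(knots)
    k = len(knots)
    if k < 3:
        return (x - x.mean())[:, None]

    def d(j: int) -> np.ndarray:
        num = np.maximum(x - knots[j], 0.0) ** 3 - np.maximum(x - knots[-1], 0.0) ** 3
        return num / (knots[-1] - knots[j])

    cols = [x - x.mean()]
    last = d(k - 2)
    for j in range(k - 2):
        cols.append(d(j) - last)
    basis = np.column_stack(cols)
    # center curvature columns for conditioning
    basis[:, 1:] -= basis[:, 1:].mean(axis=0)
    return basis


@dataclass
class SmoothTrendFit:
    """Per-vertex residuals and residual SE from the smooth-age-trend model."""

    residuals: np.ndarray  # (n_obs, V) conditional residuals
    residual_se: np.ndarray  # (V,) sqrt of residual variance component
    icc: np.ndarray
    degenerate: np.ndarray  # (V,) or all-False; per-vertex degenerate flag
    degenerate_design: bool  # all ages equal -> intercept-only fallback


def fit_smooth_trend(
    data: VertexData,
    table: pd.DataFrame,
    *,
    spline_df: int = 5,
    refine_tol: float = 1e-4,
) -> SmoothTrendFit:
    """Fit value ~ smooth(age at scan) + subject random intercept per vertex.

    Residuals are conditional (the subject-intercept BLUP is subtracted);
    the residual SE is the square root of the estimated residual variance
    component.  A design with a single distinct age degenerates to an
    intercept-only fit, flagged on the result.
    """
    if len(table) != data.matrix.shape[0]:
        raise ValueError("table and vertex matrix row counts differ")
    age = (table["baseline_age"] + table["time"]).to_numpy(dtype=float)
    degenerate_design = len(np.unique(age)) < 3
    if degenerate_design:
        X = np.ones((len(table), 1))
    else:
        X = np.column_stack([np.ones(len(age)), natural_cubic_basis(age, df=spline_df)])
    groups = table["subject_id"].to_numpy()
    degenerate = ~np.all(np.isfinite(data.matrix), axis=0)
    Y = np.where(degenerate[None, :], 0.0, data.matrix)
    res = fit_mass_lme(X, Y, groups, refine_tol=refine_tol)
    resid = res.conditional_residuals(Y, X, groups)
    resid_se = np.sqrt(res.sigma2_resid)
    resid[:, degenerate] = np.nan
    return SmoothTrendFit(
        residuals=resid,
        residual_se=resid_se,
        icc=res.icc,
        degenerate=degenerate,
        degenerate_design=degenerate_design,
    )


def default_vertex_count_threshold(n_vertices: int) -> int:
    """The 6000-of-163,842 rule, kept exact at full resolution and applied
    as the equivalent fraction (rounded) on smaller meshes."""
    if n_vertices >= REFERENCE_VERTEX_COUNT:
        return REFERENCE_OUTLIER_COUNT
    return int(round(REFERENCE_OUTLIER_COUNT / REFERENCE_VERTEX_COUNT * n_vertices))


@dataclass
class OutlierReport:
    """Which observations the residual screen excludes and why."""

    vertex_exceed_count: np.ndarray  # (n_obs,) vertices where |resid| > k*SE
    excluded: np.ndarray  # (n_obs,) bool
    observation_ids: np.ndarray
    k: float
    vertex_count_threshold: int

    @property
    def excluded_ids(self) -> np.ndarray:
        return np.asarray(self.observation_ids)[self.excluded]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "observation_id": self.observation_ids,
                "vertex_exceed_count": self.vertex_exceed_count,
                "excluded": self.excluded,
            }
        )


def flag_outlier_observations(
    fit: SmoothTrendFit,
    observation_ids: np.ndarray,
    *,
    k: float = 4.0,
    vertex_count_threshold: int | None = None,
) -> OutlierReport:
    """Apply the strict two-part exclusion rule.

    An observation is excluded when |residual| > k * residual SE at strictly
    more than ``vertex_count_threshold`` vertices (default: the mesh-scaled
    6000-vertex rule).  Degenerate vertices never count.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    resid = fit.residuals
    n_vertices = resid.shape[1]
    if vertex_count_threshold is None:
        vertex_count_threshold = default_vertex_count_threshold(n_vertices)
    with np.errstate(invalid="ignore"):
        exceed = np.abs(resid) > (k * fit.residual_se)[None, :]
    exceed[:, fit.degenerate] = False
    counts = exceed.sum(axis=1)
    excluded = counts > vertex_count_threshold
    return OutlierReport(
        vertex_exceed_count=counts,
        excluded=excluded,
        observation_ids=np.asarray(observation_ids),
        k=float(k),
        vertex_count_threshold=int(vertex_count_threshold),
    )
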