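"""Mass-univariate longitudinal models of cortical structure.

At every vertex the same linear mixed model is fitted (see
:mod:`vertexspan.lme`): the measure regressed on a contrast of interest plus
the standard covariate set — baseline age, sex, scanner site, and time since
baseline — with a subject random intercept.  Three contrast families are
supported, fitted in turn as in the study design this emulates:

* the birth-weight (BW) main effect,
* the BW x time interaction (change analysis), with BW and time main
  effects as covariates,
* the baseline age x time x BW three-way interaction, with all three
  two-way interactions and main effects as covariates,

plus the monozygotic-twin discordance contrast, where the predictor is the
standardized within-pair BW difference and the pair-mean BW is an additional
covariate.  Continuous predictors are expected pre-standardized within
cohort (see :func:`vertexspan.phenotype.standardize_covariates`), so
estimates read as natural measure units per 1 SD of the predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import VertexData
from .lme import MassLMEResult, fit_mass_lme
from .qc import natural_cubic_basis

__all__ = [
    "ModelSpec",
    "EffectMap",
    "build_design",
    "fit_vertex_lme",
    "fit_twin_discordance",
    "fit_spline_sensitivity",
    "MIN_P",
]

#: Floor applied before -log10 so maps stay finite.
MIN_P = 1e-300

DEFAULT_CATEGORICAL = ("site", "ethnicity")


@dataclass(frozen=True)
class ModelSpec:
    """Which fixed effects to fit and which single term to report.

    ``contrast`` is a column name or a ':'-joined interaction
    (e.g. ``"bw:time"``); all lower-order terms of an interaction contrast
    are added as covariates automatically.  Flags toggle the sensitivity
    covariates.
    """

    contrast: str = "bw"
    covariates: tuple[str, ...] = ("baseline_age", "sex", "site", "time")
    include_education: bool = False
    include_icv: bool = False
    include_gestational: bool = False
    include_ethnicity: bool = False
    categorical: tuple[str, ...] = DEFAULT_CATEGORICAL

    def all_covariates(self) -> list[str]:
        cols = list(self.covariates)
        for flag, col in (
            (self.include_education, "education"),
            (self.include_icv, "icv"),
            (self.include_gestational, "gestational_length"),
            (self.include_ethnicity, "ethnicity"),
        ):
            if flag and col not in cols:
                cols.append(col)
        return cols

    def contrast_factors(self) -> list[str]:
        return self.contrast.split(":")


@dataclass
class EffectMap:
    """Per-vertex statistics for one contrast in one cohort.

    ``log10p`` is sign(t) * -log10(two-sided p); degenerate vertices (non-
    finite input) carry NaN and are excluded from the cluster stage.
    """

    estimate: np.ndarray
    se: np.ndarray
    tstat: np.ndarray
    df: float
    log10p: np.ndarray
    contrast: str
    cohort: str = ""
    measure: str = ""
    degenerate: np.ndarray | None = None
    n_obs: int = 0
    icc: np.ndarray | None = None

    @property
    def pvalue(self) -> np.ndarray:
        return 10.0 ** (-np.abs(self.log10p))

    @property
    def n_vertices(self) -> int:
        return len(self.estimate)


def _interaction_terms(factors: list[str]) -> list[tuple[str, ...]]:
    """All sub-products of an interaction, lowest order first, excluding the
    full product itself."""
    from itertools import combinations

    terms: list[tuple[str, ...]] = []
    for k in range(1, len(factors)):
        terms.extend(combinations(factors, k))
    return terms


def build_design(
    table: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, list[str], int]:
    """Assemble the fixed-effect design matrix.

    Returns (X, column names, index of the contrast column).  Categorical
    covariates (site, ethnicity) are dummy-coded dropping the first level;
    interaction contrasts include all lower-order terms as covariates.
    """
    cols: list[np.ndarray] = [np.ones(len(table))]
    names: list[str] = ["intercept"]

    def add_numeric(name: str, values: np.ndarray) -> None:
        cols.append(np.asarray(values, dtype=float))
        names.append(name)

    def add_column(col: str) -> None:
        if col in spec.categorical:
            dummies = pd.get_dummies(table[col].astype(str), prefix=col, drop_first=True)
            for c in dummies.columns:
                add_numeric(c, dummies[c].to_numpy(dtype=float))
        else:
            add_numeric(col, table[col].to_numpy(dtype=float))

    factors = spec.contrast_factors()
    covariates = spec.all_covariates()
    for col in covariates:
        add_column(col)
    # lower-order terms of an interaction contrast enter as covariates
    for term in _interaction_terms(factors):
        name = ":".join(term)
        if len(term) == 1:
            if term[0] not in covariates:
                add_column(term[0])
        elif name not in names:
            add_numeric(name, np.prod([table[f].to_numpy(dtype=float) for f in term], axis=0))
    contrast_name = ":".join(factors)
    contrast_values = np.prod([table[f].to_numpy(dtype=float) for f in factors], axis=0)
    contrast_index = len(names)
    add_numeric(contrast_name, contrast_values)
    X = np.column_stack(cols)
    if not np.all(np.isfinite(X)):
        bad = [names[j] for j in range(X.shape[1]) if not np.all(np.isfinite(X[:, j]))]
        raise ValueError(f"non-finite values in design columns {bad}")
    return X, names, contrast_index


def _result_to_map(
    res: MassLMEResult,
    contrast_index: int,
    contrast: str,
    cohort: str,
    measure: str,
    degenerate: np.ndarray | None,
) -> EffectMap:
    beta = res.beta[contrast_index].copy()
    se = res.se[contrast_index].copy()
    t = np.where(se > 0, beta / se, 0.0)
    p = np.maximum(2.0 * stats.t.sf(np.abs(t), res.df), MIN_P)
    log10p = np.sign(t) * -np.log10(p)
    if degenerate is not None and degenerate.any():
        for arr in (beta, se, t, log10p):
            arr[degenerate] = np.nan
    return EffectMap(
        estimate=beta,
        se=se,
        tstat=t,
        df=res.df,
        log10p=log10p,
        contrast=contrast,
        cohort=cohort,
        measure=measure,
        degenerate=degenerate,
        n_obs=res.n_obs,
        icc=res.icc,
    )


def fit_vertex_lme(
    data: VertexData,
    table: pd.DataFrame,
    spec: ModelSpec,
    *,
    refine_tol: float = 1e-6,
) -> EffectMap:
    """Fit the per-vertex random-intercept model and report the contrast.

    ``table`` rows must align with ``data.matrix`` rows and continuous
    covariates must already be standardized.  Vertices with non-finite data
    are flagged degenerate and excluded from downstream clustering.
    """
    if len(table) != data.matrix.shape[0]:
        raise ValueError("table and vertex matrix row counts differ")
    X, names, ci = build_design(table, spec)
    Y = data.matrix
    degenerate = ~np.all(np.isfinite(Y), axis=0)
    Y_fit = np.where(degenerate[None, :], 0.0, Y)
    res = fit_mass_lme(
        X, Y_fit, table["subject_id"].to_numpy(), refine_tol=refine_tol, column_names=names
    )
    cohort = ",".join(sorted(table["cohort"].astype(str).unique()))
    return _result_to_map(res, ci, spec.contrast, cohort, data.measure, degenerate)


def fit_twin_discordance(
    data: VertexData,
    table: pd.DataFrame,
    spec: ModelSpec | None = None,
    *,
    min_pairs: int = 10,
    refine_tol: float = 1e-6,
) -> EffectMap:
    """Within-pair birth-weight discordance contrast in MZ twins.

    Predictor: standardized ``bw_discordance`` (grams above/below the
    co-twin); covariates: time, baseline age, sex, site, and the
    standardized pair-mean BW.  Twins with single time points are allowed;
    the random intercept is still identified by subjects with repeats.
    """
    if table["twin_pair_id"].isna().any():
        raise ValueError("twin-discordance model requires a pair id on every row")
    n_pairs = table["twin_pair_id"].nunique()
    if n_pairs < min_pairs:
        raise ValueError(f"only {n_pairs} twin pairs; at least {min_pairs} required")
    if spec is None:
        spec = ModelSpec(
            contrast="bw_discordance",
            covariates=("time", "baseline_age", "sex", "site", "pair_mean_bw"),
        )
    return fit_vertex_lme(data, table, spec, refine_tol=refine_tol)


def fit_spline_sensitivity(
    data: VertexData,
    table: pd.DataFrame,
    spec: ModelSpec,
    parcellation: np.ndarray,
    *,
    spline_df: int = 5,
    refine_tol: float = 1e-6,
) -> EffectMap:
    """Region-of-interest rerun with a spline age trend.

    ``parcellation`` labels each vertex with a region; vertex values are
    averaged within region and the model is refitted with the linear
    baseline-age term replaced by a natural cubic spline basis in age,
    absorbing nonlinear age trends that could otherwise bias the contrast.
    """
    parcellation = np.asarray(parcellation)
    if len(parcellation) != data.n_vertices:
        raise ValueError("parcellation length must equal vertex count")
    regions = np.unique(parcellation)
    if len(regions) < 2:
        raise ValueError("parcellation must define at least 2 regions")
    Yr = np.column_stack(
        [data.matrix[:, parcellation == r].mean(axis=1) for r in regions]
    )
    base_spec = replace(
        spec,
        covariates=tuple(c for c in spec.covariates if c != "baseline_age"),
    )
    X, names, ci = build_design(table, base_spec)
    age = table["baseline_age"].to_numpy(dtype=float)
    basis = natural_cubic_basis(age, df=spline_df)
    spline_names = [f"age_spline{j}" for j in range(basis.shape[1])]
    # age spline enters as covariates, before the contrast column
    X = np.column_stack([X[:, :ci], basis, X[:, ci:]])
    names = names[:ci] + spline_names + names[ci:]
    ci = ci + basis.shape[1]
    res = fit_mass_lme(
        X, Yr, table["subject_id"].to_numpy(), refine_tol=refine_tol, column_names=names
    )
    cohort = ",".join(sorted(table["cohort"].astype(str).unique()))
    return _result_to_map(res, ci, spec.contrast, cohort, data.measure, None)
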