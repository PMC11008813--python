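"""Split-half and across-sample replicability of vertex-wise effects.

Brain-wide association effects are notoriously sample-dependent, so the
pipeline quantifies replicability two ways.  *Within sample*: the analysis
(vertex mixed model + cluster correction) is repeated on many random 50%
subject subsamples; exploratory replicability is, per vertex, the fraction
of subsamples in which it survives correction, and confirmatory
replicability is, per subsample, the fraction of its corrected-significant
vertices that are also significant — uncorrected p < 0.05, same direction —
in the held-out half.  Subsamples with no significant vertices are excluded
from the confirmatory summary rather than counted as zeros.  *Across
samples*: one cohort's corrected-significant set plays the train role and
another cohort's uncorrected map the test role, in both directions.

Splits are at the subject level (all of a subject's scans stay together;
co-twins travel together when pair ids are present) and stratified by
cohort and site to avoid incidental site imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import VertexData
from .inference import ClusterResult, clusterwise_p
from .models import EffectMap, ModelSpec, fit_vertex_lme

__all__ = [
    "ReplicabilityReport",
    "split_half_replicability",
    "across_sample_replicability",
    "confirmatory_fraction",
]


@dataclass
class ReplicabilityReport:
    """Summary of a split-half replicability run."""

    n_splits: int
    exploratory: np.ndarray  # (2V,) fraction of splits each vertex survived
    confirmatory: np.ndarray  # (n_assessable,) per-split fractions
    n_excluded_splits: int  # splits with no corrected-significant vertices
    params: dict = field(default_factory=dict)

    @property
    def mean_confirmatory(self) -> float:
        return float(np.mean(self.confirmatory)) if len(self.confirmatory) else np.nan

    def summary(self) -> dict:
        c = self.confirmatory
        return {
            "n_splits": self.n_splits,
            "n_assessable": int(len(c)),
            "n_excluded_splits": self.n_excluded_splits,
            "mean_confirmatory": self.mean_confirmatory,
            "q25_confirmatory": float(np.quantile(c, 0.25)) if len(c) else np.nan,
            "q75_confirmatory": float(np.quantile(c, 0.75)) if len(c) else np.nan,
            "mean_exploratory": float(self.exploratory.mean()),
        }


def _split_units(table: pd.DataFrame) -> pd.DataFrame:
    """One row per split unit (a subject, or a whole twin pair) with its
    stratum (cohort, site)."""
    t = table.drop_duplicates("subject_id")[["subject_id", "cohort", "site"]].copy()
    if "twin_pair_id" in table:
        pair = table.drop_duplicates("subject_id").set_index("subject_id")["twin_pair_id"]
        t["unit"] = [
            f"pair:{pair[s]}" if pd.notna(pair[s]) else f"subj:{s}"
            for s in t["subject_id"]
        ]
    else:
        t["unit"] = "subj:" + t["subject_id"].astype(str)
    return t


def _half_split(units: pd.DataFrame, rng: np.random.Generator) -> set:
    """Pick half of the units into the train set, stratified by cohort/site."""
    train: list[str] = []
    for _, grp in units.drop_duplicates("unit").groupby(["cohort", "site"], observed=True):
        u = np.sort(grp["unit"].to_numpy())  # order-invariant before shuffling
        rng.shuffle(u)
        train.extend(u[: len(u) // 2])
    return set(train)


def confirmatory_fraction(
    train_sig_mask: np.ndarray,
    train_sign: np.ndarray,
    test_map: EffectMap,
    alpha: float = 0.05,
) -> float | None:
    """Fraction of train-significant vertices confirmed in the test half
    (uncorrected p < alpha, same direction).  None when the train set is
    empty (not assessable)."""
    idx = np.flatnonzero(train_sig_mask)
    if len(idx) == 0:
        return None
    p_test = test_map.pvalue[idx]
    sign_test = np.sign(test_map.tstat[idx])
    ok = np.isfinite(p_test) & (p_test < alpha) & (sign_test == train_sign[idx])
    return float(np.mean(ok))


def split_half_replicability(
    data: VertexData,
    table: pd.DataFrame,
    spec: ModelSpec,
    *,
    n_splits: int = 50,
    seed: int = 0,
    cft: float = 2.0,
    n_null: int = 200,
    alpha_cluster: float = 0.025,
    alpha_test: float = 0.05,
) -> ReplicabilityReport:
    """Repeated split-half replicability of one contrast.

    Reference-scale runs use 500 splits on a 2562-vertex mesh; desk-scale
    defaults use 50 splits and a reduced cluster null (n_null = 200), both
    recorded in ``params``.
    """
    if n_splits < 2:
        raise ValueError("n_splits must be >= 2")
    table = table.reset_index(drop=True)
    if table["subject_id"].nunique() < 20:
        raise ValueError("need at least 20 subjects for split-half analysis")
    units = _split_units(table)
    unit_of_subject = units.set_index("subject_id")["unit"]
    rng = np.random.default_rng(seed)
    v2 = data.n_vertices
    tally = np.zeros(v2)
    confirmatory: list[float] = []
    n_excluded = 0
    for _ in range(n_splits):
        train_units = _half_split(units, rng)
        in_train = table["subject_id"].map(unit_of_subject).isin(train_units).to_numpy()
        tr_tbl = table[in_train].reset_index(drop=True)
        te_tbl = table[~in_train].reset_index(drop=True)
        tr_data = data.subset_rows(in_train)
        te_data = data.subset_rows(~in_train)
        clusters = clusterwise_p(
            tr_data, tr_tbl, spec, cft=cft, n_null=n_null,
            seed=int(rng.integers(2**31)), alpha_per_hemisphere=alpha_cluster,
        )
        sig = clusters.significant_vertices(alpha_cluster)
        tally += sig
        if not sig.any():
            n_excluded += 1
            continue
        sign_train = np.zeros(v2)
        for _, row in clusters.table.iterrows():
            if row["p"] < alpha_cluster:
                sign_train[clusters.labels == row["id"]] = row["sign"]
        test_map = fit_vertex_lme(te_data, te_tbl, spec, refine_tol=1e-3)
        frac = confirmatory_fraction(sig, sign_train, test_map, alpha_test)
        if frac is not None:
            confirmatory.append(frac)
    return ReplicabilityReport(
        n_splits=n_splits,
        exploratory=tally / n_splits,
        confirmatory=np.asarray(confirmatory),
        n_excluded_splits=n_excluded,
        params={
            "cft": cft, "n_null": n_null, "alpha_cluster": alpha_cluster,
            "alpha_test": alpha_test, "seed": seed, "contrast": spec.contrast,
        },
    )


def across_sample_replicability(
    data_a: VertexData,
    table_a: pd.DataFrame,
    data_b: VertexData,
    table_b: pd.DataFrame,
    spec: ModelSpec,
    *,
    cft: float = 2.0,
    n_null: int = 200,
    seed: int = 0,
    alpha_cluster: float = 0.025,
    alpha_test: float = 0.05,
) -> dict:
    """Pairwise across-cohort replicability, both directions.

    Each cohort in turn provides the corrected-significant (train) set; the
    other cohort's uncorrected map is the test.  A direction with no
    significant train vertices is reported as ``None`` (not assessable),
    never as zero.
    """
    if data_a.n_vertices != data_b.n_vertices:
        raise ValueError("cohorts must share a mesh")
    out = {}
    pairs = [("a_to_b", data_a, table_a, data_b, table_b),
             ("b_to_a", data_b, table_b, data_a, table_a)]
    for i, (label, d_tr, t_tr, d_te, t_te) in enumerate(pairs):
        clusters = clusterwise_p(
            d_tr, t_tr.reset_index(drop=True), spec, cft=cft, n_null=n_null,
            seed=seed + i, alpha_per_hemisphere=alpha_cluster,
        )
        sig = clusters.significant_vertices(alpha_cluster)
        sign_train = np.zeros(d_tr.n_vertices)
        for _, row in clusters.table.iterrows():
            if row["p"] < alpha_cluster:
                sign_train[clusters.labels == row["id"]] = row["sign"]
        test_map = fit_vertex_lme(d_te, t_te.reset_index(drop=True), spec, refine_tol=1e-3)
        out[label] = confirmatory_fraction(sig, sign_train, test_map, alpha_test)
    return out
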