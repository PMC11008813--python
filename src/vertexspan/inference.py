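"""Multiple-comparison control and spatial-consistency inference.

Three inferential devices operate on the vertex-wise effect maps:

* **Cluster-extent correction.**  Vertices with -log10 p beyond a
  cluster-forming threshold (default 2.0, i.e. p < 0.01) are grouped into
  connected components of common sign within each hemisphere's mesh
  adjacency; each cluster's size is referred to a permutation null of the
  maximum cluster size per hemisphere, and clusters are declared significant
  at p < 0.025 per hemisphere (0.05 split over two hemispheres).  The null
  permutes the contrast variable's residuals across subjects (whole subjects,
  keeping each subject's longitudinal rows intact), in the Freedman-Lane
  spirit; the permutation fits run on a whitened model with the working
  intraclass correlation estimated once from the observed data, which makes
  the observed and null statistics exchangeable and the whole null bank a
  few hundred matrix products.

* **Spin tests.**  The spatial correlation of two maps is referred to a
  null built by spinning one map with random sphere rotations (mirrored into
  the right hemisphere), preserving its spatial autocorrelation; p-values
  are two-tailed with the +1 permutation convention, and sets of comparisons
  are FDR-adjusted (Benjamini-Hochberg).

* **Fixed-effect meta-analysis.**  Beta maps from several cohorts combine
  per vertex with inverse-variance weights, yielding a meta map comparable
  to, e.g., a twin-discordance map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from .cohort import VertexData
from .lme import fit_mass_lme, whiten
from .models import MIN_P, EffectMap, ModelSpec, build_design
from .surface import SpinNull, SurfaceMesh, mesh_adjacency

__all__ = [
    "ClusterResult",
    "SpatialComparison",
    "find_clusters",
    "clusterwise_p",
    "spatial_correlation",
    "spin_test",
    "fdr_adjust",
    "meta_analyze_maps",
]


@dataclass
class ClusterResult:
    """Signed supra-threshold clusters and their cluster-wise p-values.

    ``labels`` assigns each vertex a cluster id (0 = sub-threshold); the
    table has one row per cluster with hemisphere, sign, size and p.
    """

    labels: np.ndarray  # (2V,) int, 0 = no cluster
    table: pd.DataFrame  # id, hemisphere, sign, size, p
    cft: float
    alpha_per_hemisphere: float = 0.025
    n_null: int = 0
    null_max_sizes: dict = field(default_factory=dict)  # hemisphere -> (n_null,)

    def significant_vertices(self, alpha: float | None = None) -> np.ndarray:
        """Boolean mask of vertices inside clusters with p < alpha."""
        alpha = self.alpha_per_hemisphere if alpha is None else alpha
        if len(self.table) == 0 or self.table["p"].isna().all():
            return np.zeros(len(self.labels), dtype=bool)
        sig_ids = self.table.loc[self.table["p"] < alpha, "id"].to_numpy()
        return np.isin(self.labels, sig_ids)

    @property
    def n_clusters(self) -> int:
        return len(self.table)


def _components(mask: np.ndarray, adjacency: sparse.csr_matrix) -> list[np.ndarray]:
    """Connected components of the adjacency restricted to masked vertices."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    sub = adjacency[idx][:, idx]
    n_comp, lab = sparse.csgraph.connected_components(sub, directed=False)
    return [idx[lab == c] for c in range(n_comp)]


def find_clusters(
    effect: EffectMap | np.ndarray,
    mesh_left: SurfaceMesh,
    mesh_right: SurfaceMesh,
    cft: float = 2.0,
) -> ClusterResult:
    """Connected components of supra-threshold vertices, split by sign and
    hemisphere.  ``effect`` may be an EffectMap or a raw signed -log10 p map
    over concatenated hemispheres.  Cluster-wise p's are NaN until a
    permutation null fills them (:func:`clusterwise_p`)."""
    slp = effect.log10p if isinstance(effect, EffectMap) else np.asarray(effect, dtype=float)
    v = mesh_left.n_vertices
    if mesh_right.n_vertices != v or len(slp) != 2 * v:
        raise ValueError("map length must be twice the per-hemisphere vertex count")
    labels = np.zeros(2 * v, dtype=int)
    rows = []
    next_id = 1
    for hemi, mesh, offset in (("left", mesh_left, 0), ("right", mesh_right, v)):
        adj = mesh_adjacency(mesh)
        hemi_map = slp[offset : offset + v]
        finite = np.isfinite(hemi_map)
        for sign in (+1, -1):
            mask = finite & (sign * hemi_map > cft)
            for comp in _components(mask, adj):
                labels[offset + comp] = next_id
                rows.append(
                    {"id": next_id, "hemisphere": hemi, "sign": sign,
                     "size": len(comp), "p": np.nan}
                )
                next_id += 1
    table = pd.DataFrame(rows, columns=["id", "hemisphere", "sign", "size", "p"])
    return ClusterResult(labels=labels, table=table, cft=cft)


def _whitened_stat_map(
    Ytil: np.ndarray, ytil_ss: np.ndarray, c_til: np.ndarray, df: int
) -> np.ndarray:
    """Signed -log10 p from the Frisch-Waugh regression of covariate-
    residualized responses on the residualized contrast column."""
    ctc = float(c_til @ c_til)
    if ctc <= 0:
        return np.zeros(Ytil.shape[1])
    beta = (c_til @ Ytil) / ctc
    rss = np.maximum(ytil_ss - beta**2 * ctc, 1e-300)
    t = beta * np.sqrt(ctc) / np.sqrt(rss / df)
    p = np.maximum(2.0 * stats.t.sf(np.abs(t), df), MIN_P)
    return np.sign(t) * -np.log10(p)


def _max_cluster_sizes(
    slp: np.ndarray, adj_left, adj_right, v: int, cft: float
) -> tuple[int, int]:
    out = []
    for adj, offset in ((adj_left, 0), (adj_right, v)):
        hemi_map = slp[offset : offset + v]
        best = 0
        for sign in (+1, -1):
            comps = _components(sign * hemi_map > cft, adj)
            if comps:
                best = max(best, max(len(c) for c in comps))
        out.append(best)
    return out[0], out[1]


def _subject_level_permuted_contrast(
    table: pd.DataFrame, X: np.ndarray, names: list[str], spec: ModelSpec, seed: int
):
    """Prepare the Freedman-Lane machinery for the contrast variable.

    The contrast's base variable (e.g. bw) is subject-constant: its
    subject-level values are residualized on the subject-level covariate
    design; the callable returned rebuilds, for one permutation of those
    residuals across subjects, the observation-level contrast column.
    """
    factors = spec.contrast_factors()
    # the permutable variable: the subject-constant factor of the contrast
    subj = table["subject_id"].to_numpy()
    uniq, codes = np.unique(subj, return_inverse=True)
    base_var = None
    for f in factors:
        vals = table[f].to_numpy(dtype=float)
        firsts = np.zeros(len(uniq))
        seen = np.zeros(len(uniq), dtype=bool)
        for i, c in enumerate(codes):
            if not seen[c]:
                firsts[c] = vals[i]
                seen[c] = True
        if np.allclose(vals, firsts[codes]):
            base_var, base_subject_vals = f, firsts
            break
    if base_var is None:
        raise ValueError(
            f"no subject-constant factor in contrast {spec.contrast!r}; "
            "cannot permute across subjects"
        )
    # subject-level covariate design: subject means of all non-contrast columns
    keep = [j for j, nm in enumerate(names) if base_var not in nm.split(":")]
    Z = np.zeros((len(uniq), len(keep)))
    counts = np.bincount(codes).astype(float)
    for k, j in enumerate(keep):
        Z[:, k] = np.bincount(codes, weights=X[:, j]) / counts
    coef, *_ = np.linalg.lstsq(Z, base_subject_vals, rcond=None)
    fitted = Z @ coef
    resid = base_subject_vals - fitted
    other = [f for f in factors if f != base_var]
    other_obs = (
        np.prod([table[f].to_numpy(dtype=float) for f in other], axis=0)
        if other
        else np.ones(len(table))
    )

    def contrast_column(perm: np.ndarray) -> np.ndarray:
        permuted_subject = fitted + resid[perm]
        return permuted_subject[codes] * other_obs

    rng = np.random.default_rng(seed)
    return contrast_column, rng, len(uniq)


def clusterwise_p(
    data: VertexData,
    table: pd.DataFrame,
    spec: ModelSpec,
    *,
    cft: float = 2.0,
    n_null: int = 1000,
    seed: int = 0,
    alpha_per_hemisphere: float = 0.025,
) -> ClusterResult:
    """Cluster-extent inference with a subject-permutation null.

    Fits the mixed model, whitens at the pooled intraclass correlation, and
    compares each observed cluster's size with the permutation distribution
    of the per-hemisphere maximum cluster size:
    p = (1 + #{null max >= size}) / (1 + n_null).
    """
    if n_null < 100:
        raise ValueError("n_null must be at least 100")
    if len(table) != data.matrix.shape[0]:
        raise ValueError("table and vertex matrix row counts differ")
    table = table.reset_index(drop=True)
    X, names, ci = build_design(table, spec)
    groups = table["subject_id"].to_numpy()
    degenerate = ~np.all(np.isfinite(data.matrix), axis=0)
    Y = np.where(degenerate[None, :], 0.0, data.matrix)

    # working intraclass correlation pooled over vertices (observed fit)
    fit = fit_mass_lme(X, Y, groups, refine_tol=1e-3)
    rho = float(np.median(fit.icc))

    Xw = whiten(X, groups, rho)
    Yw = whiten(Y, groups, rho)
    covar_idx = [j for j in range(X.shape[1]) if j != ci]
    Q, _ = np.linalg.qr(Xw[:, covar_idx])
    Ytil = Yw - Q @ (Q.T @ Yw)
    ytil_ss = np.einsum("ij,ij->j", Ytil, Ytil)
    df = X.shape[0] - X.shape[1]

    def residualize(c: np.ndarray) -> np.ndarray:
        cw = whiten(c, groups, rho)
        return cw - Q @ (Q.T @ cw)

    # observed statistic map via the same whitened route as the null
    c_obs = residualize(X[:, ci])
    slp_obs = _whitened_stat_map(Ytil, ytil_ss, c_obs, df)
    slp_obs[degenerate] = np.nan
    observed = find_clusters(slp_obs, data.mesh_left, data.mesh_right, cft)

    # Null responses are the FULL-model residuals (observed contrast effect
    # removed), so a strong true effect cannot masquerade as exchangeable
    # noise and inflate the null cluster sizes; the permuted contrast is
    # then regressed on this signal-free pool.
    ctc = float(c_obs @ c_obs)
    proj = (c_obs @ Ytil) / ctc
    E = Ytil - np.outer(c_obs, proj)
    e_ss = np.maximum(ytil_ss - proj**2 * ctc, 0.0)

    contrast_column, rng, n_subjects = _subject_level_permuted_contrast(
        table, X, names, spec, seed
    )
    v = data.mesh_left.n_vertices
    adj_left = mesh_adjacency(data.mesh_left)
    adj_right = mesh_adjacency(data.mesh_right)
    null_max = {"left": np.empty(n_null, dtype=int), "right": np.empty(n_null, dtype=int)}
    for b in range(n_null):
        perm = rng.permutation(n_subjects)
        slp = _whitened_stat_map(E, e_ss, residualize(contrast_column(perm)), df)
        slp[degenerate] = 0.0
        ml, mr = _max_cluster_sizes(slp, adj_left, adj_right, v, cft)
        null_max["left"][b] = ml
        null_max["right"][b] = mr

    tbl = observed.table
    ps = np.empty(len(tbl))
    for i, row in tbl.iterrows():
        nm = null_max[row["hemisphere"]]
        ps[i] = (1 + np.sum(nm >= row["size"])) / (1 + n_null)
    tbl = tbl.assign(p=ps)
    return ClusterResult(
        labels=observed.labels,
        table=tbl,
        cft=cft,
        alpha_per_hemisphere=alpha_per_hemisphere,
        n_null=n_null,
        null_max_sizes=null_max,
    )


def spatial_correlation(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Pearson correlation of two vertex maps, excluding non-finite vertices
    pairwise.  Constant maps raise (the correlation is undefined)."""
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 3 or a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined: constant or near-empty map")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class SpatialComparison:
    """One map-pair comparison: Pearson r with its spin-test p."""

    label_a: str
    label_b: str
    r: float
    p_spin: float
    n_perm: int
    q: float = np.nan  # FDR-adjusted, filled when comparisons are batched
    spun_map: str = "a"


def spin_test(
    map_a: np.ndarray,
    map_b: np.ndarray,
    null: SpinNull,
    *,
    label_a: str = "a",
    label_b: str = "b",
) -> SpatialComparison:
    """Two-tailed spin test of the spatial correlation of two maps.

    The first map is spun (convention); null correlations between each spun
    version of map A and the fixed map B give
    p = (1 + #{|r_null| >= |r_obs|}) / (1 + n_perm).
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    v = null.n_vertices
    if len(a) != 2 * v or len(b) != 2 * v:
        raise ValueError("maps must live on the spin null's mesh (2V vertices)")
    r_obs = spatial_correlation(a, b)
    spun_left, spun_right = null.apply(a[:v], a[v:])
    spun = np.concatenate([spun_left, spun_right], axis=1)  # (n_perm, 2V)
    ok = np.isfinite(b)
    bz = b[ok] - b[ok].mean()
    s = spun[:, ok]
    s = s - s.mean(axis=1, keepdims=True)
    denom = np.sqrt((s**2).sum(axis=1) * (bz**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r_null = (s @ bz) / denom
    r_null = r_null[np.isfinite(r_null)]
    p = (1 + np.sum(np.abs(r_null) >= abs(r_obs))) / (1 + len(r_null))
    return SpatialComparison(
        label_a=label_a, label_b=label_b, r=r_obs, p_spin=float(p),
        n_perm=int(len(r_null)), spun_map="a",
    )


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def meta_analyze_maps(maps: list[EffectMap]) -> EffectMap:
    """Per-vertex inverse-variance fixed-effect meta-analysis of beta maps.

    beta_meta = sum(w beta) / sum(w) with w = 1/SE^2;
    SE_meta = 1/sqrt(sum w).  Inference is normal (z).  Vertices with a zero
    SE in any input are flagged degenerate.  A single input map is returned
    as its own (normal-inference) meta map.
    """
    if len(maps) < 1:
        raise ValueError("need at least one map")
    v = maps[0].n_vertices
    contrast, measure = maps[0].contrast, maps[0].measure
    for m in maps[1:]:
        if m.n_vertices != v:
            raise ValueError("maps must share a mesh")
        if m.contrast != contrast or m.measure != measure:
            raise ValueError("maps must share contrast and measure")
    beta = np.stack([m.estimate for m in maps])
    se = np.stack([m.se for m in maps])
    degenerate = np.any(~np.isfinite(beta) | ~np.isfinite(se) | (se == 0), axis=0)
    se_safe = np.where(se > 0, se, np.nan)
    w = 1.0 / se_safe**2
    meta_beta = np.nansum(w * beta, axis=0) / np.nansum(w, axis=0)
    meta_se = 1.0 / np.sqrt(np.nansum(w, axis=0))
    z = np.where(meta_se > 0, meta_beta / meta_se, 0.0)
    p = np.maximum(2.0 * stats.norm.sf(np.abs(z)), MIN_P)
    log10p = np.sign(z) * -np.log10(p)
    for arr in (meta_beta, meta_se, z, log10p):
        arr[degenerate] = np.nan
    return EffectMap(
        estimate=meta_beta, se=meta_se, tstat=z, df=np.inf, log10p=log10p,
        contrast=contrast, cohort="meta(" + ",".join(m.cohort for m in maps) + ")",
        measure=measure, degenerate=degenerate,
        n_obs=sum(m.n_obs for m in maps),
    )
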