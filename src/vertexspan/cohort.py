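"""Synthetic multi-cohort longitudinal vertex-wise data with known truth.

The generator emulates the design features that drive the downstream
statistics, without any real data: an accelerated longitudinal design (1-5
scans per subject, intervals summing to several years), three cohorts with
very different baseline-age distributions (a lifespan sample spanning 4-82 y,
a narrow developmental sample at 9-11 y, an older-adult sample at 47-80 y),
multiple scanner sites with additive offsets, spatially smooth true effect
maps for age / sex / birth weight (BW) on a spherical mesh pair, subject
random intercepts, monozygotic twin pairs with within-pair BW discordance,
and optional grossly corrupted observations for exercising the QC screen.

The generative model is deliberately the model the analysis fits — linear in
standardized covariates with a subject random intercept — so parameter
recovery is a well-posed check.  An optional quadratic age term provides a
misspecification scenario for the spline sensitivity path.

All randomness flows from explicit integer seeds through
``numpy.random.default_rng``; regeneration with the same seed is
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .surface import SurfaceMesh, smooth_on_mesh

__all__ = [
    "CohortConfig",
    "EffectSpec",
    "TwinConfig",
    "GroundTruth",
    "VertexData",
    "lcbc_like",
    "abcd_like",
    "ukb_like",
    "sample_design",
    "sample_truth",
    "generate_vertex_data",
    "generate_twin_subsample",
    "cap_mask",
]

TRUTH_MAP_NAMES = ("b0", "age", "sex", "bw", "time", "bw_time", "discord")


@dataclass(frozen=True)
class CohortConfig:
    """Design parameters for one cohort.

    Ages are years at baseline; ``visit_counts``/``visit_probs`` give the
    distribution of scans per subject; ``interval_mean``/``interval_sd`` the
    gap (years) between consecutive scans; BW is drawn from a normal
    truncated to (0.5, 6.5) kg.
    """

    name: str
    n_subjects: int
    age_range: tuple[float, float]
    visit_counts: tuple[int, ...] = (2,)
    visit_probs: tuple[float, ...] = (1.0,)
    interval_mean: float = 2.0
    interval_sd: float = 0.5
    n_sites: int = 3
    bw_mean: float = 3.4
    bw_sd: float = 0.6
    has_ethnicity: bool = False
    n_ethnicities: int = 4
    has_education: bool = True
    has_gestational: bool = False
    has_icv: bool = True
    sex_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        if self.age_range[1] < self.age_range[0]:
            raise ValueError(f"infeasible age range {self.age_range}")
        if len(self.visit_counts) != len(self.visit_probs):
            raise ValueError("visit_counts and visit_probs lengths differ")
        if abs(sum(self.visit_probs) - 1.0) > 1e-9:
            raise ValueError("visit_probs must sum to 1")
        if self.interval_mean <= 0 or self.interval_sd < 0:
            raise ValueError("interval parameters must be positive")


def lcbc_like(n_subjects: int = 635) -> CohortConfig:
    """Lifespan cohort: ages 4-82, 2-5 visits, follow-up up to ~8 y."""
    return CohortConfig(
        name="LCBC",
        n_subjects=n_subjects,
        age_range=(4.1, 81.9),
        visit_counts=(2, 3, 4, 5),
        visit_probs=(0.45, 0.3, 0.15, 0.1),
        interval_mean=2.0,
        interval_sd=0.8,
        n_sites=4,
        bw_mean=3.5,
        bw_sd=0.6,
        has_gestational=True,
    )


def abcd_like(n_subjects: int = 3324) -> CohortConfig:
    """Narrow developmental cohort: ages ~9-11, two visits ~2 y apart,
    many sites, ethnic variation (so ethnicity enters as a covariate)."""
    return CohortConfig(
        name="ABCD",
        n_subjects=n_subjects,
        age_range=(8.9, 11.1),
        visit_counts=(2,),
        visit_probs=(1.0,),
        interval_mean=2.0,
        interval_sd=0.1,
        n_sites=8,
        bw_mean=3.3,
        bw_sd=0.6,
        has_ethnicity=True,
        has_gestational=True,
    )


def ukb_like(n_subjects: int = 1759) -> CohortConfig:
    """Older-adult cohort: ages 47-80, two visits ~2.3 y apart."""
    return CohortConfig(
        name="UKB",
        n_subjects=n_subjects,
        age_range=(47.0, 80.3),
        visit_counts=(2,),
        visit_probs=(1.0,),
        interval_mean=2.3,
        interval_sd=0.1,
        n_sites=3,
        bw_mean=3.4,
        bw_sd=0.6,
    )


_TABLE_COLUMNS = [
    "observation_id", "subject_id", "cohort", "baseline_age", "sex", "site",
    "time", "bw", "education", "ethnicity", "gestational_length", "icv",
    "twin_pair_id", "zygosity", "bw_discordance", "pair_mean_bw",
]


def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_design(
    configs: CohortConfig | list[CohortConfig],
    seed: int,
    *,
    min_visits_override: int | None = None,
) -> pd.DataFrame:
    """Draw a longitudinal design table for one or more cohorts.

    The returned frame has one row per scan observation with ``time = 0`` at
    each subject's first scan and strictly increasing within subject.  BW is
    independent of site and sex.
    """
    if isinstance(configs, CohortConfig):
        configs = [configs]
    rng = np.random.default_rng(seed)
    frames = []
    for cfg in configs:
        if cfg.n_subjects == 0:
            continue
        n = cfg.n_subjects
        baseline_age = rng.uniform(cfg.age_range[0], cfg.age_range[1], size=n)
        sex = (rng.random(n) < cfg.sex_ratio).astype(int)
        site = rng.integers(0, cfg.n_sites, size=n)
        bw = _truncnorm(rng, cfg.bw_mean, cfg.bw_sd, 0.5, 6.5, n)
        visits = rng.choice(cfg.visit_counts, size=n, p=cfg.visit_probs)
        if min_visits_override is not None:
            visits = np.maximum(visits, min_visits_override)
        education = (
            np.clip(rng.normal(13.0, 3.0, size=n), 8, 22) if cfg.has_education else np.full(n, np.nan)
        )
        ethnicity = (
            rng.integers(0, cfg.n_ethnicities, size=n) if cfg.has_ethnicity else np.full(n, -1)
        )
        gest = (
            np.clip(rng.normal(39.5, 1.8, size=n), 25, 44) if cfg.has_gestational else np.full(n, np.nan)
        )
        icv = rng.normal(1.5e6, 1.3e5, size=n) if cfg.has_icv else np.full(n, np.nan)
        rows = []
        for i in range(n):
            t = 0.0
            for v in range(visits[i]):
                if v > 0:
                    gap = max(rng.normal(cfg.interval_mean, cfg.interval_sd), 0.1)
                    t += gap
                rows.append(
                    {
                        "subject_id": f"{cfg.name}_{i:05d}",
                        "cohort": cfg.name,
                        "baseline_age": baseline_age[i],
                        "sex": sex[i],
                        "site": f"{cfg.name}_site{site[i]}",
                        "time": t,
                        "bw": bw[i],
                        "education": education[i],
                        "ethnicity": int(ethnicity[i]) if cfg.has_ethnicity else None,
                        "gestational_length": gest[i],
                        "icv": icv[i],
                    }
                )
        frames.append(pd.DataFrame(rows))
    if not frames:
        return pd.DataFrame(columns=_TABLE_COLUMNS)
    table = pd.concat(frames, ignore_index=True)
    for col in ("twin_pair_id", "zygosity"):
        table[col] = pd.Series([None] * len(table), dtype=object)
    table["bw_discordance"] = np.nan
    table["pair_mean_bw"] = np.nan
    table.insert(0, "observation_id", [f"obs{i:06d}" for i in range(len(table))])
    return table[_TABLE_COLUMNS]


@dataclass(frozen=True)
class EffectSpec:
    """Amplitudes and noise for the generative model.

    Each nonzero-amplitude effect map is spatially smooth white noise
    standardized to the requested SD across vertices; ``b0_mean`` is the
    constant intercept (natural units of the measure).  ``cap_effects`` names
    maps generated instead as a constant-amplitude spherical-cap patch (used
    for localized-effect and twin-discordance scenarios).  ``corrupt_k`` is
    the size (in residual SDs) of the whole-row offset applied to the
    corrupted fraction of observations.
    """

    b0_mean: float = 100.0
    amplitudes: dict = field(
        default_factory=lambda: {
            "b0": 1.0, "age": 1.0, "sex": 0.5, "bw": 1.0,
            "time": -0.3, "bw_time": 0.0, "discord": 0.0,
        }
    )
    smooth_iterations: int = 20
    sigma_u: float = 1.0
    sigma_e: float = 1.0
    site_offset_sd: float = 0.5
    corrupt_fraction: float = 0.0
    corrupt_k: float = 10.0
    cap_effects: dict = field(default_factory=dict)  # {map_name: radius_radians}
    quadratic_age: float = 0.0  # optional misspecification term

    def __post_init__(self) -> None:
        if self.sigma_u < 0 or self.sigma_e < 0:
            raise ValueError("variance components must be non-negative")
        if self.corrupt_k < 8 and self.corrupt_fraction > 0:
            raise ValueError("corruption offset must be at least 8 residual SDs")


@dataclass
class GroundTruth:
    """True effect maps and variance components behind a generated dataset."""

    maps: dict  # name -> (2V,) array, left then right hemisphere
    site_offsets: dict  # site label -> scalar (filled at generation time)
    sigma_u: float
    sigma_e: float
    mesh_left: SurfaceMesh
    mesh_right: SurfaceMesh
    corrupted_rows: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    cap_masks: dict = field(default_factory=dict)
    spec: EffectSpec | None = None

    @property
    def n_vertices(self) -> int:
        return 2 * self.mesh_left.n_vertices


@dataclass
class VertexData:
    """Observations x vertices matrix for one measure, bound to its meshes
    and to the cohort table's row order (left-hemisphere vertices first)."""

    measure: str
    matrix: np.ndarray  # (n_obs, 2V)
    mesh_left: SurfaceMesh
    mesh_right: SurfaceMesh
    observation_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.measure not in ("area", "thickness", "volume"):
            raise ValueError(f"unknown measure {self.measure!r}")
        expected = 2 * self.mesh_left.n_vertices
        if self.matrix.shape[1] != expected:
            raise ValueError(
                f"matrix has {self.matrix.shape[1]} vertex columns, meshes imply {expected}"
            )
        if len(self.observation_ids) != self.matrix.shape[0]:
            raise ValueError("observation_ids length must match matrix rows")

    @property
    def n_vertices(self) -> int:
        return self.matrix.shape[1]

    def subset_rows(self, mask: np.ndarray) -> "VertexData":
        return VertexData(
            self.measure, self.matrix[mask], self.mesh_left, self.mesh_right,
            np.asarray(self.observation_ids)[mask],
        )


def cap_mask(mesh: SurfaceMesh, center: np.ndarray, radius: float) -> np.ndarray:
    """Vertices within geodesic angle ``radius`` of the unit vector ``center``."""
    center = np.asarray(center, dtype=float)
    center = center / np.linalg.norm(center)
    return np.arccos(np.clip(mesh.vertex_coords @ center, -1, 1)) < radius


def _smooth_standardized_map(
    mesh_left: SurfaceMesh, mesh_right: SurfaceMesh, amplitude: float,
    iterations: int, rng: np.random.Generator,
) -> np.ndarray:
    v = mesh_left.n_vertices
    raw = rng.standard_normal(2 * v)
    left = smooth_on_mesh(mesh_left, raw[:v], iterations)
    right = smooth_on_mesh(mesh_right, raw[v:], iterations)
    m = np.concatenate([left, right])
    m = (m - m.mean()) / m.std()
    return amplitude * m


def sample_truth(
    mesh_left: SurfaceMesh,
    mesh_right: SurfaceMesh,
    spec: EffectSpec,
    seed: int,
) -> GroundTruth:
    """Draw ground-truth effect maps on a mesh pair.

    Smooth maps are standardized so their SD across vertices equals the
    requested amplitude exactly; zero amplitude yields an exactly-zero map.
    Cap-shaped effects are constant at the amplitude inside a geodesic cap
    centered on the north pole of each hemisphere.
    """
    rng = np.random.default_rng(seed)
    v2 = 2 * mesh_left.n_vertices
    maps: dict[str, np.ndarray] = {}
    cap_masks: dict[str, np.ndarray] = {}
    for name in TRUTH_MAP_NAMES:
        amp = float(spec.amplitudes.get(name, 0.0))
        if amp == 0.0:
            maps[name] = np.zeros(v2)
        elif name in spec.cap_effects:
            radius = spec.cap_effects[name]
            pole = np.array([0.0, 0.0, 1.0])
            mask = np.concatenate(
                [cap_mask(mesh_left, pole, radius), cap_mask(mesh_right, pole, radius)]
            )
            maps[name] = np.where(mask, amp, 0.0)
            cap_masks[name] = mask
        else:
            maps[name] = _smooth_standardized_map(
                mesh_left, mesh_right, amp, spec.smooth_iterations, rng
            )
    maps["b0"] = maps["b0"] + spec.b0_mean
    return GroundTruth(
        maps=maps,
        site_offsets={},
        sigma_u=spec.sigma_u,
        sigma_e=spec.sigma_e,
        mesh_left=mesh_left,
        mesh_right=mesh_right,
        cap_masks=cap_masks,
        spec=spec,
    )


def _zscore_within_cohort(table: pd.DataFrame, column: str) -> np.ndarray:
    """Within-cohort standardization used inside the generative model."""
    x = table[column].astype(float)
    out = np.zeros(len(table))
    for _, idx in table.groupby("cohort", observed=True).groups.items():
        v = x.loc[idx]
        sd = v.std(ddof=1)
        out[table.index.get_indexer(idx)] = 0.0 if (not np.isfinite(sd) or sd == 0) else (
            (v - v.mean()) / sd
        )
    return out


def generate_vertex_data(
    table: pd.DataFrame,
    truth: GroundTruth,
    seed: int,
    measure: str = "area",
) -> VertexData:
    """Simulate the vertex matrix implied by a design table and ground truth.

    y(obs, v) = b0(v) + b_age(v) z(baseline_age) + b_sex(v) sex + site(v-less
    offset) + b_bw(v) z(bw) + b_time(v) time + b_bw_time(v) z(bw) time
    [+ b_discord(v) z(bw_discordance) for twins] + u_subject(v) + eps, with
    standardization z(.) computed within cohort.  A configured fraction of
    rows receives a whole-row offset of corrupt_k * sigma_e and is recorded
    in ``truth.corrupted_rows``.
    """
    spec = truth.spec or EffectSpec()
    rng = np.random.default_rng(seed)
    n = len(table)
    v2 = truth.n_vertices
    table = table.reset_index(drop=True)

    z_age = _zscore_within_cohort(table, "baseline_age")
    z_bw = _zscore_within_cohort(table, "bw")
    sex = table["sex"].to_numpy(dtype=float)
    time = table["time"].to_numpy(dtype=float)

    y = np.empty((n, v2))
    y[:] = truth.maps["b0"][None, :]
    y += np.outer(z_age, truth.maps["age"])
    y += np.outer(sex, truth.maps["sex"])
    y += np.outer(time, truth.maps["time"])
    y += np.outer(z_bw, truth.maps["bw"])
    y += np.outer(z_bw * time, truth.maps["bw_time"])
    if spec.quadratic_age != 0.0:
        y += np.outer(spec.quadratic_age * z_age**2, truth.maps["age"])

    if table["bw_discordance"].notna().any() and np.any(truth.maps["discord"] != 0):
        disc = table["bw_discordance"].fillna(0.0).to_numpy(dtype=float)
        twin = table["twin_pair_id"].notna().to_numpy()
        if twin.any():
            sd = disc[twin].std(ddof=1)
            z_disc = np.where(twin, disc / sd if sd > 0 else 0.0, 0.0)
            y += np.outer(z_disc, truth.maps["discord"])

    # site offsets: drawn once per site label, stored back into the truth
    sites = table["site"].astype(str)
    for s in sites.unique():
        if s not in truth.site_offsets:
            truth.site_offsets[s] = float(rng.normal(0.0, spec.site_offset_sd))
    y += np.array([truth.site_offsets[s] for s in sites])[:, None]

    # subject random intercepts, independent across subjects and vertices
    subjects, codes = np.unique(table["subject_id"], return_inverse=True)
    if spec.sigma_u > 0:
        u = rng.normal(0.0, spec.sigma_u, size=(len(subjects), v2))
        y += u[codes]
    if spec.sigma_e > 0:
        y += rng.normal(0.0, spec.sigma_e, size=(n, v2))

    if spec.corrupt_fraction > 0:
        n_bad = int(round(spec.corrupt_fraction * n))
        bad = rng.choice(n, size=n_bad, replace=False)
        y[bad] += spec.corrupt_k * spec.sigma_e
        truth.corrupted_rows = np.sort(bad)

    return VertexData(
        measure=measure,
        matrix=y,
        mesh_left=truth.mesh_left,
        mesh_right=truth.mesh_right,
        observation_ids=table["observation_id"].to_numpy(),
    )


@dataclass(frozen=True)
class TwinConfig:
    """Monozygotic twin subsample: ``n_pairs`` pairs sharing a latent pair-
    mean BW, with within-pair discordance of SD ``discordance_sd_g`` grams.

    The default 193 pairs (386 twins) mirrors a mixed-age composition:
    mostly developmental-age pairs with smaller adult and older-adult
    contingents.  ``single_timepoint_fraction`` of twins get only a baseline
    scan.
    """

    n_pairs: int = 193
    discordance_sd_g: float = 300.0
    cohort_mix: tuple[tuple[str, float], ...] = (
        ("ABCD", 0.80), ("LCBC", 0.17), ("UKB", 0.03),
    )
    single_timepoint_fraction: float = 0.2
    pair_bw_mean: float = 3.2
    pair_bw_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.n_pairs <= 0:
            raise ValueError("n_pairs must be positive")
        if self.discordance_sd_g < 0:
            raise ValueError("discordance SD must be non-negative")


_TWIN_COHORT_TEMPLATES = {
    "ABCD": dict(age_range=(9.9, 11.1), interval_mean=2.0, interval_sd=0.1, n_sites=4),
    "LCBC": dict(age_range=(18.0, 79.0), interval_mean=2.5, interval_sd=0.8, n_sites=2),
    "UKB": dict(age_range=(50.0, 80.0), interval_mean=2.3, interval_sd=0.1, n_sites=2),
}


def generate_twin_subsample(
    config: TwinConfig,
    spec: EffectSpec,
    mesh_left: SurfaceMesh,
    mesh_right: SurfaceMesh,
    seed: int,
    measure: str = "area",
) -> tuple[pd.DataFrame, VertexData, GroundTruth]:
    """Generate a twin design, its ground truth, and the vertex matrix.

    Co-twins share a latent pair-mean BW; individual BW = pair mean +/-
    discordance/2, so ``bw_discordance`` (grams above/below the co-twin) sums
    to zero within each pair and the discordance effect acts only through
    within-pair differences.
    """
    rng = np.random.default_rng(seed)
    truth = sample_truth(mesh_left, mesh_right, spec, seed)

    names, probs = zip(*config.cohort_mix)
    pair_cohorts = rng.choice(names, size=config.n_pairs, p=np.asarray(probs) / sum(probs))
    rows = []
    for p in range(config.n_pairs):
        cname = str(pair_cohorts[p])
        tmpl = _TWIN_COHORT_TEMPLATES[cname]
        pair_mean = float(_truncnorm(rng, config.pair_bw_mean, config.pair_bw_sd, 0.8, 6.0, 1)[0])
        d_g = float(rng.normal(0.0, config.discordance_sd_g))
        base_age = rng.uniform(*tmpl["age_range"])
        site = f"{cname}_twsite{rng.integers(0, tmpl['n_sites'])}"
        sex = int(rng.random() < 0.5)  # MZ co-twins share sex
        for k, sign in enumerate((+1.0, -1.0)):
            bw_kg = pair_mean + sign * (d_g / 1000.0) / 2.0
            n_visits = 1 if rng.random() < config.single_timepoint_fraction else 2
            t = 0.0
            for v in range(n_visits):
                if v > 0:
                    t += max(rng.normal(tmpl["interval_mean"], tmpl["interval_sd"]), 0.1)
                rows.append(
                    {
                        "subject_id": f"tw{p:04d}_{k}",
                        "cohort": cname,
                        "baseline_age": base_age,  # MZ co-twins scanned together
                        "sex": sex,
                        "site": site,
                        "time": t,
                        "bw": max(bw_kg, 0.4),
                        "education": np.nan,
                        "ethnicity": None,
                        "gestational_length": np.nan,
                        "icv": np.nan,
                        "twin_pair_id": f"pair{p:04d}",
                        "zygosity": "MZ",
                        "bw_discordance": sign * d_g,
                        "pair_mean_bw": pair_mean,
                    }
                )
    table = pd.DataFrame(rows)
    table.insert(0, "observation_id", [f"tobs{i:06d}" for i in range(len(table))])
    table = table[_TABLE_COLUMNS]
    data = generate_vertex_data(table, truth, seed + 1, measure=measure)
    return table, data, truth
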