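# vertexspan

Vertex-wise lifespan analysis of birth-weight effects on cortical structure:
mass-univariate longitudinal linear mixed models on spherical surface
meshes, cluster-extent correction, spin-test spatial consistency analysis,
split-half replicability, monozygotic-twin discordance contrasts, and
effect-size / aging-equivalence reporting — exercised end to end on a
synthetic cohort generator with known ground truth.

## The problem

Birth weight (BW) indexes fetal growth, and its association with cortical
surface area and volume appears to be established early and carried through
life (brain *reserve*) rather than protecting against age-related change
(brain *maintenance*).  Testing that claim takes longitudinal brain MRI
across the lifespan, harmonized birth-weight phenotypes, mass-univariate
models with proper multiple-comparison control, formal tests that effect
*topographies* agree across cohorts, replicability quantification, and MZ
twin discordance designs to separate genetic from intrauterine influence.
`vertexspan` packages that entire analysis as a reusable, tested Python
library for methodologists and neuroimaging researchers who want to run,
calibrate, or extend the pipeline — on synthetic cohorts with known truth,
or on their own vertex data via FreeSurfer-compatible I/O.

## The model

At each vertex *v* of a spherical mesh pair, for observation *i* of subject
*s(i)*:

```
y_iv = β₀(v) + β_bw(v)·z(bw_s) + β_age(v)·z(age_s) + β_sex(v)·sex_s
       + site_i + β_t(v)·z(t_i) + u_{s(i)}(v) + ε_iv

u_s(v) ~ N(0, σ_u²),   ε_iv ~ N(0, σ_e²)
```

fitted by profiled maximum likelihood over the intraclass correlation
ρ = σ_u²/(σ_u²+σ_e²), vectorized across all vertices at once.  Contrasts
fitted in turn: BW; BW × time (change); baseline age × time × BW; and, in
MZ twins, the standardized within-pair BW discordance with pair-mean BW as
a covariate.  Inference per map: cluster-forming threshold −log₁₀p > 2.0
(p < .01), cluster-wise p < .025 per hemisphere from a subject-level
permutation null of the maximum cluster size; map-to-map correspondence by
Pearson *r* with two-tailed spin-test p (random sphere rotations, mirrored
across hemispheres) and Benjamini–Hochberg FDR.

## Worked example

Fit the BW effect map on a simulated lifespan cohort and check recovery
(`examples/05_fit_bw_effect_map.py`):

```
$ python examples/05_fit_bw_effect_map.py
fitted beta map over 1284 vertices, df=886
correlation with true birth-weight map: r = 0.997
median intraclass correlation (subject clustering): 0.49
vertices with |t| > 2: 1171 (raw, before cluster correction)
estimates are in measure units per 1 SD of birth weight (~588 g here)
```

The fitted beta map recovers the true effect topography almost exactly
(r = 0.997 at 300 subjects), the estimated subject clustering matches the
generator's ICC of 0.5, and estimates are in natural units per standard
deviation of birth weight.

Translate effect sizes into years-of-aging equivalence
(`examples/10_aging_equivalence.py`):

```
$ python examples/10_aging_equivalence.py
lifespan cohort: 6708 mm^3 per SD / 895 mm^3 per year = 7.495 y -> reported as 7.5
older-adult cohort: 8466 mm^3 per SD / 1402 mm^3 per year = 6.039 y -> reported as 6.0
...
```

Read: a one-SD (~600–700 g) birth-weight difference corresponds to as much
cortical volume as 7.5 (resp. 6) years of estimated aging change in a
50–60-year window — the headline framing the reporting module reproduces.

The other scripts in `examples/` each demonstrate one capability: mesh and
spin-null construction, cohort simulation, phenotype harmonization rules,
the QC outlier screen, cluster inference, cross-cohort spatial consistency,
twins and meta-analysis, and replicability.

A thin CLI mirrors the library (`vertexspan mesh|spin|simulate|qc|fit|
cluster|compare|run`), and `vertexspan run --config cfg.yaml --out rundir`
executes a validated end-to-end pipeline with a reproducibility manifest.

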