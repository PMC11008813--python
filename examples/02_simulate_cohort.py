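"""Generate a synthetic longitudinal cohort with known ground truth.

Three cohort presets emulate the designs the pipeline targets: a lifespan
sample (ages 4-82, up to 5 scans), a narrow developmental sample (9-11, two
scans) and an older-adult sample (47-80, two scans ~2.3 y apart).  Vertex
data follow a linear mixed model with spatially smooth true effect maps for
age, sex and birth weight, site offsets and a subject random intercept.
"""

import vertexspan as vs

mesh_l, mesh_r = vs.make_icosphere(3, "left"), vs.make_icosphere(3, "right")

truth = vs.sample_truth(mesh_l, mesh_r, vs.EffectSpec(), seed=1)
table = vs.sample_design([vs.lcbc_like(100), vs.ukb_like(80)], seed=2)
data = vs.generate_vertex_data(table, truth, seed=3)

print(f"{table['subject_id'].nunique()} subjects, {len(table)} scan observations")
print(f"vertex matrix: {data.matrix.shape[0]} observations x {data.matrix.shape[1]} vertices")
print(table.groupby("cohort")["baseline_age"].agg(["min", "max", "count"]).round(1))
print(f"true birth-weight map SD across vertices: {truth.maps['bw'].std():.3f} "
      f"(the configured amplitude)")
print(f"noise: sigma_u={truth.sigma_u}, sigma_e={truth.sigma_e} "
      "(subject intercept and residual SDs)")
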