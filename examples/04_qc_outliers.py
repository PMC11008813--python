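"""Residual-based screening of corrupted scan observations.

A smooth-age-trend mixed model (spline in age at scan + subject random
intercept) is fitted at every vertex; an observation is dropped when its
absolute conditional residual exceeds 4 residual SEs at more than ~3.66% of
vertices (the 6000-of-163,842 rule, rescaled to the mesh).
"""

import numpy as np

import vertexspan as vs

mesh_l, mesh_r = vs.make_icosphere(3, "left"), vs.make_icosphere(3, "right")
spec = vs.EffectSpec(corrupt_fraction=0.01, corrupt_k=10.0)
truth = vs.sample_truth(mesh_l, mesh_r, spec, seed=1)
table = vs.sample_design(vs.lcbc_like(150), seed=2)
data = vs.generate_vertex_data(table, truth, seed=3)

trend = vs.fit_smooth_trend(data, table)
report = vs.flag_outlier_observations(trend, table["observation_id"].to_numpy())

print(f"{len(table)} observations, {len(truth.corrupted_rows)} corrupted by "
      "a 10-sigma whole-row offset")
print(f"vertex-count threshold: > {report.vertex_count_threshold} of "
      f"{data.n_vertices} vertices beyond 4 residual SEs")
print(f"excluded observations: {sorted(report.excluded_ids)}")
truth_ids = set(table['observation_id'].iloc[truth.corrupted_rows])
print(f"truth set:             {sorted(truth_ids)}")
print("exact match" if set(report.excluded_ids) == truth_ids else "MISMATCH")
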