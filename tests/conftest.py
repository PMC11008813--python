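import numpy as np
import pytest

import vertexspan as vs


@pytest.fixture(scope="session")
def mesh_pair_s2():
    return vs.make_icosphere(2, "left"), vs.make_icosphere(2, "right")


@pytest.fixture(scope="session")
def mesh_pair_s3():
    return vs.make_icosphere(3, "left"), vs.make_icosphere(3, "right")


@pytest.fixture(scope="session")
def small_cohort(mesh_pair_s2):
    """60-subject lifespan-like cohort with a positive BW effect, on s=2."""
    ml, mr = mesh_pair_s2
    spec = vs.EffectSpec()
    truth = vs.sample_truth(ml, mr, spec, seed=11)
    table = vs.sample_design(vs.lcbc_like(60), seed=12)
    data = vs.generate_vertex_data(table, truth, seed=13)
    table, scaling = vs.standardize_covariates(table, ["baseline_age", "bw", "time"])
    return table, data, truth, scaling


def smooth_random_map(mesh_left, mesh_right, seed, iterations=20):
    rng = np.random.default_rng(seed)
    v = mesh_left.n_vertices
    return np.concatenate(
        [
            vs.smooth_on_mesh(mesh_left, rng.standard_normal(v), iterations),
            vs.smooth_on_mesh(mesh_right, rng.standard_normal(v), iterations),
        ]
    )
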