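import numpy as np
import pandas as pd
import pytest
from scipy import stats

import vertexspan as vs


class TestSampleDesign:
    def test_empty_config(self):
        table = vs.sample_design(vs.lcbc_like(0), seed=1)
        assert len(table) == 0

    def test_bit_identical_regeneration(self):
        a = vs.sample_design(vs.lcbc_like(50), seed=7)
        b = vs.sample_design(vs.lcbc_like(50), seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_design_invariants(self):
        table = vs.sample_design([vs.lcbc_like(40), vs.ukb_like(30)], seed=3)
        assert (table["bw"] > 0).all()
        for _, grp in table.groupby("subject_id"):
            t = grp["time"].to_numpy()
            assert t[0] == 0.0
            assert np.all(np.diff(t) > 0)

    def test_lcbc_bw_moments(self):
        """Large-sample BW distribution matches the configured 3.5 (0.6) kg."""
        table = vs.sample_design(vs.lcbc_like(5000), seed=5)
        bw = table.drop_duplicates("subject_id")["bw"]
        assert bw.mean() == pytest.approx(3.5, abs=0.05)
        assert bw.std() == pytest.approx(0.6, abs=0.05)

    def test_ukb_two_visits_interval(self):
        table = vs.sample_design(vs.ukb_like(300), seed=6)
        sizes = table.groupby("subject_id").size()
        assert (sizes == 2).all()
        intervals = table[table["time"] > 0]["time"]
        assert intervals.mean() == pytest.approx(2.3, abs=0.1)

    def test_infeasible_age_range(self):
        with pytest.raises(ValueError):
            vs.CohortConfig(name="bad", n_subjects=5, age_range=(50.0, 10.0))


class TestSampleTruth:
    def test_zero_amplitude_exactly_zero(self, mesh_pair_s2):
        ml, mr = mesh_pair_s2
        spec = vs.EffectSpec(amplitudes={"bw": 0.0, "b0": 1.0})
        truth = vs.sample_truth(ml, mr, spec, 1)
        assert np.all(truth.maps["bw"] == 0.0)

    def test_amplitude_sets_map_sd(self, mesh_pair_s3):
        ml, mr = mesh_pair_s3
        spec = vs.EffectSpec(amplitudes={"bw": 2.0})
        truth = vs.sample_truth(ml, mr, spec, 2)
        assert truth.maps["bw"].std() == pytest.approx(2.0, rel=0.02)

    def test_independent_seeds_uncorrelated(self, mesh_pair_s3):
        ml, mr = mesh_pair_s3
        spec = vs.EffectSpec(amplitudes={"bw": 1.0})
        a = vs.sample_truth(ml, mr, spec, 10).maps["bw"]
        b = vs.sample_truth(ml, mr, spec, 20).maps["bw"]
        assert abs(np.corrcoef(a, b)[0, 1]) < 0.1


class TestGenerateVertexData:
    def test_noise_free_constant(self, mesh_pair_s2):
        ml, mr = mesh_pair_s2
        spec = vs.EffectSpec(
            b0_mean=100.0,
            amplitudes={k: 0.0 for k in ("b0", "age", "sex", "bw", "time")},
            sigma_u=0.0, sigma_e=0.0, site_offset_sd=0.0,
        )
        truth = vs.sample_truth(ml, mr, spec, 1)
        table = vs.sample_design(vs.lcbc_like(10), 2)
        data = vs.generate_vertex_data(table, truth, 3)
        np.testing.assert_allclose(data.matrix, 100.0, atol=1e-12)

    def test_bw_effect_visible_to_ols_oracle(self, mesh_pair_s2):
        """At a vertex, regressing y on z(bw) should recover ~beta_bw(v)."""
        ml, mr = mesh_pair_s2
        spec = vs.EffectSpec(
            amplitudes={"b0": 0.0, "age": 0.0, "sex": 0.0, "bw": 1.0, "time": 0.0},
            sigma_u=0.5, sigma_e=0.5, site_offset_sd=0.0, b0_mean=0.0,
        )
        truth = vs.sample_truth(ml, mr, spec, 4)
        table = vs.sample_design(vs.lcbc_like(800), 5)
        data = vs.generate_vertex_data(table, truth, 6)
        z = (table["bw"] - table["bw"].mean()) / table["bw"].std(ddof=1)
        v = int(np.argmax(np.abs(truth.maps["bw"])))
        slope, _, _, _, se = stats.linregress(z, data.matrix[:, v])
        assert abs(slope - truth.maps["bw"][v]) < 3 * se

    def test_corruption_recorded_and_visible(self, mesh_pair_s2):
        ml, mr = mesh_pair_s2
        spec = vs.EffectSpec(corrupt_fraction=0.02, corrupt_k=10.0)
        truth = vs.sample_truth(ml, mr, spec, 7)
        table = vs.sample_design(vs.lcbc_like(500), 8)
        n = len(table)
        data = vs.generate_vertex_data(table, truth, 9)
        assert len(truth.corrupted_rows) == round(0.02 * n)
        clean_spec = vs.EffectSpec(**{**spec.__dict__, "corrupt_fraction": 0.0})
        clean_truth = vs.sample_truth(ml, mr, clean_spec, 7)
        clean = vs.generate_vertex_data(table, clean_truth, 9)
        shift = data.matrix.mean(axis=1) - clean.matrix.mean(axis=1)
        flagged = np.zeros(n, dtype=bool)
        flagged[truth.corrupted_rows] = True
        np.testing.assert_allclose(shift[flagged], 10.0, atol=1e-9)
        np.testing.assert_allclose(shift[~flagged], 0.0, atol=1e-9)

    def test_seed_reproducibility(self, mesh_pair_s2):
        ml, mr = mesh_pair_s2
        spec = vs.EffectSpec()
        table = vs.sample_design(vs.lcbc_like(20), 1)
        t1 = vs.sample_truth(ml, mr, spec, 2)
        t2 = vs.sample_truth(ml, mr, spec, 2)
        a = vs.generate_vertex_data(table, t1, 3)
        b = vs.generate_vertex_data(table, t2, 3)
        np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_null_marginal_distribution(self, mesh_pair_s2):
        """With zero effects, baseline values at one site are
        Normal(b0 + site, sigma_u^2 + sigma_e^2)."""
        ml, mr = mesh_pair_s2
        spec = vs.EffectSpec(
            b0_mean=0.0,
            amplitudes={k: 0.0 for k in ("b0", "age", "sex", "bw", "time")},
            sigma_u=1.0, sigma_e=1.0, site_offset_sd=0.0,
        )
        truth = vs.sample_truth(ml, mr, spec, 1)
        cfg = vs.CohortConfig(name="X", n_subjects=5000, age_range=(20, 60),
                              visit_counts=(1,), visit_probs=(1.0,), n_sites=1)
        table = vs.sample_design(cfg, 2)
        data = vs.generate_vertex_data(table, truth, 3)
        draws = data.matrix[:, 0]
        _, p = stats.kstest(draws, "norm", args=(0.0, np.sqrt(2.0)))
        assert p > 0.01


class TestTwins:
    def test_pair_count(self, mesh_pair_s2):
        ml, mr = mesh_pair_s2
        table, _, _ = vs.generate_twin_subsample(
            vs.TwinConfig(n_pairs=193), vs.EffectSpec(), ml, mr, seed=1
        )
        assert table["subject_id"].nunique() == 386
        assert table["twin_pair_id"].nunique() == 193

    def test_discordance_sums_to_zero_within_pair(self, mesh_pair_s2):
        ml, mr = mesh_pair_s2
        table, _, _ = vs.generate_twin_subsample(
            vs.TwinConfig(n_pairs=30), vs.EffectSpec(), ml, mr, seed=2
        )
        per_pair = table.drop_duplicates("subject_id").groupby("twin_pair_id")
        assert np.allclose(per_pair["bw_discordance"].sum(), 0.0)
        assert (per_pair["pair_mean_bw"].nunique() == 1).all()

    def test_zero_discordance_identical_bw(self, mesh_pair_s2):
        ml, mr = mesh_pair_s2
        table, data, truth = vs.generate_twin_subsample(
            vs.TwinConfig(n_pairs=20, discordance_sd_g=0.0),
            vs.EffectSpec(sigma_u=0.0, sigma_e=0.0, site_offset_sd=0.0),
            ml, mr, seed=3,
        )
        subj = table.drop_duplicates("subject_id")
        assert (subj.groupby("twin_pair_id")["bw"].nunique() == 1).all()
        # identical covariates and zero noise: co-twins' rows at time 0 match
        base = table[table["time"] == 0]
        for _, grp in base.groupby("twin_pair_id"):
            rows = data.matrix[grp.index.to_numpy()]
            np.testing.assert_allclose(rows[0], rows[1], atol=1e-9)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            vs.TwinConfig(n_pairs=0)
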