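import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vertexspan as vs
from vertexspan.inference import find_clusters, meta_analyze_maps
from vertexspan.models import EffectMap
from vertexspan.surface import mesh_adjacency

from conftest import smooth_random_map
from oracles import bh_stepup_bruteforce


def _slp_map(v2):
    return np.zeros(v2)


def _as_effect_map(log10p, beta=None):
    v = len(log10p)
    beta = np.sign(log10p) if beta is None else beta
    return EffectMap(
        estimate=beta, se=np.ones(v), tstat=np.sign(log10p) * np.abs(log10p),
        df=100, log10p=log10p, contrast="bw",
    )


class TestFindClusters:
    def test_no_supra_threshold(self, mesh_pair_s2):
        ml, mr = mesh_pair_s2
        result = find_clusters(_slp_map(2 * ml.n_vertices), ml, mr, cft=2.0)
        assert result.n_clusters == 0
        assert not result.significant_vertices(0.025).any()

    def test_contiguous_cap_single_cluster(self, mesh_pair_s2):
        ml, mr = mesh_pair_s2
        v = ml.n_vertices
        center = ml.vertex_coords[0]
        order = np.argsort(-(ml.vertex_coords @ center))
        cap = order[:40]
        slp = _slp_map(2 * v)
        slp[cap] = 5.0
        result = find_clusters(slp, ml, mr, cft=2.0)
        assert result.n_clusters == 1
        assert result.table.iloc[0]["size"] == 40
        assert result.table.iloc[0]["hemisphere"] == "left"
        assert result.table.iloc[0]["sign"] == 1

    def test_two_caps_joined_by_subthreshold_vertex(self, mesh_pair_s2):
        """Two supra-threshold neighbors of a sub-threshold bridge vertex
        form two clusters, not one."""
        ml, mr = mesh_pair_s2
        adj = mesh_adjacency(ml)
        bridge = 0
        nbrs = adj[bridge].indices
        a, b = None, None
        for i in nbrs:
            for j in nbrs:
                if i != j and adj[i, j] == 0:
                    a, b = i, j
                    break
            if a is not None:
                break
        slp = _slp_map(2 * ml.n_vertices)
        slp[[a, b]] = 5.0
        result = find_clusters(slp, ml, mr, cft=2.0)
        assert result.n_clusters == 2

    def test_opposite_signs_separate_clusters(self, mesh_pair_s2):
        ml, mr = mesh_pair_s2
        adj = mesh_adjacency(ml)
        nbr = adj[0].indices[0]
        slp = _slp_map(2 * ml.n_vertices)
        slp[0], slp[nbr] = 5.0, -5.0
        result = find_clusters(slp, ml, mr, cft=2.0)
        assert result.n_clusters == 2
        assert set(result.table["sign"]) == {1, -1}

    def test_invariant_under_vertex_relabeling(self, mesh_pair_s2):
        ml, mr = mesh_pair_s2
        v = ml.n_vertices
        rng = np.random.default_rng(5)
        perm = rng.permutation(v)
        inv = np.empty(v, dtype=int)
        inv[perm] = np.arange(v)
        relabeled = vs.SurfaceMesh(ml.vertex_coords[perm], inv[ml.faces], "left")
        slp = _slp_map(2 * v)
        slp[:60] = np.where(rng.random(60) < 0.5, 4.0, 0.0)
        result = find_clusters(slp, ml, mr, cft=2.0)
        slp_perm = slp.copy()
        slp_perm[:v] = slp[:v][perm]
        result_perm = find_clusters(slp_perm, relabeled, mr, cft=2.0)
        assert sorted(result.table["size"]) == sorted(result_perm.table["size"])


class TestClusterwiseP:
    def test_strong_cap_effect_hits_p_floor(self, mesh_pair_s2):
        ml, mr = mesh_pair_s2
        spec = vs.EffectSpec(
            amplitudes={"b0": 1.0, "age": 1.0, "sex": 0.5, "bw": 6.0, "time": -0.3},
            cap_effects={"bw": 0.8},
        )
        truth = vs.sample_truth(ml, mr, spec, 1)
        table = vs.sample_design(vs.lcbc_like(150), 2)
        data = vs.generate_vertex_data(table, truth, 3)
        table, _ = vs.standardize_covariates(table, ["baseline_age", "bw", "time"])
        result = vs.clusterwise_p(data, table, vs.ModelSpec(), n_null=100, seed=4)
        assert result.table["p"].min() == pytest.approx(1 / 101)
        sig = result.significant_vertices(0.025)
        cap = truth.cap_masks["bw"]
        # the significant set recovers most of the true cap
        assert (sig & cap).sum() / cap.sum() > 0.6

    def test_n_null_validated(self, small_cohort):
        table, data, *_ = small_cohort
        with pytest.raises(ValueError):
            vs.clusterwise_p(data, table, vs.ModelSpec(), n_null=50, seed=1)

    def test_non_permutable_contrast(self, small_cohort):
        table, data, *_ = small_cohort
        # time varies within subject: no subject-constant factor to permute
        spec = vs.ModelSpec(contrast="time", covariates=("baseline_age", "sex", "site"))
        with pytest.raises(ValueError, match="subject-constant"):
            vs.clusterwise_p(data, table, spec, n_null=100, seed=1)


class TestSpatialCorrelation:
    def test_self_and_negation(self, mesh_pair_s2):
        ml, mr = mesh_pair_s2
        m = smooth_random_map(ml, mr, 1)
        assert vs.spatial_correlation(m, m) == pytest.approx(1.0)
        assert vs.spatial_correlation(m, -m) == pytest.approx(-1.0)

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError):
            vs.spatial_correlation(np.ones(100), np.arange(100.0))

    def test_independent_smooth_maps_mostly_weak(self, mesh_pair_s3):
        ml, mr = mesh_pair_s3
        rs = []
        for seed in range(40):
            a = smooth_random_map(ml, mr, 1000 + seed, iterations=10)
            b = smooth_random_map(ml, mr, 2000 + seed, iterations=10)
            rs.append(abs(vs.spatial_correlation(a, b)))
        assert np.mean(np.array(rs) < 0.25) >= 0.9


class TestSpinTest:
    def test_self_comparison_hits_floor(self, mesh_pair_s3):
        ml, mr = mesh_pair_s3
        null = vs.build_spin_null(ml, mr, 200, seed=3)
        m = smooth_random_map(ml, mr, 4)
        comp = vs.spin_test(m, m, null)
        assert comp.r == pytest.approx(1.0)
        assert comp.p_spin == pytest.approx(1 / 201)

    def test_invariance_to_shift_and_scale(self, mesh_pair_s3):
        ml, mr = mesh_pair_s3
        null = vs.build_spin_null(ml, mr, 100, seed=5)
        a = smooth_random_map(ml, mr, 6)
        b = smooth_random_map(ml, mr, 7)
        base = vs.spin_test(a, b, null)
        shifted = vs.spin_test(a, 3.0 * b + 10.0, null)
        assert shifted.p_spin == base.p_spin
        assert shifted.r == pytest.approx(base.r)

    def test_mesh_mismatch(self, mesh_pair_s2):
        ml, mr = mesh_pair_s2
        null = vs.build_spin_null(ml, mr, 10, seed=1)
        with pytest.raises(ValueError):
            vs.spin_test(np.zeros(10), np.zeros(10), null)


class TestFDR:
    def test_enumerated_example(self):
        np.testing.assert_allclose(vs.fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert vs.fdr_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_equal(self):
        np.testing.assert_allclose(vs.fdr_adjust([0.04] * 5), [0.04] * 5)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            vs.fdr_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(deadline=None, derandomize=True)
    def test_matches_bruteforce_stepup(self, ps):
        q = vs.fdr_adjust(ps)
        q_ref = bh_stepup_bruteforce(ps)
        np.testing.assert_allclose(q, q_ref, atol=1e-12)
        assert np.all(q >= np.asarray(ps) - 1e-12)


class TestMetaAnalysis:
    def test_identical_maps(self):
        m = _as_effect_map(np.array([1.0, -2.0, 0.5]), beta=np.array([2.0, -1.0, 0.3]))
        meta = meta_analyze_maps([m, m])
        np.testing.assert_allclose(meta.estimate, m.estimate)
        np.testing.assert_allclose(meta.se, m.se / np.sqrt(2))

    def test_opposite_maps_cancel(self):
        a = _as_effect_map(np.array([1.0]), beta=np.array([2.0]))
        b = _as_effect_map(np.array([-1.0]), beta=np.array([-2.0]))
        meta = meta_analyze_maps([a, b])
        np.testing.assert_allclose(meta.estimate, [0.0], atol=1e-12)

    def test_hand_computed_weights(self):
        betas = [2.0, 4.0, 0.0]
        ses = [1.0, 2.0, 1.0]
        maps = []
        for beta, se in zip(betas, ses):
            maps.append(EffectMap(
                estimate=np.array([beta]), se=np.array([se]),
                tstat=np.array([beta / se]), df=50, log10p=np.array([0.0]),
                contrast="bw",
            ))
        meta = meta_analyze_maps(maps)
        assert meta.estimate[0] == pytest.approx((2 + 1 + 0) / (1 + 0.25 + 1))

    def test_single_map_identity(self):
        m = _as_effect_map(np.array([1.0, 2.0]), beta=np.array([0.5, 0.7]))
        meta = meta_analyze_maps([m])
        np.testing.assert_allclose(meta.estimate, m.estimate)
        np.testing.assert_allclose(meta.se, m.se)

    def test_zero_se_flagged(self):
        a = _as_effect_map(np.array([1.0, 1.0]))
        a.se = np.array([1.0, 0.0])
        b = _as_effect_map(np.array([1.0, 1.0]))
        meta = meta_analyze_maps([a, b])
        assert meta.degenerate[1] and not meta.degenerate[0]
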