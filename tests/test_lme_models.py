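import numpy as np
import pandas as pd
import pytest

import vertexspan as vs
from vertexspan.lme import fit_mass_lme, whiten
from vertexspan.models import build_design

from oracles import profiled_gls_oracle


def _small_dataset(seed, n_subjects=12, n_visits=2, p_extra=2, icc=0.5):
    rng = np.random.default_rng(seed)
    n = n_subjects * n_visits
    groups = np.repeat(np.arange(n_subjects), n_visits)
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p_extra))])
    beta = rng.standard_normal(p_extra + 1)
    u = rng.standard_normal(n_subjects) * np.sqrt(icc)
    y = X @ beta + u[groups] + rng.standard_normal(n) * np.sqrt(1 - icc)
    return X, y, groups


class TestAgainstOracles:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_profiled_gls(self, seed):
        """The vectorized profiled-ML fit must agree with a dense
        grid-search GLS oracle to high precision."""
        X, y, groups = _small_dataset(seed)
        res = fit_mass_lme(X, y[:, None], groups)
        beta_o, se_o, t_o, rho_o = profiled_gls_oracle(X, y, groups)
        np.testing.assert_allclose(res.beta[:, 0], beta_o, rtol=1e-5, atol=1e-5)
        np.testing.assert_allclose(res.se[:, 0], se_o, rtol=1e-5, atol=1e-5)
        np.testing.assert_allclose(res.beta[:, 0] / res.se[:, 0], t_o, rtol=1e-5, atol=1e-5)

    def test_matches_statsmodels_mixedlm(self):
        """Cross-check beta and the ML log-likelihood against an
        independent mixed-model implementation."""
        import statsmodels.api as sm

        X, y, groups = _small_dataset(99, n_subjects=30, n_visits=3)
        res = fit_mass_lme(X, y[:, None], groups)
        m = sm.MixedLM(y, X, groups=groups).fit(reml=False)
        np.testing.assert_allclose(res.beta[:, 0], m.fe_params, rtol=1e-4, atol=1e-4)
        np.testing.assert_allclose(res.loglik[0], m.llf, rtol=1e-6)


class TestModelProperties:
    def test_scale_equivariance(self):
        X, y, groups = _small_dataset(3, n_subjects=20)
        r1 = fit_mass_lme(X, y[:, None], groups)
        r2 = fit_mass_lme(X, (7.0 * y)[:, None], groups)
        np.testing.assert_allclose(r2.beta, 7.0 * r1.beta, rtol=1e-10)
        np.testing.assert_allclose(r2.se, 7.0 * r1.se, rtol=1e-10)
        np.testing.assert_allclose(r2.beta / r2.se, r1.beta / r1.se, rtol=1e-10)

    def test_sigma_u_zero_collapses_to_ols(self, mesh_pair_s2):
        ml, mr = mesh_pair_s2
        spec = vs.EffectSpec(sigma_u=0.0)
        truth = vs.sample_truth(ml, mr, spec, 5)
        table = vs.sample_design(vs.lcbc_like(40), 6)
        data = vs.generate_vertex_data(table, truth, 7)
        table, _ = vs.standardize_covariates(table, ["baseline_age", "bw", "time"])
        X, _, ci = build_design(table, vs.ModelSpec())
        res = fit_mass_lme(X, data.matrix, table["subject_id"].to_numpy())
        ols = np.linalg.lstsq(X, data.matrix, rcond=None)[0]
        # with no true subject variance the ML boundary estimate rho = 0 is
        # selected at a large share of vertices, and there the fit IS OLS
        boundary = res.icc == 0.0
        assert boundary.mean() > 0.3
        np.testing.assert_allclose(res.beta[:, boundary], ols[:, boundary], atol=1e-6)
        # the remaining vertices carry only small sampling-noise icc
        assert np.median(res.icc) < 0.1
        np.testing.assert_allclose(res.beta, ols, atol=0.15)

    def test_single_observation_per_subject_is_ols_exactly(self):
        rng = np.random.default_rng(8)
        n = 50
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.standard_normal((n, 3))
        res = fit_mass_lme(X, y, np.arange(n))
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.all(res.icc == 0.0)
        np.testing.assert_allclose(res.beta, ols, atol=1e-12)

    def test_vertex_permutation_equivariance(self):
        X, y, groups = _small_dataset(4, n_subjects=15)
        Y = np.column_stack([y, 2 * y, y**2])
        perm = np.array([2, 0, 1])
        r1 = fit_mass_lme(X, Y, groups)
        r2 = fit_mass_lme(X, Y[:, perm], groups)
        np.testing.assert_allclose(r2.beta, r1.beta[:, perm], rtol=1e-12)

    def test_rank_deficient_design_raises(self):
        X, y, groups = _small_dataset(5)
        X = np.column_stack([X, X[:, 1]])
        with pytest.raises(np.linalg.LinAlgError):
            fit_mass_lme(X, y[:, None], groups)


class TestWhitening:
    def test_whitened_ols_equals_gls(self):
        """OLS after whitening at rho must reproduce the GLS fit at rho."""
        from oracles import dense_gls

        X, y, groups = _small_dataset(6, n_subjects=15)
        rho = 0.4
        Xw, yw = whiten(X, groups, rho), whiten(y, groups, rho)
        beta_w = np.linalg.lstsq(Xw, yw, rcond=None)[0]
        beta_gls = dense_gls(X, y, groups, rho)[0]
        np.testing.assert_allclose(beta_w, beta_gls, rtol=1e-10)


class TestDesignBuilder:
    def test_interaction_contrast_includes_lower_order_terms(self, small_cohort):
        table, *_ = small_cohort
        spec = vs.ModelSpec(contrast="bw:time")
        X, names, ci = build_design(table, spec)
        assert names[ci] == "bw:time"
        assert "bw" in names and "time" in names
        spec3 = vs.ModelSpec(contrast="baseline_age:time:bw")
        _, names3, ci3 = build_design(table, spec3)
        for required in ("bw", "baseline_age:time", "baseline_age:bw", "time:bw"):
            assert required in names3
        assert names3[ci3] == "baseline_age:time:bw"

    def test_site_dummy_coded(self, small_cohort):
        table, *_ = small_cohort
        _, names, _ = build_design(table, vs.ModelSpec())
        n_sites = table["site"].nunique()
        assert sum(n.startswith("site_") for n in names) == n_sites - 1


class TestFitVertexLME:
    def test_effect_map_consistency(self, small_cohort):
        table, data, truth, _ = small_cohort
        emap = vs.fit_vertex_lme(data, table, vs.ModelSpec())
        assert np.all(np.sign(emap.estimate) == np.sign(emap.tstat))
        assert np.all(np.abs(emap.log10p) >= 0)
        assert np.all(np.isfinite(emap.estimate))
        assert emap.df == emap.n_obs - len(build_design(table, vs.ModelSpec())[1])

    def test_degenerate_vertex_flagged(self, small_cohort):
        table, data, *_ = small_cohort
        bad = data.matrix.copy()
        bad[0, 5] = np.nan
        data_bad = vs.VertexData(data.measure, bad, data.mesh_left, data.mesh_right,
                                 data.observation_ids)
        emap = vs.fit_vertex_lme(data_bad, table, vs.ModelSpec())
        assert emap.degenerate[5]
        assert np.isnan(emap.estimate[5])
        assert np.isfinite(emap.estimate[4])


class TestTwinDiscordance:
    def test_too_few_pairs_refused(self, mesh_pair_s2):
        ml, mr = mesh_pair_s2
        table, data, _ = vs.generate_twin_subsample(
            vs.TwinConfig(n_pairs=5), vs.EffectSpec(), ml, mr, seed=1
        )
        table, _ = vs.standardize_covariates(
            table, ["baseline_age", "bw_discordance", "pair_mean_bw", "time"],
            within=None,
        )
        with pytest.raises(ValueError, match="pairs"):
            vs.fit_twin_discordance(data, table)

    def test_cap_effect_sign_recovered(self, mesh_pair_s2):
        ml, mr = mesh_pair_s2
        spec = vs.EffectSpec(
            amplitudes={"b0": 1.0, "age": 0.5, "sex": 0.3, "bw": 0.0,
                        "time": -0.2, "discord": 0.8},
            cap_effects={"discord": 0.7},
        )
        table, data, truth = vs.generate_twin_subsample(
            vs.TwinConfig(n_pairs=60), spec, ml, mr, seed=3
        )
        table, _ = vs.standardize_covariates(
            table, ["baseline_age", "bw_discordance", "pair_mean_bw", "time"],
            within=None,
        )
        emap = vs.fit_twin_discordance(data, table)
        cap = truth.cap_masks["discord"]
        assert np.mean(emap.estimate[cap] > 0) > 0.8


class TestSplineSensitivity:
    def test_agrees_with_linear_model_under_linear_truth(self, small_cohort):
        table, data, *_ = small_cohort
        rng = np.random.default_rng(0)
        parcellation = rng.integers(0, 8, size=data.n_vertices)
        linear = vs.fit_vertex_lme(data, table, vs.ModelSpec())
        spline = vs.fit_spline_sensitivity(data, table, vs.ModelSpec(), parcellation)
        region_linear = np.array(
            [linear.estimate[parcellation == r].mean() for r in range(8)]
        )
        diffs = np.abs(spline.estimate - region_linear) / spline.se
        assert diffs.mean() < 0.5

    def test_quadratic_age_confounding_bias_reduced(self, mesh_pair_s2):
        """With a nonlinear age trend and age-BW confounding, the spline
        model should be less biased for the (zero) BW effect."""
        ml, mr = mesh_pair_s2
        spec = vs.EffectSpec(
            amplitudes={"b0": 0.0, "age": 2.0, "sex": 0.0, "bw": 0.0, "time": 0.0},
            quadratic_age=1.0, sigma_u=0.3, sigma_e=0.3, site_offset_sd=0.0,
        )
        truth = vs.sample_truth(ml, mr, spec, 4)
        table = vs.sample_design(vs.lcbc_like(150), 5)
        # confound BW with age so a misfit age trend leaks into the BW term
        table["bw"] = 3.4 + 0.01 * (table["baseline_age"] - 40) + \
            np.random.default_rng(6).normal(0, 0.2, len(table))
        data = vs.generate_vertex_data(table, truth, 7)
        table, _ = vs.standardize_covariates(table, ["baseline_age", "bw", "time"])
        parcellation = np.zeros(data.n_vertices, dtype=int)
        parcellation[data.n_vertices // 2:] = 1
        linear = vs.fit_vertex_lme(data, table, vs.ModelSpec())
        spline = vs.fit_spline_sensitivity(data, table, vs.ModelSpec(), parcellation)
        linear_region = np.array(
            [linear.estimate[parcellation == r].mean() for r in (0, 1)]
        )
        assert np.abs(spline.estimate).mean() < np.abs(linear_region).mean()
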