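"""Event-related GLM: design build, OLS, pooling, thresholding, overlap."""

import numpy as np
import pytest
from scipy import stats

from dotppi import glm
from dotppi.glm import (DesignMatrix, StatMap, build_design, fit_glm,
                        fixed_effects, overlap_map, random_effects,
                        signflip_null_maps, threshold_cluster, t_to_z)
from dotppi.synth import Event, EventDesign
from dotppi.volume import VolumetricTimeSeries


def _design(events, length_s=120.0):
    return EventDesign(run_id=0, events=events, length_s=length_s)


def _series(mat):
    """(T, V) matrix -> VolumetricTimeSeries with V voxels on a line."""
    arr = np.asarray(mat, dtype=float).T.reshape(-1, 1, 1, mat.shape[0])
    return VolumetricTimeSeries(data=arr, affine=np.eye(4), rate=1.0)


class TestBuildDesign:
    def test_single_noise_event_is_shifted_boxcar_response(self, hrf1):
        d = _design([Event("noise", 10.0, 2.0)])
        dm = build_design(d, hrf1, 1.0, 120)
        assert dm.names == ["noise", "intercept"]
        col = dm.matrix[:, 0]
        assert np.all(col[:12] == 0)       # 2-s delay after the 10-s onset
        assert np.any(col[12:] != 0)

    def test_button_event_column_is_impulse_response(self, hrf1):
        d = _design([Event("noise", 5.0, 2.0), Event("button_left", 20.0, 0.0)])
        dm = build_design(d, hrf1, 1.0, 120)
        col = dm.matrix[:, dm.names.index("button_left")]
        k = hrf1.samples.size
        assert np.allclose(col[20:20 + k], hrf1.samples[:100])

    def test_full_default_design_has_five_condition_columns(self, hrf1,
                                                            default_designs):
        dm = build_design(default_designs[0], hrf1, 1.0,
                          int(default_designs[0].length_s))
        conds = [n for n in dm.names if n != "intercept"]
        assert sorted(conds) == sorted(["easy", "complex", "noise",
                                        "button_left", "button_right"])
        assert np.all(np.any(dm.matrix != 0, axis=0))

    def test_event_beyond_series_rejected(self, hrf1):
        d = _design([Event("noise", 200.0, 2.0)])
        with pytest.raises(ValueError, match="beyond"):
            build_design(d, hrf1, 1.0, 120)


class TestFitGLM:
    def _toy_design(self, n=80, p=3, seed=0):
        rng = np.random.default_rng(seed)
        X = np.column_stack([rng.standard_normal((n, p - 1)), np.ones(n)])
        return DesignMatrix(matrix=X, names=[f"x{i}" for i in range(p - 1)]
                            + ["intercept"], rate=1.0)

    def test_exact_recovery_without_noise(self):
        dm = self._toy_design()
        beta_true = np.array([[1.5, -2.0, 0.5], [0.0, 3.0, 1.0]]).T  # p x V
        Y = dm.matrix @ beta_true
        fit = fit_glm(_series(Y), dm)
        assert np.allclose(fit.beta, beta_true.T, atol=1e-8)
        assert np.allclose(fit.residual_variance, 0.0, atol=1e-12)
        assert fit.dof == 80 - 3

    def test_matches_brute_force_normal_equations(self):
        """5-voxel oracle: solve X'X b = X'y per voxel by hand."""
        rng = np.random.default_rng(3)
        dm = self._toy_design(n=60, seed=3)
        Y = rng.standard_normal((60, 5))
        fit = fit_glm(_series(Y), dm)
        X = dm.matrix
        for v in range(5):
            b = np.linalg.solve(X.T @ X, X.T @ Y[:, v])
            assert np.allclose(fit.beta[v], b, atol=1e-10)
            r = Y[:, v] - X @ b
            assert np.isclose(fit.residual_variance[v],
                              r @ r / (60 - 3), atol=1e-10)

    def test_white_noise_t_statistics_match_student_t(self):
        rng = np.random.default_rng(11)
        dm = self._toy_design(n=40, seed=5)
        Y = rng.standard_normal((40, 2000))
        fit = fit_glm(_series(Y), dm)
        c = np.array([1.0, 0.0, 0.0])
        t_vals = (fit.beta @ c) / np.sqrt(
            fit.residual_variance * (c @ fit.xtx_inv @ c))
        dof = fit.dof
        expected = stats.t(dof).expect(lambda x: abs(x))
        assert np.mean(np.abs(t_vals)) == pytest.approx(expected, rel=0.1)

    def test_adding_orthogonal_regressor_keeps_other_betas(self):
        n = 100
        t = np.arange(n)
        x1 = np.sin(2 * np.pi * t / 20)
        x2 = np.cos(2 * np.pi * t / 20)  # orthogonal over complete periods
        rng = np.random.default_rng(8)
        Y = np.outer(x1, [2.0, -1.0]) + rng.standard_normal((n, 2))
        dm1 = DesignMatrix(matrix=x1[:, None], names=["x1"], rate=1.0)
        dm2 = DesignMatrix(matrix=np.column_stack([x1, x2]),
                           names=["x1", "x2"], rate=1.0)
        f1 = fit_glm(_series(Y), dm1)
        f2 = fit_glm(_series(Y), dm2)
        assert np.allclose(f1.beta[:, 0], f2.beta[:, 0], atol=1e-8)

    def test_rank_deficient_design_names_columns(self):
        x = np.random.default_rng(0).standard_normal(50)
        dm = DesignMatrix(matrix=np.column_stack([x, 2 * x]),
                          names=["a", "b"], rate=1.0)
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_glm(_series(np.zeros((50, 2))), dm)


class TestFixedEffects:
    def _noisy_run(self, beta, seed, n=120):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        dm = DesignMatrix(matrix=np.column_stack([x, np.ones(n)]),
                          names=["x", "intercept"], rate=1.0)
        Y = np.outer(x, [beta]) + 0.5 * rng.standard_normal((n, 1))
        return fit_glm(_series(Y), dm)

    def test_single_run_reduces_to_t_to_z(self):
        fit = self._noisy_run(1.0, seed=0)
        smap = fixed_effects([fit], {"x": 1.0})
        c = np.array([1.0, 0.0])
        t = (fit.beta @ c) / np.sqrt(fit.residual_variance
                                     * (c @ fit.xtx_inv @ c))
        assert np.allclose(smap.values.ravel()[0],
                           t_to_z(t, fit.dof)[0], atol=1e-6)

    def test_pooling_beats_single_run(self):
        fits = [self._noisy_run(1.0, seed=s) for s in range(4)]
        pooled = fixed_effects(fits, {"x": 1.0}).values.ravel()[0]
        singles = [fixed_effects([f], {"x": 1.0}).values.ravel()[0]
                   for f in fits]
        assert np.isfinite(pooled)
        assert pooled > max(singles)

    def test_zero_contrast_gives_zero_map(self):
        fit = self._noisy_run(1.0, seed=1)
        assert np.all(fixed_effects([fit], {"x": 0.0}).values == 0)

    def test_unknown_contrast_column_rejected(self):
        fit = self._noisy_run(1.0, seed=2)
        with pytest.raises(ValueError, match="unknown"):
            fixed_effects([fit], {"nope": 1.0})


class TestRandomEffects:
    def test_zero_variance_hits_documented_cap(self):
        maps = [np.full((3, 3, 3), 2.0)] * 4
        out = random_effects(maps)
        assert np.all(out.values == glm.Z_CAP)

    def test_null_false_positive_rate(self):
        rng = np.random.default_rng(17)
        maps = [rng.standard_normal((25, 20, 20)) for _ in range(10)]
        out = random_effects(maps)
        frac = np.mean(np.abs(out.values) > 1.96)
        assert frac == pytest.approx(0.05, abs=0.01)

    def test_sign_flip_antisymmetry(self):
        rng = np.random.default_rng(2)
        maps = [rng.standard_normal((4, 4, 4)) for _ in range(5)]
        a = random_effects(maps).values
        b = random_effects([-m for m in maps]).values
        assert np.allclose(a, -b)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            random_effects([np.zeros((2, 2, 2))] * 2)


class TestThresholdCluster:
    def test_forming_threshold_is_3_09_at_p_001(self):
        assert stats.norm.isf(0.001) == pytest.approx(3.0902, abs=1e-4)
        assert round(float(stats.norm.isf(0.001)), 1) == 3.1

    def test_all_subthreshold_gives_empty_map(self):
        smap = StatMap(values=np.ones((5, 5, 5)), mask=np.ones((5, 5, 5), bool))
        nulls = [np.zeros((5, 5, 5))] * 100
        out = threshold_cluster(smap, 0.001, 0.05, nulls)
        assert not out.values.any()

    def test_large_cluster_survives_small_null(self):
        rng = np.random.default_rng(12)
        # null: pure-noise subject maps -> sign-flip permutation nulls
        subj = [rng.standard_normal((12, 12, 12)) for _ in range(8)]
        nulls = signflip_null_maps(subj, 100, seed=0)
        vals = np.zeros((12, 12, 12))
        vals[2:8, 2:8, 2:8] = 5.0   # 216-voxel cluster
        smap = StatMap(values=vals, mask=np.ones(vals.shape, bool))
        out = threshold_cluster(smap, 0.001, 0.05, nulls)
        assert (out.values > 0).sum() == 216

    def test_no_null_maps_rejected(self):
        smap = StatMap(values=np.zeros((3, 3, 3)), mask=np.ones((3, 3, 3), bool))
        with pytest.raises(ValueError, match="permutation"):
            threshold_cluster(smap, 0.001, 0.05, [])

    def test_familywise_error_control_on_null_data(self):
        """On null datasets the corrected map should rarely keep any cluster."""
        rng = np.random.default_rng(99)
        n_fp = 0
        n_datasets = 50
        for _ in range(n_datasets):
            subj = [rng.standard_normal((10, 10, 10)) for _ in range(8)]
            group = random_effects(subj)
            nulls = signflip_null_maps(subj, 60, seed=int(rng.integers(2**31)))
            out = threshold_cluster(group, 0.001, 0.05, nulls)
            n_fp += bool(out.values.any())
        assert n_fp / n_datasets <= 0.10

    def test_cluster_p_one_keeps_everything_above_forming_threshold(self):
        rng = np.random.default_rng(5)
        vals = rng.standard_normal((8, 8, 8)) + 2.0
        smap = StatMap(values=vals, mask=np.ones(vals.shape, bool))
        nulls = [np.full(vals.shape, 10.0)] * 50
        out = threshold_cluster(smap, 0.001, 1.0, nulls)
        assert np.array_equal(out.values > 0, vals > stats.norm.isf(0.001))


class TestOverlapMap:
    def _map(self, vals):
        return StatMap(values=vals, mask=np.ones(vals.shape, bool))

    def test_single_subject_everywhere_above(self):
        out = overlap_map([self._map(np.full((3, 3, 3), 5.0))], 1.6)
        assert np.all(out == 1)

    def test_infinite_threshold_gives_zero(self):
        out = overlap_map([self._map(np.full((3, 3, 3), 5.0))], np.inf)
        assert np.all(out == 0)

    def test_mean_count_matches_binomial_oracle(self):
        rng = np.random.default_rng(0)
        maps = [self._map(rng.standard_normal((25, 20, 20)))
                for _ in range(10)]
        out = overlap_map(maps, 1.6)
        expected = 10 * stats.norm.sf(1.6)   # 0.548
        assert out.mean() == pytest.approx(expected, abs=0.05)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            overlap_map([], 1.6)
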