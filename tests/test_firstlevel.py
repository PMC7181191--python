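"""Subject-level GLM: HRF shape, design assembly, estimation, residualization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mbfmri.core import VolumeSeries
from mbfmri.firstlevel import (Contrast, DesignMatrix, build_design,
                               canonical_hrf, compcor_regressors,
                               contrast_tmap, dct_highpass_basis, fit_glm,
                               gaussian_smooth, residualize_for_rest)
from mbfmri.sequences import SequenceSpec
from mbfmri.simulate import NoiseModel, generate_task_design, simulate_subject


def toy_series(Y, tr=1.0):
    """Wrap a (T, V) matrix as a 1 x V x 1 x T VolumeSeries."""
    T, V = Y.shape
    data = Y.T.reshape(1, V, 1, T)
    return VolumeSeries(data=data.astype(float), affine=np.eye(4), tr=tr,
                        mask=np.ones((1, V, 1), bool))


class TestCanonicalHrf:
    def test_shape_properties(self):
        dt = 0.1
        h = canonical_hrf(dt)
        assert h[0] == 0.0
        assert h.max() == pytest.approx(1.0)
        # BOLD response peaks about 5 s after stimulation
        assert np.argmax(h) * dt == pytest.approx(5.0, abs=0.3)
        # one positive lobe then one undershoot: exactly one sign change
        signs = np.sign(h[np.abs(h) > 1e-12])
        assert (np.diff(signs) != 0).sum() == 1

    def test_rejects_bad_dt(self):
        with pytest.raises(ValueError):
            canonical_hrf(0.0)
        with pytest.raises(ValueError):
            canonical_hrf(40.0)


@pytest.fixture(scope="module")
def spec():
    return SequenceSpec(name="s", tr=2.45, mb_factor=1, sense_factor=2,
                        voxel_dims=(2.7,) * 3, flip_angle=79,
                        n_volumes=200, n_slices=44)


@pytest.fixture(scope="module")
def design():
    return generate_task_design(seed=1)


class TestBuildDesign:

    @pytest.mark.parametrize("variant,n_task", [
        ("canonical", 2),
        ("canonical+temporal", 4),
        ("canonical+temporal+dispersion", 6),
    ])
    def test_task_column_count(self, design, spec, variant, n_task):
        X = build_design(design, spec, hrf_variant=variant)
        assert len(X.task_columns()) == n_task

    def test_column_layout(self, design, spec):
        motion = np.random.default_rng(0).standard_normal((200, 6))
        cc = np.random.default_rng(1).standard_normal((200, 10))
        X = build_design(design, spec, motion=motion, compcor=cc)
        # 2 task + 6 motion + 10 compcor + DCT + intercept
        n_dct = int(np.floor(2 * 200 * 2.45 / 128))   # independent formula
        assert n_dct == 7
        assert X.n_regressors == 2 + 6 + 10 + n_dct + 1
        assert X.column_names[-1] == "intercept"
        # task columns mean-centred
        for i in X.task_columns():
            assert abs(X.matrix[:, i].mean()) < 1e-12

    def test_dct_count_formula(self):
        for n, tr, cutoff in [(200, 2.45, 128), (780, 0.63, 128), (100, 1.0, 128)]:
            b = dct_highpass_basis(n, tr, cutoff)
            assert b.shape == (n, int(np.floor(2 * n * tr / cutoff)))

    def test_rank_deficiency_names_columns(self, design, spec):
        motion = np.ones((200, 2))          # duplicated constant columns
        with pytest.raises(ValueError, match="collinear"):
            build_design(design, spec, motion=np.column_stack([motion[:, 0],
                                                               motion[:, 0]]))

    def test_motion_row_mismatch_rejected(self, design, spec):
        with pytest.raises(ValueError, match="n_volumes"):
            build_design(design, spec, motion=np.zeros((100, 6)))


class TestCompCor:
    def test_recovers_planted_shared_component(self):
        rng = np.random.default_rng(0)
        tc = rng.standard_normal(120)
        Y = np.outer(tc, rng.uniform(0.5, 1.5, 40)) + \
            0.01 * rng.standard_normal((120, 40))
        series = toy_series(Y)
        comps = compcor_regressors(series, np.ones((1, 40, 1), bool), k=3)
        r = np.corrcoef(comps[:, 0], tc)[0, 1]
        assert abs(r) > 0.99

    def test_k_zero_and_orthogonality(self):
        rng = np.random.default_rng(1)
        series = toy_series(rng.standard_normal((80, 30)))
        mask = np.ones((1, 30, 1), bool)
        assert compcor_regressors(series, mask, k=0).shape == (80, 0)
        comps = compcor_regressors(series, mask, k=5)
        gram = comps.T @ comps
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_mask_errors(self):
        series = toy_series(np.random.default_rng(0).standard_normal((50, 3)))
        with pytest.raises(ValueError, match="empty"):
            compcor_regressors(series, np.zeros((1, 3, 1), bool), k=2)
        with pytest.raises(ValueError, match="< k"):
            compcor_regressors(series, np.ones((1, 3, 1), bool), k=5)


def _toy_fit():
    """5-timepoint, 2-regressor toy with hand-computable OLS solution."""
    X = np.array([[1.0, 1.0], [1.0, 2.0], [1.0, 3.0], [1.0, 4.0], [1.0, 5.0]])
    y = np.array([2.0, 3.0, 5.0, 4.0, 6.0])
    design = DesignMatrix(matrix=X, column_names=["intercept_first", "slope"],
                          tr=1.0)
    series = toy_series(y[:, None])
    fit = fit_glm(series, design, whitening="none")
    beta_hand = np.linalg.solve(X.T @ X, X.T @ y)
    return X, y, design, series, fit, beta_hand


class TestFitGlm:
    def test_ols_matches_normal_equations(self):
        X, y, design, series, fit, beta_hand = _toy_fit()
        assert np.allclose(fit.betas[:, 0, 0, 0], beta_hand, atol=1e-10)
        resid_hand = y - X @ beta_hand
        assert np.allclose(fit.residuals.data[0, 0, 0], resid_hand, atol=1e-10)
        assert fit.dof == 3

    def test_noise_free_data_gives_zero_resms(self):
        X = np.column_stack([np.arange(10.0), np.ones(10)])
        design = DesignMatrix(matrix=X, column_names=["x", "intercept"], tr=1.0)
        y = X @ np.array([2.0, -1.0])
        fit = fit_glm(toy_series(y[:, None]), design, whitening="none")
        assert fit.resms[0, 0, 0] == pytest.approx(0.0, abs=1e-18)
        assert np.allclose(fit.residuals.data, 0.0, atol=1e-10)

    def test_ar1_phi_recovered(self):
        rng = np.random.default_rng(0)
        T, V, phi = 400, 60, 0.5
        innov = rng.standard_normal((T, V))
        noise = np.zeros((T, V))
        for t in range(1, T):
            noise[t] = phi * noise[t - 1] + innov[t]
        X = np.column_stack([rng.standard_normal(T), np.ones(T)])
        design = DesignMatrix(matrix=X, column_names=["x", "intercept"], tr=1.0)
        fit = fit_glm(toy_series(noise), design, whitening="ar1")
        assert fit.autocorr["phi"] == pytest.approx(phi, abs=0.1)

    def test_gls_equals_ols_on_prewhitened_data(self):
        """Whitened GLS must agree with OLS after explicit pre-whitening."""
        from mbfmri.firstlevel import _whitening_matrix
        rng = np.random.default_rng(3)
        T, V = 120, 20
        X = np.column_stack([rng.standard_normal(T), np.ones(T)])
        design = DesignMatrix(matrix=X, column_names=["x", "intercept"], tr=1.0)
        Y = rng.standard_normal((T, V))
        fit = fit_glm(toy_series(Y), design, whitening="ar1")
        phi = fit.autocorr["phi"]
        corr = phi ** np.arange(31)
        W = _whitening_matrix(corr, T)
        beta_manual = np.linalg.pinv(W @ X) @ (W @ Y)
        assert np.allclose(fit.betas[:, 0, :, 0].T, beta_manual.T, atol=1e-8)

    def test_rejects_mismatch_and_nonfinite(self):
        X = DesignMatrix(matrix=np.ones((10, 1)), column_names=["i"], tr=1.0)
        with pytest.raises(ValueError, match="timepoints"):
            fit_glm(toy_series(np.ones((9, 2))), X)
        bad = np.ones((10, 2))
        bad[3, 1] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_glm(toy_series(bad), X, whitening="none")


class TestContrastTmap:
    def test_toy_t_matches_hand_computation(self):
        X, y, design, series, fit, beta_hand = _toy_fit()
        c = Contrast(weights=(0.0, 1.0), name="slope")
        tmap, con = contrast_tmap(fit, c)
        resid = y - X @ beta_hand
        s2 = resid @ resid / 3
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        assert tmap.values[0, 0, 0] == pytest.approx(beta_hand[1] / se,
                                                     abs=1e-8)
        assert con[0, 0, 0] == pytest.approx(beta_hand[1], abs=1e-10)

    def test_equal_betas_give_zero_contrast(self):
        rng = np.random.default_rng(2)
        T = 60
        shared = rng.standard_normal(T)
        X = np.column_stack([shared, shared * 2, np.ones(T)])
        # CA - CC style contrast on proportional columns is rank-deficient;
        # build orthogonal columns with equal true betas instead
        a, b = rng.standard_normal(T), rng.standard_normal(T)
        X = np.column_stack([a, b, np.ones(T)])
        y = a + b + 0.1 * rng.standard_normal(T)
        design = DesignMatrix(matrix=X, column_names=["ca", "cc", "i"], tr=1.0)
        fit = fit_glm(toy_series(y[:, None]), design, whitening="none")
        tmap, _ = contrast_tmap(fit, Contrast(weights=(1.0, -1.0, 0.0)))
        assert abs(tmap.values[0, 0, 0]) < 3.0  # consistent with a null

    def test_null_t_distribution_matches_student(self):
        """White-noise-only fits: voxelwise t values follow Student t(dof)."""
        rng = np.random.default_rng(7)
        T, V = 100, 4000
        X = np.column_stack([rng.standard_normal(T), np.ones(T)])
        design = DesignMatrix(matrix=X, column_names=["x", "intercept"], tr=1.0)
        fit = fit_glm(toy_series(rng.standard_normal((T, V))), design,
                      whitening="none")
        tmap, _ = contrast_tmap(fit, Contrast(weights=(1.0, 0.0)))
        tvals = tmap.values[0, :, 0]
        _, p = stats.kstest(tvals, "t", args=(fit.dof,))
        assert p > 0.01
        # dof accounting: variance of t matches Student t within 10%
        expected_var = fit.dof / (fit.dof - 2)
        assert tvals.var() == pytest.approx(expected_var, rel=0.1)

    def test_zero_variance_voxels_flagged(self):
        X = DesignMatrix(matrix=np.column_stack([np.arange(6.0), np.ones(6)]),
                         column_names=["x", "i"], tr=1.0)
        Y = np.column_stack([np.arange(6.0) * 2 + 1,          # exact fit
                             np.arange(6.0) + 0.3 * np.array([1, -1, 0, 1, -1, 0])])
        fit = fit_glm(toy_series(Y), X, whitening="none")
        tmap, _ = contrast_tmap(fit, Contrast(weights=(1.0, 0.0)))
        valid = tmap.threshold_info["valid_mask"]
        assert not valid[0, 0, 0]                # zero-resms voxel excluded
        assert valid[0, 1, 0]
        assert np.isfinite(tmap.values).all()


class TestResidualize:
    def test_design_span_maps_to_zero(self):
        rng = np.random.default_rng(0)
        T = 50
        X = np.column_stack([rng.standard_normal(T), np.ones(T)])
        design = DesignMatrix(matrix=X, column_names=["x", "i"], tr=1.0)
        Y = X @ rng.standard_normal((2, 8))
        out = residualize_for_rest(toy_series(Y), design)
        assert np.abs(out.data).max() < 1e-10

    def test_orthogonality_and_planted_survival(self):
        rng = np.random.default_rng(1)
        T = 120
        X = np.column_stack([rng.standard_normal(T), np.ones(T)])
        design = DesignMatrix(matrix=X, column_names=["x", "i"], tr=1.0)
        planted = np.sin(np.linspace(0, 9 * np.pi, T))
        Y = X @ rng.standard_normal((2, 10)) \
            + np.outer(planted, rng.uniform(0.5, 1.5, 10)) \
            + 0.05 * rng.standard_normal((T, 10))
        out = residualize_for_rest(toy_series(Y), design)
        resid = out.data[0, :, 0].T
        dots = X.T @ resid
        assert np.abs(dots).max() < 1e-6
        r = np.corrcoef(resid[:, 0], planted)[0, 1]
        assert abs(r) > 0.95


class TestGaussianSmooth:
    def test_identity_at_zero_fwhm(self, sim_run):
        series, _, _ = sim_run
        assert gaussian_smooth(series, 0.0) is series

    def test_mass_conservation(self):
        vol = np.zeros((24, 24, 24))
        vol[12, 12, 12] = 100.0
        sm = gaussian_smooth(vol, 6.0, voxel_sizes=np.array([3.0, 3.0, 3.0]))
        assert sm.sum() == pytest.approx(100.0, abs=1e-6)

    def test_delta_reaches_requested_fwhm(self):
        vol = np.zeros((31, 31, 31))
        vol[15, 15, 15] = 1.0
        sm = gaussian_smooth(vol, 6.0, voxel_sizes=np.array([3.0, 3.0, 3.0]))
        profile = sm[:, 15, 15]
        half = profile.max() / 2
        above = np.nonzero(profile >= half)[0]
        # linear interpolation of the half-maximum crossings, in mm
        lo = above[0] - (profile[above[0]] - half) / \
            (profile[above[0]] - profile[above[0] - 1])
        hi = above[-1] + (profile[above[-1]] - half) / \
            (profile[above[-1]] - profile[above[-1] + 1])
        fwhm_mm = (hi - lo) * 3.0
        assert fwhm_mm == pytest.approx(6.0, abs=1.5)   # half a voxel

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            gaussian_smooth(np.zeros((5, 5, 5)), -1.0, voxel_sizes=np.ones(3))


class TestEffectRecovery:
    def test_contrast_estimate_unbiased_on_simulated_runs(self, phantom,
                                                          spec_mb1):
        """Mean CA-CC amplitude estimate across simulated subjects lands
        within 5% of the planted effect at the activation peak."""
        noise = NoiseModel(thermal_sd_ref=1.0, physio_amplitudes=(0.2, 0.2),
                           drift_amplitude=0.5)
        peak = np.unravel_index(np.argmax(phantom.activation_truth),
                                phantom.grid_shape)
        baseline_pct = None
        estimates = []
        for s in range(10):
            design = generate_task_design(seed=100 + s)
            series, motion = simulate_subject(
                phantom, design, spec_mb1, noise, subject_effect=1.0,
                seed=200 + s, rsn_amplitudes=np.zeros(20))
            X = build_design(design, spec_mb1, motion=motion)
            fit = fit_glm(series, X, whitening="ar1",
                          pool_mask=phantom.gm_mask)
            _, con = contrast_tmap(
                fit, Contrast.from_names(X, "task_CA", "task_CC"))
            base = series.data[peak].mean()
            estimates.append(100.0 * con[peak] / base)
        # planted: 1% signal change at the truth peak
        assert np.mean(estimates) == pytest.approx(1.0, abs=0.05)
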