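"""Synthetic cohort generator: design timing, phantom structure, noise physics."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from mbfmri.sequences import SequenceSpec, TissueRelaxation, steady_state_signal
from mbfmri.simulate import (NoiseModel, generate_phantom,
                             generate_task_design, simulate_cohort,
                             simulate_subject, synthesize_gfactor)


def small_spec(name="test", tr=1.0, n_volumes=500, mb=1, sense=2.0,
               voxel=3.0):
    return SequenceSpec(name=name, tr=tr, mb_factor=mb, sense_factor=sense,
                        voxel_dims=(voxel,) * 3, flip_angle=70.0,
                        n_volumes=n_volumes, n_slices=20)


class TestTaskDesign:
    def test_block_structure(self):
        d = generate_task_design(seed=0)
        assert len(d.onsets) == 26
        assert sum(c == "CA" for c in d.conditions) == 13
        assert sum(c == "CC" for c in d.conditions) == 13
        assert all(dur == 7.0 for dur in d.durations)
        # total stimulus-on time
        assert sum(d.durations) == 26 * 7
        isis = np.diff(d.onsets) - 7.0
        assert np.all(isis >= 8.0) and np.all(isis <= 12.0)
        # run length close to 8 minutes
        assert 420 <= d.session_duration <= 520

    def test_deterministic_and_randomized(self):
        assert generate_task_design(seed=7) == generate_task_design(seed=7)
        a, b = generate_task_design(seed=1), generate_task_design(seed=2)
        assert a.conditions != b.conditions or a.onsets != b.onsets

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            generate_task_design(seed=0, block_s=-1)
        with pytest.raises(ValueError):
            generate_task_design(seed=0, isi_range=(12, 8))


class TestPhantom:
    def test_tissue_masks_disjoint_within_brain(self, phantom):
        overlap = (phantom.gm_mask.astype(int) + phantom.wm_mask
                   + phantom.csf_mask)
        assert overlap.max() == 1
        union = phantom.gm_mask | phantom.wm_mask | phantom.csf_mask
        assert np.all(phantom.brain_mask[union])

    def test_activation_truth_in_gm_with_unit_peak(self, phantom):
        assert np.all(phantom.activation_truth[~phantom.gm_mask] == 0)
        assert phantom.activation_truth.max() == pytest.approx(1.0)

    def test_requested_blob_count(self, phantom):
        structure = ndimage.generate_binary_structure(3, 2)  # 18-connectivity
        _, n = ndimage.label(phantom.activation_truth > 0, structure=structure)
        assert n == 5

    def test_zero_blobs(self):
        ph = generate_phantom(grid_shape=(18, 18, 18), n_activation_blobs=0,
                              seed=2)
        assert np.all(ph.activation_truth == 0)

    def test_atlas_partitions_gm(self, phantom):
        labels = phantom.atlas_labels
        assert np.all((labels > 0) == phantom.gm_mask)
        assert len(np.unique(labels[labels > 0])) >= 10

    def test_templates_unit_peak(self, phantom):
        assert phantom.rsn_templates.shape[0] == 20
        assert np.allclose(phantom.rsn_templates.reshape(20, -1).max(axis=1),
                           1.0)

    def test_deterministic(self):
        a = generate_phantom(grid_shape=(16, 16, 16), seed=9)
        b = generate_phantom(grid_shape=(16, 16, 16), seed=9)
        assert np.array_equal(a.activation_truth, b.activation_truth)
        assert np.array_equal(a.rsn_templates, b.rsn_templates)

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            generate_phantom(grid_shape=(8, 16, 16))


class TestGFactor:
    def test_reference_scheme_is_unity(self, phantom):
        g = synthesize_gfactor(phantom, mb_factor=1, sense_factor=2.0)
        assert np.all(g.values == 1.0)

    def test_mean_increases_with_acceleration(self, phantom):
        g2 = synthesize_gfactor(phantom, 2, 2.0)
        g4 = synthesize_gfactor(phantom, 4, 2.0)
        assert g4.values.mean() > g2.values.mean() > 1.0
        assert g2.values.min() >= 1.0

    def test_centre_exceeds_edge(self, phantom):
        g = synthesize_gfactor(phantom, 4, 2.0)
        centre = tuple(s // 2 for s in phantom.grid_shape)
        assert g.values[centre] >= g.values[0, 0, 0]


class TestSimulateSubject:
    def test_noise_free_series_is_constant_baseline(self, phantom, quiet_noise):
        spec = small_spec(n_volumes=60)
        design = generate_task_design(seed=0).truncated(50.0)
        series, _ = simulate_subject(phantom, design, spec, quiet_noise,
                                     subject_effect=0.0, seed=1,
                                     rsn_amplitudes=np.zeros(20))
        data = series.data[phantom.brain_mask]
        assert np.allclose(data, data[:, :1], atol=1e-4)

    def test_seed_reproducibility(self, phantom, spec_mb1, design_mb1):
        noise = NoiseModel()
        a, ma = simulate_subject(phantom, design_mb1, spec_mb1, noise, seed=4)
        b, mb = simulate_subject(phantom, design_mb1, spec_mb1, noise, seed=4)
        assert np.array_equal(a.data, b.data)
        pd.testing.assert_frame_equal(ma, mb)

    def test_design_spec_mismatch_rejected(self, phantom, design_mb1):
        short = small_spec(tr=1.0, n_volumes=100)   # 100 s run, ~460 s design
        with pytest.raises(ValueError, match="does not fit"):
            simulate_subject(phantom, design_mb1, short, NoiseModel(), seed=0)

    def test_thermal_sd_scales_inversely_with_voxel_volume(self, phantom):
        """Doubling the voxel volume halves the per-sample thermal SD, and the
        log-variance vs log-scaling slope is 2."""
        noise = NoiseModel(ar_coefficient=0.0, physio_amplitudes=(0, 0),
                           drift_amplitude=0.0, thermal_sd_ref=2.0)
        design = generate_task_design(seed=0).truncated(100.0)
        sds, scalings = [], []
        for voxel in (2.7, 2.7 * 2 ** (1 / 3), 2.7 * 2 ** (2 / 3)):
            spec = small_spec(tr=0.5, n_volumes=400, voxel=voxel)
            series, _ = simulate_subject(phantom, design, spec, noise,
                                         subject_effect=0.0, seed=11,
                                         rsn_amplitudes=np.zeros(20))
            resid = series.data[phantom.gm_mask]
            resid = resid - resid.mean(axis=1, keepdims=True)
            sds.append(np.sqrt((resid ** 2).mean()))
            scalings.append(2.7 ** 3 / voxel ** 3)
        # adjacent steps double the voxel volume -> halve the thermal SD
        assert sds[0] / sds[1] == pytest.approx(2.0, rel=0.05)
        slope = np.polyfit(np.log(scalings), 2 * np.log(sds), 1)[0]
        assert slope == pytest.approx(2.0, abs=0.1)

    def test_ar1_autocorrelation_recovered(self, phantom):
        noise = NoiseModel(ar_coefficient=0.4, physio_amplitudes=(0, 0),
                           drift_amplitude=0.0, thermal_sd_ref=2.0)
        design = generate_task_design(seed=0).truncated(100.0)
        spec = small_spec(tr=1.0, n_volumes=500)
        series, _ = simulate_subject(phantom, design, spec, noise,
                                     subject_effect=0.0, seed=3,
                                     rsn_amplitudes=np.zeros(20))
        x = series.data[phantom.gm_mask]
        x = x - x.mean(axis=1, keepdims=True)
        lag1 = (x[:, 1:] * x[:, :-1]).sum() / (x ** 2).sum()
        assert lag1 == pytest.approx(0.4, abs=0.05)

    def test_gm_wm_contrast_decreases_with_shorter_tr(self, phantom):
        """Grey-white baseline contrast shrinks as TR shortens (saturation)."""
        tissue = TissueRelaxation()
        contrasts = []
        for tr in (2.45, 2.00, 1.22, 0.70, 0.63):
            gm = 100 * tissue.proton_density_grey * steady_state_signal(
                tr, tissue.t1_grey)
            wm = 100 * tissue.proton_density_white * steady_state_signal(
                tr, tissue.t1_white)
            contrasts.append(gm - wm)
        assert all(a > b for a, b in zip(contrasts, contrasts[1:]))

    def test_physio_aliasing_at_long_tr(self, phantom):
        """A 0.7 Hz cardiac component appears at its true frequency when
        sampled at TR 0.63 s (Nyquist 0.79 Hz) but folds below the 0.204 Hz
        Nyquist when sampled at TR 2.45 s."""
        noise = NoiseModel(ar_coefficient=0.0, thermal_sd_ref=0.0,
                           physio_amplitudes=(0.0, 1.0),
                           physio_cardiac_hz=0.7, drift_amplitude=0.0,
                           motion_signal_pct=0.0)
        design = generate_task_design(seed=0).truncated(50.0)
        peaks = {}
        for tr, n_vol in ((0.63, 780), (2.45, 200)):
            spec = small_spec(tr=tr, n_volumes=n_vol)
            series, _ = simulate_subject(phantom, design, spec, noise,
                                         subject_effect=0.0, seed=6,
                                         rsn_amplitudes=np.zeros(20))
            vox = series.data[phantom.csf_mask][0]
            vox = vox - vox.mean()
            freqs = np.fft.rfftfreq(n_vol, d=tr)
            spec_power = np.abs(np.fft.rfft(vox)) ** 2
            peaks[tr] = freqs[np.argmax(spec_power[1:]) + 1]
        assert peaks[0.63] == pytest.approx(0.7, abs=0.02)
        nyquist_long = 1.0 / (2 * 2.45)
        assert peaks[2.45] < nyquist_long + 1e-9
        assert abs(peaks[2.45] - 0.7) > 0.3   # genuinely aliased


class TestSimulateCohort:
    def test_manifest_and_effects(self, tmp_path):
        ph = generate_phantom(grid_shape=(16, 16, 16), seed=0)
        specs = [small_spec("A", tr=2.0, n_volumes=250),
                 small_spec("B", tr=1.0, n_volumes=500)]
        noise = NoiseModel(thermal_sd_ref=1.0, between_subject_sd=0.0)
        manifest = simulate_cohort(ph, specs, n_subjects=3, noise=noise,
                                   out_dir=tmp_path / "c", seed=0)
        assert len(manifest) == 3 * 2
        for p in manifest["bold_path"]:
            assert (tmp_path / "c").joinpath(p.split("/")[-1]).exists()
        # tau = 0: all subjects share the mean effect amplitude
        assert manifest["subject_effect"].nunique() == 1

    def test_effect_draws_concentrate_on_mean(self, tmp_path):
        ph = generate_phantom(grid_shape=(16, 16, 16), seed=0)
        spec = small_spec("A", tr=2.0, n_volumes=250)
        noise = NoiseModel(thermal_sd_ref=1.0, between_subject_sd=0.3)
        manifest = simulate_cohort(ph, [spec], n_subjects=12, noise=noise,
                                   out_dir=tmp_path / "c", mean_effect=1.0,
                                   seed=1)
        effects = manifest.groupby("subject")["subject_effect"].first()
        assert abs(effects.mean() - 1.0) <= 3 * 0.3 / np.sqrt(12)

    def test_rejects_single_subject(self, tmp_path):
        ph = generate_phantom(grid_shape=(16, 16, 16), seed=0)
        with pytest.raises(ValueError):
            simulate_cohort(ph, [small_spec()], n_subjects=1,
                            out_dir=tmp_path / "c", seed=0)
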