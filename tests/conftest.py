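"""Shared fixtures: a small phantom and simulated runs reused across tests."""

import numpy as np
import pytest

from mbfmri.firstlevel import build_design, compcor_regressors
from mbfmri.sequences import SequenceSpec, default_sequence_table
from mbfmri.simulate import (NoiseModel, generate_phantom,
                             generate_task_design, simulate_subject)


@pytest.fixture(scope="session")
def phantom():
    return generate_phantom(grid_shape=(20, 22, 20), seed=1)


@pytest.fixture(scope="session")
def specs():
    """The five bundled acquisition schemes keyed by name."""
    return {s.name: s for s in default_sequence_table()}


@pytest.fixture(scope="session")
def spec_mb1(specs):
    return specs["MB1S22.7iso2.45"]


@pytest.fixture(scope="session")
def design_mb1():
    return generate_task_design(seed=3)


@pytest.fixture(scope="session")
def sim_run(phantom, spec_mb1, design_mb1):
    """One default-noise simulated run plus its assembled design matrix."""
    noise = NoiseModel()
    series, motion = simulate_subject(phantom, design_mb1, spec_mb1, noise,
                                      subject_effect=1.0, seed=5)
    cc = np.column_stack([
        compcor_regressors(series, phantom.csf_mask, k=5),
        compcor_regressors(series, phantom.wm_mask, k=5),
    ])
    X = build_design(design_mb1, spec_mb1, motion=motion, compcor=cc)
    return series, motion, X


@pytest.fixture(scope="session")
def quiet_noise():
    """Noise model with everything off (pure signal)."""
    return NoiseModel(ar_coefficient=0.0, thermal_sd_ref=0.0,
                      physio_amplitudes=(0.0, 0.0), drift_amplitude=0.0,
                      between_subject_sd=0.0, motion_signal_pct=0.0)
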