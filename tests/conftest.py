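"""Shared fixtures: small phantom subjects and the (expensive, session-
scoped) desk-scale segmentation experiment."""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pytest

from adiposeg.experiments import run_segmentation_experiment
from adiposeg.phantom import desk_group_configs, render_volume, sample_subject

warnings.filterwarnings("ignore", message="a stratum has fewer than 3")


@pytest.fixture(scope="session")
def control_config():
    return desk_group_configs(base_seed=2)[0]


@pytest.fixture(scope="session")
def patient_config():
    return desk_group_configs(base_seed=2)[1]


@pytest.fixture(scope="session")
def subject(control_config):
    return sample_subject(control_config, "control", 0)


@pytest.fixture(scope="session")
def clean_subject(subject):
    """Noise-free, bias-free, bone-free variant of the same subject."""
    return replace(subject, noise_sigma=0.0, bias_amplitude=0.0,
                   bone_flag=False)


@pytest.fixture(scope="session")
def clean_volume(clean_subject):
    return render_volume(clean_subject)


@pytest.fixture(scope="session")
def noisy_volume(subject):
    return render_volume(subject)


@pytest.fixture(scope="session")
def trained_experiment():
    """The scaled two-group segmentation experiment: 16+16 phantom cohort,
    shrunken U-Net (8/16/32), 10 epochs.  Trained once per session."""
    return run_segmentation_experiment(seed=11, n_per_group=16, epochs=10)


def rng(seed=0):
    return np.random.default_rng(seed)
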