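"""Shared fixtures: reduced-scale network experiments and synthetic recordings.

The condition experiments here use fewer long propagations than the
full-scale analysis (30 instead of 200) so the whole suite stays fast;
the medians they produce are stable to a few mm/s.
"""

import numpy as np
import pytest

from gjprop.propagation import run_condition_experiment
from gjprop.synth import SyntheticConfig, generate_recording
from gjprop.mua import StimTrain


@pytest.fixture(scope="session")
def high_k_experiment():
    return run_condition_experiment("high_k", n_long=30, seed=11,
                                    max_attempts=150)


@pytest.fixture(scope="session")
def four_ap_experiment():
    return run_condition_experiment("four_ap", n_long=30, seed=12,
                                    max_attempts=60)


@pytest.fixture(scope="session")
def control_experiment():
    return run_condition_experiment("control", n_long=5, seed=13,
                                    max_attempts=12)


def short_train(n_trials=2):
    return StimTrain(n_trials=n_trials, first_onset_s=6.0)


@pytest.fixture(scope="session")
def propagation_recording():
    """Synthetic recording with 60 mm/s propagation, two trials."""
    cfg = SyntheticConfig(stim=short_train(2), epoch_s=52.0, k_out_mm=9.5,
                          speed_mm_s=60.0, seed=101)
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def no_propagation_recording():
    """Baseline [K+]o recording: activity confined to the illuminated span."""
    cfg = SyntheticConfig(stim=short_train(2), epoch_s=52.0, k_out_mm=3.5,
                          propagation=False, seed=102)
    return generate_recording(cfg)
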