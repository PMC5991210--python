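"""Shared fixtures: small synthetic experiments reused across test modules.

Everything is generated at test time from fixed seeds; session scope keeps
the simulation cost paid once.
"""

import numpy as np
import pytest

from ildpipe import RunConfig, process_recording
from ildpipe.synthetic import (
    BINAURAL_CLASSES,
    GroundTruthNeuron,
    SimParams,
    StimulusSpec,
    make_population,
    plant_spatial_structure,
    simulate_fluorescence,
)


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def small_experiment():
    """Noisy 40-neuron experiment, noise stimuli only."""
    pop = make_population(40, seed=101)
    pop = plant_spatial_structure(pop, seed=101)
    return simulate_fluorescence(pop, SimParams(include_tones=False), seed=102)


@pytest.fixture(scope="session")
def small_tensor(small_experiment, config):
    return process_recording(small_experiment.recording, small_experiment.trials)


@pytest.fixture(scope="session")
def class_experiment():
    """Noise-free experiment with one untuned neuron per binaural class."""
    neurons = [
        GroundTruthNeuron(
            tuning_type="untuned", binaural_class_truth=c,
            baseline_rate_hz=2.0, response_gain=40.0, noise_share=0.0,
            bf_hz=None, abl_gain={40.0: 1.0, 60.0: 1.0, 80.0: 1.0})
        for c in BINAURAL_CLASSES
    ]
    exp = simulate_fluorescence(
        neurons, SimParams(noiseless=True, include_tones=False), seed=7)
    return exp


@pytest.fixture(scope="session")
def class_tensor(class_experiment):
    return process_recording(class_experiment.recording, class_experiment.trials)


@pytest.fixture(scope="session")
def default_ilds():
    return np.array(StimulusSpec().ild_values)
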