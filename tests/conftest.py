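from dataclasses import replace

import numpy as np
import pytest

from spikeattn.simulate import cbm_preset, hmm_preset, simulate_session


@pytest.fixture(scope="session")
def tiny_hmm():
    """2 neurons, 2 trials, I=2 with 30 ms intervals: enumerable exactly."""
    design = replace(hmm_preset(2, n_neurons=2, n_trials=2, n_intervals=2,
                                seed=42), interval_ms=30)
    session, truths = simulate_session(design)
    return design, session, truths


@pytest.fixture(scope="session")
def small_hmm():
    """3 neurons, I=3 with 25 ms intervals: the largest enumerable case."""
    design = replace(hmm_preset(3, n_neurons=3, n_trials=2, n_intervals=3,
                                seed=7), interval_ms=25)
    session, truths = simulate_session(design)
    return design, session, truths


@pytest.fixture(scope="session")
def small_cbm():
    design = replace(cbm_preset(3, n_neurons=3, n_trials=2, n_intervals=3,
                                seed=13), interval_ms=25)
    session, truths = simulate_session(design)
    return design, session, truths


@pytest.fixture(scope="session")
def study_hmm():
    """The reference simulation-study design: 10 neurons, 20 trials, I=10."""
    design = hmm_preset(1, seed=101)
    session, truths = simulate_session(design)
    return design, session, truths


@pytest.fixture(scope="session")
def study_cbm():
    design = cbm_preset(1, seed=103)
    session, truths = simulate_session(design)
    return design, session, truths
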