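"""Shared fixtures: small seeded synthetic datasets.

Everything is generated at test time; module/session scope keeps the more
expensive objects (demo movie, concentration-series tables) shared.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from pirinv.pipeline import default_movie_sim, toy_movie_signals
from pirinv.synth import (SimConfig, generate_movie,
                          generate_response_dataset, generate_trial_traces,
                          odor_panel)


@pytest.fixture(scope="session")
def series_table():
    """300-cell concentration-series response table with ground truth."""
    return generate_response_dataset(SimConfig(n_cells=300, seed=3))


@pytest.fixture(scope="session")
def demo_movie():
    """64 x 64 simulated movie with 25 planted cells (segmentation demo)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_movie(default_movie_sim(7))


@pytest.fixture(scope="session")
def trial_tensor():
    """Small noise-free trial tensor with every responsive trial firing."""
    cfg = SimConfig(n_cells=60, trace_noise_sd=0.0, trial_noise_sd=0.0,
                    p_respond=1.0, seed=9)
    tensor, gt = generate_trial_traces(cfg)
    return cfg, tensor, gt


@pytest.fixture(scope="session")
def toy_signals():
    """The 3 x 3 pixels x 6 frames schematic movie as (frames, pixels)."""
    return toy_movie_signals()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
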