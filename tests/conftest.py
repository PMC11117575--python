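import dataclasses

import numpy as np
import pytest

from corneadic import dic, synthetic


@pytest.fixture(scope="session")
def small_config() -> synthetic.SimulationConfig:
    """Compact exam geometry for fast unit tests (noise-free)."""
    return dataclasses.replace(
        synthetic.demo_config(),
        noise_sd=0.0,
        n_frames=12,
        peak_frame=6,
        recovery_lag=3.0,
        amplitude_peak=5.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_exam(small_config):
    """Rendered noise-free sequence with its ground truth."""
    return synthetic.render_sequence(small_config)


@pytest.fixture(scope="session")
def small_tracked(small_exam):
    """DIC output for the small exam, shared across tests."""
    seq, truth = small_exam
    roi = dic.segment_cornea(seq.frames[0])
    grid = dic.build_grid(roi, step=8, subset_size=21)
    field = dic.track_incremental(seq, grid, dic.DICConfig(subset_size=21, step=8))
    return seq, truth, grid, field


@pytest.fixture(scope="session")
def frozen_cohort():
    """Fast-mode synthetic cohort at the frozen study conditions (50 + 50)."""
    return synthetic.generate_cohort(50, 50, seed=123)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
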