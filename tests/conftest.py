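"""Shared fixtures: a white-noise movie, a ground-truth ON cell and its train.

Session-scoped because several modules probe the same simulated recording;
seeds are fixed so every run sees identical data.
"""

import numpy as np
import pytest

from retdecode.stimuli import StimulusMovie, generate_white_noise
from retdecode.synthetic_retina import GroundTruthCell, SpikeTrain, simulate_cell


@pytest.fixture(scope="session")
def wn_movie() -> StimulusMovie:
    """300 s of 12x12 binary white noise at 30 Hz."""
    return generate_white_noise((9000, 12, 12), frame_rate=30.0, seed=1)


@pytest.fixture(scope="session")
def on_cell() -> GroundTruthCell:
    return GroundTruthCell(cell_id="on0", polarity="ON", center_um=(360.0, 360.0))


@pytest.fixture(scope="session")
def on_train(on_cell, wn_movie) -> SpikeTrain:
    """~8000 spikes from the noiseless ON cell."""
    return simulate_cell(on_cell, wn_movie, seed=2)


def perfect_responder(n_spikes: int = 40, depth: int = 24, shape=(8, 8), seed: int = 7):
    """A movie and spike train where every spike follows one fixed pattern.

    The same ``depth``-frame binary pattern is written into the movie before
    each spike, so every partial STA equals the pattern exactly.
    """
    rng = np.random.default_rng(seed)
    gap = depth + 6
    T = (n_spikes + 1) * gap + depth
    frames = (rng.random((T,) + shape) < 0.5).astype(np.float64)
    pattern = (rng.random((depth,) + shape) < 0.5).astype(np.float64)
    frame_rate = 30.0
    times = []
    for k in range(n_spikes):
        start = depth + k * gap
        frames[start : start + depth] = pattern
        times.append((start + depth - 1 + 0.5) / frame_rate)
    movie = StimulusMovie(frames, frame_rate, 60.0, "visual")
    train = SpikeTrain(np.asarray(times), movie.duration)
    return movie, train, pattern
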