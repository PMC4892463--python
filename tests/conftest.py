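import logging

import numpy as np
import pytest

import pptrack as pt


@pytest.fixture(autouse=True)
def _quiet_logs():
    logging.disable(logging.WARNING)
    yield
    logging.disable(logging.NOTSET)


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free scene: 20 well-separated spots, 10 frames, 256x256."""
    truth = pt.simulate_tracks(
        20, 10, (256, 256), pt.MotionSpec(step_sd=0.5), seed=1,
        amplitude=150.0, sigma=1.5, min_separation=20,
    )
    stack = pt.render_frames(truth, background=10.0, shape=(256, 256))
    return stack, truth


@pytest.fixture(scope="session")
def clean_params():
    return pt.DetectionParams(S=12, s=4, N=20, density="low", snr=7.0)


def noisy_scene(seed: int, n_tracks=60, n_frames=5, shape=(128, 128), snr=4.0):
    """Noisy scene factory with the default Poisson + Gaussian(5, 30) model."""
    noise = pt.NoiseSpec()
    background = 20.0
    amp = pt.amplitude_for_snr(snr, background, noise)
    truth = pt.simulate_tracks(
        n_tracks, n_frames, shape, pt.MotionSpec(step_sd=1.0), seed=seed,
        amplitude=amp, sigma=1.5,
    )
    clean = pt.render_frames(truth, background=background, shape=shape)
    stack = pt.add_noise(clean, noise, seed=seed + 1000)
    return stack, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
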