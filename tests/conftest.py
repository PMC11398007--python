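import numpy as np
import pytest

import gaitlab as gl


@pytest.fixture(scope="session")
def clean_walk() -> gl.SimulatedWalk:
    """Noise-free 1.0 m/s walk over the default 4 m walkway."""
    return gl.simulate_walk(gl.WalkSpec(speed=1.0, seed=11))


@pytest.fixture(scope="session")
def clean_result(clean_walk) -> gl.AnalysisResult:
    w = clean_walk
    return gl.analyze_walk(w.series, w.spec.camera, w.depth, w.walkway)


@pytest.fixture(scope="session")
def noisy_walk() -> gl.SimulatedWalk:
    """2 px pixel noise, 1% dropout."""
    return gl.simulate_walk(
        gl.WalkSpec(speed=1.1, pixel_noise_sd=2.0, dropout_prob=0.01, seed=23)
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def small_series() -> gl.KeypointSeries:
    """A tiny deterministic 6-frame series with one missing keypoint."""
    rng = np.random.default_rng(7)
    n = 6
    t = np.arange(n) / 60.0
    xy = rng.uniform(0, 720, size=(n, 25, 2))
    q = np.full((n, 25), 0.9)
    q[2, 10] = 0.0
    xy[2, 10] = np.nan
    return gl.KeypointSeries(t, xy, q)
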