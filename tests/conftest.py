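import numpy as np
import pytest

from afmosc.io import Quantity, TimeSeries


@pytest.fixture
def uniform_series():
    """Uniform 0.5 Hz adhesion series: line + sinusoid, N=200."""

    def make(
        n=200,
        fs=0.5,
        slope=0.02,
        intercept=60.0,
        tones=((0.01, 4.0, 0.5),),
        sigma=0.0,
        seed=0,
        quantity=Quantity.ADHESION_FORCE,
    ):
        t = np.arange(n) / fs
        x = intercept + slope * t
        for f, a, phi in tones:
            x = x + a * np.sin(2 * np.pi * f * t + phi)
        if sigma:
            x = x + np.random.default_rng(seed).normal(0, sigma, n)
        return TimeSeries(t, x, quantity, sampling_rate=fs)

    return make
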