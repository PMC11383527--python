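import numpy as np
import pytest
from scipy.special import erf


def pixel_gaussian(shape, x0, y0, amplitude, sigma, background=0.0):
    """Independent pixel-integrated Gaussian renderer (test oracle).

    ``amplitude`` is the total flux; pixel (i, j) integrates the 2-D
    Gaussian over [j-0.5, j+0.5] × [i-0.5, i+0.5].
    """
    h, w = shape

    def axis(n, c):
        edges = np.arange(n + 1) - 0.5
        cdf = 0.5 * (1 + erf((edges - c) / (sigma * np.sqrt(2))))
        return np.diff(cdf)

    return background + amplitude * np.outer(axis(h, y0), axis(w, x0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
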