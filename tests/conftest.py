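import numpy as np
import pytest

import lipidphasor as lp


@pytest.fixture(scope="session")
def axis():
    return lp.default_axis()


@pytest.fixture(scope="session")
def spectra(axis):
    return lp.default_spectra(axis)


@pytest.fixture(scope="session")
def pure_phasors(spectra):
    """True (G, S) of each pure component at harmonic 1."""
    return {k: np.array(lp.spectrum_phasor(v)) for k, v in spectra.items()}


@pytest.fixture(scope="session")
def true_vertices(pure_phasors):
    return lp.ReferenceVertices(
        v_polar=tuple(pure_phasors["polar_nilered"]),
        v_neutral=tuple(pure_phasors["neutral_nilered"]),
        v_egfp=tuple(pure_phasors["egfp"]),
    )


def random_image(rng, shape=(16, 16), n_channels=22, axis=None):
    """Random nonnegative lambda stack for oracle comparisons."""
    if axis is None:
        axis = lp.SpectralAxis(493.0, 10.0, n_channels)
    data = rng.gamma(2.0, 50.0, size=shape + (n_channels,))
    return lp.HyperspectralImage(data, axis)


def naive_phasor(data, harmonic=1):
    """Per-pixel discrete-Fourier loop: the independent phasor oracle."""
    h, w, n = data.shape
    g = np.zeros((h, w))
    s = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            total = 0.0
            gs = 0.0
            ss = 0.0
            for k in range(n):
                ang = 2.0 * np.pi * harmonic * k / n
                gs += data[i, j, k] * np.cos(ang)
                ss += data[i, j, k] * np.sin(ang)
                total += data[i, j, k]
            g[i, j] = gs / total
            s[i, j] = ss / total
    return g, s
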