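import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import holostain as hs

settings.register_profile(
    "suite", deadline=None, max_examples=25, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cfg256():
    """Desk-scale acquisition geometry used by most optics tests."""
    return hs.small_config(256, z_jitter=30.0)


@pytest.fixture(scope="session")
def sparse_phantom(cfg256):
    """A flat (single-plane) sparse Gram-negative smear."""
    return hs.generate_phantom(cfg256, "GNB", density=800, stain_quality=0.0,
                               seed=5, z_span=0.0)


@pytest.fixture(scope="session")
def sparse_hologram(cfg256, sparse_phantom):
    return hs.record_hologram(sparse_phantom, cfg256, seed=5, noise=hs.NOISELESS)


@pytest.fixture(scope="session")
def gs_stack(sparse_hologram):
    """Converged multi-wavelength reconstruction of the sparse phantom."""
    return hs.gs_reconstruct(sparse_hologram, sparse_hologram.z_true,
                             max_iters=50, tol=1e-5)


@pytest.fixture(scope="session")
def bandlimited_field(cfg256):
    """A complex field whose FFT support lies strictly inside the
    propagating band (so ASM round trips are exact)."""
    rng = np.random.default_rng(0)
    n = 256
    spec = np.fft.fft2(rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n)))
    fy = np.fft.fftfreq(n, cfg256.grid_pitch)
    fx = np.fft.fftfreq(n, cfg256.grid_pitch)
    fr2 = fx[None, :] ** 2 + fy[:, None] ** 2
    wavelength = 0.52
    spec[fr2 > (0.8 / wavelength) ** 2] = 0.0
    values = np.fft.ifft2(spec)
    return hs.ComplexField(values / np.abs(values).max(), cfg256.grid_pitch,
                           wavelength)
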