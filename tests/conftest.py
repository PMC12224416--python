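import numpy as np
import pytest

from axdki import phantom, schemes


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Small single-frequency noiseless two-region phantom."""
    spec = phantom.PhantomSpec(shape=(8, 8, 4), noise_model="none")
    return phantom.generate(spec, scheme=phantom.default_scheme(frequencies=(0.0,)))


@pytest.fixture(scope="session")
def noiseless_multifreq_phantom():
    """Noiseless phantom at 0/60/120 Hz with programmed kurtosis dispersion."""
    spec = phantom.PhantomSpec(
        shape=(8, 8, 4), noise_model="none", dispersion_mode="linear-decrease",
        dispersion_slope=0.3,
    )
    return phantom.generate(spec)


@pytest.fixture()
def noisy_phantom():
    """Factory for seeded noisy phantoms at configurable SNR."""

    def make(seed=0, snr=20.0, shape=(8, 8, 4), frequencies=(0.0,), **kw):
        spec = phantom.PhantomSpec(shape=shape, snr=snr, seed=seed, **kw)
        return phantom.generate(
            spec, scheme=phantom.default_scheme(frequencies=frequencies)
        )

    return make


@pytest.fixture(scope="session")
def two_shell_scheme():
    """10-direction two-shell single-frequency scheme with 2 b0s."""
    return phantom.default_scheme(frequencies=(0.0,))


@pytest.fixture(scope="session")
def oblique_params():
    """A representative anisotropic parameter set with an oblique axis."""
    from axdki.model import AxisymmetricParams

    axis = np.array([1.0, 2.0, 3.0])
    return AxisymmetricParams(
        log_s0=0.1, d_perp=0.4, d_par=1.5, w_perp=1.6, w_par=0.6, w_mean=1.0,
        axis=axis / np.linalg.norm(axis),
    )


def pytest_configure(config):
    np.seterr(all="ignore")


@pytest.fixture()
def single_voxel_volume():
    """Wrap a (nvol,) signal vector into a 1-voxel SignalVolume."""
    from axdki.io import SignalVolume

    def make(signals):
        return SignalVolume(data=np.asarray(signals).reshape(1, 1, 1, -1))

    return make


def signals_from_params(params, scheme):
    """Noiseless magnitude signals of one parameter set under a scheme."""
    from axdki.model import predict_log_signal

    units = scheme.unit_directions
    theta = np.arccos(np.clip(np.abs(units @ params.axis), 0.0, 1.0))
    theta[scheme.is_b0] = 0.0
    return np.exp(predict_log_signal(params, scheme.bvalues, theta))
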