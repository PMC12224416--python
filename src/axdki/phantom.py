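"""Synthetic multi-frequency axisymmetric DKI phantom generator.

The default phantom emulates a small pre-clinical frequency-dependent
DKI acquisition at desk scale: a 16×16×8 grid holding a curved
high-anisotropy "white matter" tube (axis following the tube tangent)
embedded in an isotropic-ish "grey matter" background, scanned with the
efficient 10-direction scheme at shells b = 1.0 and 2.5 ms/µm²,
oscillation frequencies 0/60/120 Hz and 2 b0 volumes per frequency.
Region parameter values are library defaults in the physiologic range;
they are inputs to the tests, not empirical claims.

Noise is Rician by default (magnitude MRI: the modulus of a complex
Gaussian perturbation), with Gaussian available for linear-theory
tests; σ = S0/SNR defines the nominal b0 SNR.  Signal averages are
simulated as independent noisy repetitions combined by the mean.
Everything is reproducible from the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import SignalVolume
from .model import AxisymmetricParams, predict_log_signal
from .schemes import GradientScheme, multi_shell_scheme

__all__ = [
    "RegionParams",
    "PhantomSpec",
    "PhantomData",
    "default_scheme",
    "frequency_dispersion_profile",
    "generate",
]


@dataclass(frozen=True)
class RegionParams:
    """Ground-truth axisymmetric parameters of one tissue region."""

    d_par: float
    d_perp: float
    w_par: float
    w_perp: float
    w_mean: float
    s0: float = 1.0


#: defaults in the physiologic range: a high-FA, high-radial-kurtosis
#: "WM" tube against a nearly isotropic "GM" background
DEFAULT_REGIONS = {
    "WM": RegionParams(d_par=1.5, d_perp=0.4, w_par=0.6, w_perp=1.6, w_mean=1.0),
    "GM": RegionParams(d_par=0.8, d_perp=0.8, w_par=0.7, w_perp=0.7, w_mean=0.7),
}


@dataclass
class PhantomSpec:
    """Geometry, ground truth, orientation and noise of a synthetic phantom."""

    shape: tuple = (16, 16, 8)
    regions: dict = field(default_factory=lambda: dict(DEFAULT_REGIONS))
    tube_radius: float = 2.5
    tube_bend: float = 2.5  # sine amplitude of the tube centerline, voxels
    orientation: str = "tube-tangent"  # or "constant"
    dispersion_mode: str = "none"  # or "linear-decrease"
    dispersion_slope: float = 0.3
    noise_model: str = "rician"  # "rician" | "gaussian" | "none"
    snr: float = 20.0
    n_averages: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_model not in ("rician", "gaussian", "none"):
            raise ValueError("noise_model must be rician, gaussian or none")
        if self.noise_model != "none" and not self.snr > 0:
            raise ValueError("SNR must be positive")


@dataclass
class PhantomData:
    """A generated phantom: signals plus every ground-truth field."""

    volume: SignalVolume
    scheme: GradientScheme
    labels: np.ndarray  # 3D int grid: 1 = WM tube, 0 = GM background
    axes: np.ndarray  # (nx, ny, nz, 3) unit orientation field
    truth: dict  # frequency -> {region name -> RegionParams}
    spec: PhantomSpec

    def region_mask(self, name: str) -> np.ndarray:
        code = {"GM": 0, "WM": 1}[name]
        return self.labels == code

    def truth_grids(self, frequency: float) -> dict:
        """Per-voxel ground-truth parameter grids for one frequency."""
        table = self.truth[float(frequency)]
        out = {}
        for attr in ("d_par", "d_perp", "w_par", "w_perp", "w_mean", "s0"):
            grid = np.empty(self.labels.shape)
            for name in table:
                grid[self.region_mask(name)] = getattr(table[name], attr)
            out[attr] = grid
        return out

    def true_params(self, frequency: float) -> AxisymmetricParams:
        """Ground truth as masked-voxel arrays in solver ordering."""
        g = self.truth_grids(frequency)
        m = self.volume.mask
        return AxisymmetricParams(
            log_s0=np.log(g["s0"][m]),
            d_perp=g["d_perp"][m],
            d_par=g["d_par"][m],
            w_perp=g["w_perp"][m],
            w_par=g["w_par"][m],
            w_mean=g["w_mean"][m],
            axis=self.axes[m],
        )


def default_scheme(frequencies=(0.0, 60.0, 120.0)) -> GradientScheme:
    """The emulated acquisition: 10 directions × shells (1.0, 2.5) + 2 b0s
    per frequency."""
    return multi_shell_scheme(frequencies=frequencies, n_b0=2)


def frequency_dispersion_profile(
    regions: dict, frequencies, mode: str = "none", slope: float = 0.3
) -> dict:
    """Per-frequency ground-truth tables with programmed kurtosis dispersion.

    ``linear-decrease`` scales every kurtosis parameter by
    (1 − slope·f/f_max), leaving diffusivities and orientation fixed; at
    f_max the kurtosis is reduced by exactly ``slope``.  ``none`` copies
    the table to every frequency.
    """
    freqs = [float(f) for f in frequencies]
    if mode == "none":
        return {f: dict(regions) for f in freqs}
    if mode != "linear-decrease":
        raise ValueError(f"unknown dispersion mode {mode!r}")
    f_max = max(freqs)
    out = {}
    for f in freqs:
        scale = 1.0 - slope * (f / f_max) if f_max > 0 else 1.0
        out[f] = {
            name: replace(
                p, w_par=p.w_par * scale, w_perp=p.w_perp * scale, w_mean=p.w_mean * scale
            )
            for name, p in regions.items()
        }
    return out


def _geometry(spec: PhantomSpec):
    nx, ny, nz = spec.shape
    x = np.arange(nx)
    yc = (ny - 1) / 2.0 + spec.tube_bend * np.sin(np.pi * x / max(nx - 1, 1))
    zc = (nz - 1) / 2.0
    yy, zz = np.meshgrid(np.arange(ny), np.arange(nz), indexing="ij")
    labels = np.zeros(spec.shape, dtype=int)
    axes = np.zeros(spec.shape + (3,))
    axes[..., 2] = 1.0  # background axis
    dy = np.gradient(yc)
    for i in range(nx):
        inside = (yy - yc[i]) ** 2 + (zz - zc) ** 2 <= spec.tube_radius**2
        labels[i][inside] = 1
        if spec.orientation == "tube-tangent":
            t = np.array([1.0, dy[i], 0.0])
        else:
            t = np.array([1.0, 0.0, 0.0])
        t /= np.linalg.norm(t)
        axes[i][inside] = t
    return labels, axes


def generate(
    spec: PhantomSpec,
    scheme: GradientScheme | None = None,
    seed: int | None = None,
) -> PhantomData:
    """Simulate the phantom's diffusion-weighted signals for a scheme.

    Noiseless signals come from the axisymmetric forward model evaluated
    per voxel and volume; noise (σ = S0/SNR) is then drawn per
    repetition and repetitions are averaged.  Identical spec + seed give
    bit-identical volumes.
    """
    if scheme is None:
        scheme = default_scheme()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    labels, axes = _geometry(spec)
    mask = np.ones(spec.shape, dtype=bool)
    truth = frequency_dispersion_profile(
        spec.regions,
        np.unique(scheme.frequencies),
        spec.dispersion_mode,
        spec.dispersion_slope,
    )

    nvox = int(mask.sum())
    flat_axes = axes[mask]
    units = scheme.unit_directions
    costh = np.clip(np.abs(flat_axes @ units.T), 0.0, 1.0)
    theta = np.arccos(costh)  # (nvox, nvol)
    theta[:, scheme.is_b0] = 0.0

    signal = np.empty((nvox, len(scheme)))
    flat_labels = labels[mask]
    for f in np.unique(scheme.frequencies):
        sel = scheme.volumes_for_frequency(f)
        for name, code in (("GM", 0), ("WM", 1)):
            vox = flat_labels == code
            if not np.any(vox):
                continue
            p = truth[float(f)][name]
            params = AxisymmetricParams(
                log_s0=np.log(p.s0),
                d_perp=p.d_perp,
                d_par=p.d_par,
                w_perp=p.w_perp,
                w_par=p.w_par,
                w_mean=p.w_mean,
            )
            logsig = predict_log_signal(
                params, scheme.bvalues[None, sel], theta[np.ix_(vox, sel)]
            )
            signal[np.ix_(vox, sel)] = np.exp(logsig)

    if spec.noise_model != "none" and np.isfinite(spec.snr):
        s0_vox = np.array([spec.regions[n].s0 for n in ("GM", "WM")])[flat_labels]
        sigma = (s0_vox / spec.snr)[:, None]
        acc = np.zeros_like(signal)
        for _ in range(spec.n_averages):
            if spec.noise_model == "gaussian":
                acc += signal + sigma * rng.standard_normal(signal.shape)
            else:
                re = signal + sigma * rng.standard_normal(signal.shape)
                im = sigma * rng.standard_normal(signal.shape)
                acc += np.hypot(re, im)
        noisy = acc / spec.n_averages
    else:
        noisy = signal

    data = np.zeros(spec.shape + (len(scheme),))
    data[mask] = noisy
    volume = SignalVolume(data=data, mask=mask)
    return PhantomData(
        volume=volume, scheme=scheme, labels=labels, axes=axes, truth=truth, spec=spec
    )
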