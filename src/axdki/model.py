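"""Axisymmetric DKI forward model and derived scalar metrics.

The signal representation is the standard cumulant expansion

    log(S_{b,n} / S0) = -b·D(n) + (b²/6)·D̄²·W(n)

restricted to voxels with one symmetry axis (λ2 = λ3 in the diffusion
tensor).  Under that constraint the kurtosis tensor collapses to three
scalars — the mean kurtosis tensor W̄, the radial tensor kurtosis W⊥ and
the axial tensor kurtosis W∥ — and both D and W along a direction depend
only on the polar angle θ between the direction and the axis:

    D(θ) = D⊥ + cos²θ·(D∥ − D⊥)
    W(θ) = (1/16)·[cos4θ·(10W⊥ + 5W∥ − 15W̄)
                   + 8·cos2θ·(W∥ − W⊥) − 2W⊥ + 3W∥ + 15W̄]

W(θ) satisfies W(0) = W∥, W(π/2) = W⊥ and a uniform sphere average of W̄
— the three identities that pin the grouping down; all three are locked
by unit tests.  Note W̄, W⊥ are tensor quantities (contractions and
surface averages of the kurtosis tensor), distinct from conventional
numerically averaged mean/radial kurtosis.

All diffusivities are in µm²/ms and b-values in ms/µm².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AxisymmetricParams",
    "Metrics",
    "directional_diffusivity",
    "directional_kurtosis_w",
    "predict_log_signal",
    "derived_metrics",
]


@dataclass
class AxisymmetricParams:
    """Axisymmetric DKI parameters of one voxel (or an array of voxels).

    Fields may be scalars or broadcastable arrays.  ``axis`` is the unit
    symmetry axis; its sign carries no meaning.  Physical validity
    (non-negative diffusivities) is a query, not a constructor constraint:
    fitted parameters may violate it and are stored as-is.
    """

    log_s0: float | np.ndarray = 0.0
    d_perp: float | np.ndarray = 0.0
    d_par: float | np.ndarray = 0.0
    w_perp: float | np.ndarray = 0.0
    w_par: float | np.ndarray = 0.0
    w_mean: float | np.ndarray = 0.0
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(self.axis, axis=-1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.axis = np.where(n > 0, self.axis / n, self.axis)

    @property
    def d_mean(self):
        """Mean diffusivity D̄ = (2D⊥ + D∥)/3."""
        return (2.0 * self.d_perp + self.d_par) / 3.0

    def is_physical(self) -> bool | np.ndarray:
        return (np.asarray(self.d_perp) >= 0) & (np.asarray(self.d_par) >= 0)

    def linear_vector(self) -> np.ndarray:
        """The 6-vector fitted in step two: (log S0, D⊥, D∥, D̄²W⊥, D̄²W∥, D̄²W̄)."""
        dm2 = np.asarray(self.d_mean) ** 2
        return np.stack(
            np.broadcast_arrays(
                self.log_s0,
                self.d_perp,
                self.d_par,
                dm2 * self.w_perp,
                dm2 * self.w_par,
                dm2 * self.w_mean,
            ),
            axis=-1,
        )


def directional_diffusivity(params: AxisymmetricParams, theta) -> np.ndarray | float:
    """Apparent diffusivity at polar angle θ (radians) from the symmetry axis."""
    c2 = np.cos(theta) ** 2
    return params.d_perp + c2 * (params.d_par - params.d_perp)


def directional_kurtosis_w(params: AxisymmetricParams, theta) -> np.ndarray | float:
    """Kurtosis tensor element W(θ) along a direction at polar angle θ."""
    return _w_of_theta(params.w_perp, params.w_par, params.w_mean, theta)


def _w_of_theta(w_perp, w_par, w_mean, theta):
    cos2 = np.cos(2.0 * np.asarray(theta, dtype=float))
    cos4 = np.cos(4.0 * np.asarray(theta, dtype=float))
    return (
        cos4 * (10.0 * w_perp + 5.0 * w_par - 15.0 * w_mean)
        + 8.0 * cos2 * (w_par - w_perp)
        - 2.0 * w_perp
        + 3.0 * w_par
        + 15.0 * w_mean
    ) / 16.0


def predict_log_signal(params: AxisymmetricParams, b, theta) -> np.ndarray | float:
    """Noiseless log signal at weighting b (ms/µm²) and polar angle θ."""
    b = np.asarray(b, dtype=float)
    d = directional_diffusivity(params, theta)
    w = directional_kurtosis_w(params, theta)
    dmean = params.d_mean
    return params.log_s0 - b * d + (b**2 / 6.0) * dmean**2 * w


@dataclass
class Metrics:
    """Derived scalar metrics with provenance metadata.

    ``k_par``/``k_perp`` are NaN (undefined, never silently infinite) where
    the corresponding diffusivity is zero.
    """

    d_mean: np.ndarray | float
    fa: np.ndarray | float
    k_par: np.ndarray | float
    k_perp: np.ndarray | float
    w_mean: np.ndarray | float
    meta: dict = field(default_factory=dict)


def fractional_anisotropy(d_perp, d_par):
    """FA of an axisymmetric tensor with radial/axial diffusivities (λ⊥, λ∥)."""
    d_perp = np.asarray(d_perp, dtype=float)
    d_par = np.asarray(d_par, dtype=float)
    dm = (2.0 * d_perp + d_par) / 3.0
    num = (d_par - dm) ** 2 + 2.0 * (d_perp - dm) ** 2
    den = d_par**2 + 2.0 * d_perp**2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.sqrt(np.where(den > 0, num / den, np.nan))
    return fa


def derived_metrics(params: AxisymmetricParams, **meta) -> Metrics:
    """D̄, FA, K∥, K⊥ and W̄ from axisymmetric parameters.

    K∥ = W∥·D̄²/D∥² and K⊥ = W⊥·D̄²/D⊥²; both are NaN where the
    denominator diffusivity is zero.
    """
    dm = np.asarray(params.d_mean, dtype=float)
    d_par = np.asarray(params.d_par, dtype=float)
    d_perp = np.asarray(params.d_perp, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        k_par = np.where(d_par != 0, params.w_par * dm**2 / d_par**2, np.nan)
        k_perp = np.where(d_perp != 0, params.w_perp * dm**2 / d_perp**2, np.nan)
    return Metrics(
        d_mean=dm,
        fa=fractional_anisotropy(d_perp, d_par),
        k_par=k_par,
        k_perp=k_perp,
        w_mean=np.asarray(params.w_mean, dtype=float),
        meta=dict(meta),
    )
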