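"""Step two: regularized linear fit of the six axisymmetric DKI parameters.

Given a fixed per-voxel symmetry axis (from the diffusion-tensor step;
never updated here), the log-signal model is linear in the 6-vector

    x = (log S0, D⊥, D∥, D̄²W⊥, D̄²W∥, D̄²W̄)

with per-volume design row

    (1, −b·sin²θ, −b·cos²θ,
     (b²/6)(10cos4θ − 8cos2θ − 2)/16,
     (b²/6)(5cos4θ + 8cos2θ + 3)/16,
     (b²/6)(−15cos4θ + 15)/16)

where θ is the polar angle between the encoding direction and the axis.
The row dotted with x reproduces the axisymmetric forward model exactly;
this identity (and the θ = 0 / π/2 limits) is locked by unit tests.
The fit minimizes ||A x − y||² + γ_DK ||T x||² jointly over masked
voxels, with T the spatial first differences of the five diffusion and
kurtosis components (log S0 is not penalized; 15 entries per voxel).

Each frequency is fitted independently — the model carries no
cross-frequency coupling other than a shared axis field under the AFAB
strategy.  Negative fitted kurtosis ("blackened" voxels) is preserved in
stored maps; it is a useful noise diagnostic and is only clamped, if
ever, in visualization layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import solver as _solver
from .dti import AxisField
from .io import SignalVolume
from .model import AxisymmetricParams, Metrics, derived_metrics
from .schemes import GradientScheme

__all__ = [
    "AxisymmetricField",
    "polar_angles",
    "build_dki_design",
    "fit_dki_regularized",
    "extract_metrics",
]

#: penalty weights for (log S0, D⊥, D∥, D̄²W⊥, D̄²W∥, D̄²W̄)
DK_PENALTY_WEIGHTS = np.array([0.0, 1.0, 1.0, 1.0, 1.0, 1.0])


@dataclass
class AxisymmetricField:
    """Fitted per-voxel 6-vectors for one frequency.

    Columns of ``params``: log S0, D⊥, D∥, u⊥ = D̄²W⊥, u∥ = D̄²W∥,
    ū = D̄²W̄.
    """

    params: np.ndarray  # (nvox, 6)
    mask: np.ndarray
    frequency: float | None = None
    axis_field: AxisField | None = None
    info: _solver.SolveInfo | None = None
    meta: dict = field(default_factory=dict)

    def as_params(self) -> AxisymmetricParams:
        """Convert to model parameters; W = u/D̄² needs D̄ > 0 (else NaN)."""
        p = self.params
        dmean = (2.0 * p[:, 1] + p[:, 2]) / 3.0
        with np.errstate(invalid="ignore", divide="ignore"):
            dm2 = np.where(dmean > 0, dmean**2, np.nan)
            return AxisymmetricParams(
                log_s0=p[:, 0],
                d_perp=p[:, 1],
                d_par=p[:, 2],
                w_perp=p[:, 3] / dm2,
                w_par=p[:, 4] / dm2,
                w_mean=p[:, 5] / dm2,
                axis=self.axis_field.axes if self.axis_field is not None else None,
            )


def polar_angles(axis_field: AxisField, scheme: GradientScheme) -> np.ndarray:
    """θ = arccos(|n̂·axis|) ∈ [0, π/2] per voxel and volume, (nvox, nvol).

    b0 volumes get θ = 0 by convention; their design row does not depend
    on θ.  The absolute dot product makes the result invariant to the
    sign indeterminacy of both the axis and the encoding direction.
    """
    units = scheme.unit_directions
    cosang = np.abs(axis_field.axes @ units.T)
    cosang = np.clip(cosang, 0.0, 1.0)
    theta = np.arccos(cosang)
    theta[:, scheme.is_b0] = 0.0
    return theta


def build_dki_design(bvalues: np.ndarray, thetas: np.ndarray) -> np.ndarray:
    """Axisymmetric design rows for b-values (nvol,) and angles (..., nvol).

    Returns an array of shape (..., nvol, 6).  Broadcasting over a
    leading voxel dimension builds the per-voxel design of a whole fit.
    """
    b = np.asarray(bvalues, dtype=float)
    theta = np.asarray(thetas, dtype=float)
    c2 = np.cos(2.0 * theta)
    c4 = np.cos(4.0 * theta)
    sin2 = (1.0 - c2) / 2.0
    cos2 = (1.0 + c2) / 2.0
    b2 = b**2 / 6.0
    shape = np.broadcast_shapes(b.shape, theta.shape)
    rows = np.stack(
        [
            np.ones(shape),
            -b * sin2,
            -b * cos2,
            b2 * (10.0 * c4 - 8.0 * c2 - 2.0) / 16.0,
            b2 * (5.0 * c4 + 8.0 * c2 + 3.0) / 16.0,
            b2 * (-15.0 * c4 + 15.0) / 16.0,
        ],
        axis=-1,
    )
    return rows


def fit_dki_regularized(
    volume: SignalVolume,
    scheme: GradientScheme,
    axis_field: AxisField,
    frequency: float | None = None,
    gamma_dk: float = 0.075,
    tol: float = 1e-8,
    maxiter: int = 500,
) -> AxisymmetricField:
    """Fit the six axisymmetric parameters for one frequency's volumes.

    ``frequency=None`` uses every volume (single-frequency data).  The
    axis field is held fixed throughout.  b0 volumes are always included
    — they constrain log S0.  With ``gamma_dk=0`` the fit is per-voxel
    ordinary least squares.
    """
    if frequency is None:
        sel = np.ones(len(scheme), dtype=bool)
    else:
        sel = scheme.volumes_for_frequency(frequency)
        if not np.any(sel):
            raise ValueError(f"no volumes at frequency {frequency} Hz")
    idx = np.where(sel)[0]
    sub = scheme.subset(idx)
    y = volume.log_signals()[:, idx]
    theta = polar_angles(axis_field, sub)  # (nvox, nsub)
    design = build_dki_design(sub.bvalues, theta)  # (nvox, nsub, 6)
    ata = np.einsum("vni,vnj->vij", design, design)
    aty = np.einsum("vni,vn->vi", design, y)
    problem = _solver.RegularizedProblem(
        ata=ata,
        aty=aty,
        mask=volume.mask,
        gamma=gamma_dk,
        penalty_weights=DK_PENALTY_WEIGHTS,
        tol=tol,
        maxiter=maxiter,
    )
    params, info = _solver.solve(problem)
    if not info.converged:
        raise RuntimeError(
            "conjugate gradients did not converge in the axisymmetric fit "
            f"(iterations={info.iterations}, relative residual={info.residual:.3e})"
        )
    return AxisymmetricField(
        params=params,
        mask=volume.mask,
        frequency=frequency,
        axis_field=axis_field,
        info=info,
        meta={"gamma_dk": gamma_dk, "strategy": axis_field.strategy},
    )


def extract_metrics(fit: AxisymmetricField) -> Metrics:
    """Scalar maps D̄, FA, K∥, K⊥, W̄ from a fitted axisymmetric field.

    D̄² cancels in K∥ = W∥·D̄²/D∥² = u∥/D∥² (likewise K⊥ = u⊥/D⊥²), so
    the kurtosis-ratio maps never divide by D̄.  W̄ = ū/D̄².  Zero
    denominators yield NaN (undefined), never silent infinities.
    """
    p = fit.params
    d_perp, d_par = p[:, 1], p[:, 2]
    dmean = (2.0 * d_perp + d_par) / 3.0
    from .model import fractional_anisotropy

    with np.errstate(invalid="ignore", divide="ignore"):
        k_par = np.where(d_par != 0, p[:, 4] / d_par**2, np.nan)
        k_perp = np.where(d_perp != 0, p[:, 3] / d_perp**2, np.nan)
        w_mean = np.where(dmean != 0, p[:, 5] / dmean**2, np.nan)
    return Metrics(
        d_mean=dmean,
        fa=fractional_anisotropy(d_perp, d_par),
        k_par=k_par,
        k_perp=k_perp,
        w_mean=w_mean,
        meta=dict(fit.meta, frequency=fit.frequency, method="axisym"),
    )
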