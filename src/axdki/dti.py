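"""Step one: regularized diffusion-tensor fitting for the symmetry axis.

The per-voxel symmetry axis used by the axisymmetric kurtosis fit is the
principal eigenvector of a diffusion tensor estimated in this module and
kept fixed afterwards.  Three pooling strategies control which volumes
feed the tensor fit:

* ``AFAB`` — all frequencies and all b-values, one shared axis field;
* ``SFAB`` — each frequency separately, all b-values;
* ``SFLB`` — each frequency separately, low b-shell (+ b0) only.

The fit minimizes ||A_DT x − y||² + γ_DT ||T_DT x||² with x the 7-vector
(log S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) per voxel and T_DT the weighted
spatial first differences of the six tensor components (log S0 is not
penalized).  Diagonal components carry weight 1 and cross terms weight 2;
equal weighting within each group keeps the penalty rotationally
invariant.  Ordinary (unweighted) least squares is used throughout for
its reduced bias relative to weighted least squares.

Two data models are available for the tensor estimate:

* ``adc_mode="joint"`` (default) — the standard joint log-linear OLS over
  all selected volumes.  On data with non-zero kurtosis this carries an
  O(b²·W) bias because the quartic signal term projects onto the tensor
  design.
* ``adc_mode="quadratic"`` — when every direction is sampled at two or
  more non-zero shells, a per-direction quadratic-in-b solve separates
  the kurtosis term from the ADC first, and the tensor is fitted to the
  kurtosis-free ADCs.  On noiseless axisymmetric data this recovers the
  tensor (hence the axis) exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import solver as _solver
from .io import SignalVolume
from .schemes import GradientScheme, b_matrix_row

__all__ = [
    "DiffusionTensorField",
    "AxisField",
    "AxisBundle",
    "build_dti_design",
    "fit_dti_regularized",
    "principal_axis",
    "compute_axes",
]

STRATEGIES = ("AFAB", "SFAB", "SFLB")

#: penalty weights for (log S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)
DT_PENALTY_WEIGHTS = np.array([0.0, 1.0, 1.0, 1.0, 2.0, 2.0, 2.0])


@dataclass
class DiffusionTensorField:
    """Per-voxel 7-vector (log S0 + 6 tensor components) inside a mask."""

    params: np.ndarray  # (nvox, 7)
    mask: np.ndarray
    info: _solver.SolveInfo | None = None
    meta: dict = field(default_factory=dict)

    def tensors(self) -> np.ndarray:
        """Symmetric 3x3 tensors, shape (nvox, 3, 3)."""
        p = self.params
        t = np.empty((p.shape[0], 3, 3))
        t[:, 0, 0] = p[:, 1]
        t[:, 1, 1] = p[:, 2]
        t[:, 2, 2] = p[:, 3]
        t[:, 0, 1] = t[:, 1, 0] = p[:, 4]
        t[:, 0, 2] = t[:, 2, 0] = p[:, 5]
        t[:, 1, 2] = t[:, 2, 1] = p[:, 6]
        return t


@dataclass
class AxisField:
    """Unit symmetry axes for the masked voxels (sign-indeterminate)."""

    axes: np.ndarray  # (nvox, 3), unit norm
    mask: np.ndarray
    strategy: str = ""
    frequency: float | None = None  # None = shared across all frequencies


@dataclass
class AxisBundle:
    """Axis fields keyed by frequency, as produced by one pooling strategy."""

    strategy: str
    axes: dict  # frequency -> AxisField (AFAB maps every frequency to one field)
    tensor_fields: dict = field(default_factory=dict)

    def for_frequency(self, frequency: float) -> AxisField:
        return self.axes[float(frequency)]


def build_dti_design(scheme: GradientScheme, subset=None) -> np.ndarray:
    """Rows (1, −b_xx, −b_yy, −b_zz, −2b_xy, −2b_xz, −2b_yz), one per volume."""
    if subset is None:
        subset = np.ones(len(scheme), dtype=bool)
    sub = scheme.subset(np.where(np.asarray(subset))[0] if np.asarray(subset).dtype == bool else subset)
    rows = np.empty((len(sub), 7))
    for n in range(len(sub)):
        bm = b_matrix_row(sub.directions[n], sub.bvalues[n])
        rows[n, 0] = 1.0
        rows[n, 1:4] = -bm[:3]
        rows[n, 4:7] = -2.0 * bm[3:]
    return rows


def _check_rank(design: np.ndarray, need: int, what: str) -> None:
    if design.shape[0] < need or np.linalg.matrix_rank(design) < need:
        raise ValueError(
            f"{what} design is rank-deficient: need {need} independent rows, "
            f"got rank {np.linalg.matrix_rank(design)} from {design.shape[0]} volumes"
        )


def _quadratic_adcs(y: np.ndarray, sub: GradientScheme):
    """Per-direction kurtosis-corrected ADCs from a multi-shell subset.

    For each distinct direction the log signal is modeled per-direction as
    log S(b) = c0 − b·D + (b²/6)·U and (D, U) are solved by least squares
    with c0 the mean log b0 signal.  Requires ≥1 b0 volume and ≥2 distinct
    non-zero b per direction.

    Returns (adcs (nvox, ndir), unit directions (ndir, 3), c0 (nvox,)).
    """
    b0 = sub.is_b0
    if not np.any(b0):
        raise ValueError("quadratic ADC estimation requires at least one b0 volume")
    c0 = y[:, b0].mean(axis=1)
    units = sub.unit_directions
    # group volumes by (sign-normalized) direction
    keys = np.round(units * np.sign(units[:, [0]] + 1e-30), 6)
    uniq, inv = np.unique(keys[~b0], axis=0, return_inverse=True)
    dwi_idx = np.where(~b0)[0]
    adcs = np.empty((y.shape[0], len(uniq)))
    dirs = np.empty((len(uniq), 3))
    for k in range(len(uniq)):
        idx = dwi_idx[inv == k]
        bs = sub.bvalues[idx]
        if len(np.unique(bs)) < 2:
            raise ValueError(
                "quadratic ADC estimation requires >=2 distinct non-zero "
                "b-values per direction"
            )
        design = np.column_stack([-bs, bs**2 / 6.0])
        pinv = np.linalg.pinv(design)
        sol = (y[:, idx] - c0[:, None]) @ pinv.T  # (nvox, 2) -> (D, U)
        adcs[:, k] = sol[:, 0]
        dirs[k] = units[idx[0]]
    return adcs, dirs, c0


def fit_dti_regularized(
    volume: SignalVolume,
    scheme: GradientScheme,
    subset=None,
    gamma_dt: float = 0.5,
    adc_mode: str = "joint",
    tol: float = 1e-8,
    maxiter: int = 500,
) -> DiffusionTensorField:
    """Spatially regularized diffusion-tensor fit over the masked volume.

    With ``gamma_dt=0`` this equals per-voxel ordinary least squares.
    """
    if subset is None:
        subset = np.ones(len(scheme), dtype=bool)
    subset = np.asarray(subset)
    idx = np.where(subset)[0] if subset.dtype == bool else subset
    sub = scheme.subset(idx)
    y = volume.log_signals()[:, idx]

    if adc_mode == "quadratic":
        adcs, dirs, c0 = _quadratic_adcs(y, sub)
        # tensor design on ADC values: rows (n_x², n_y², n_z², 2n_xn_y, …)
        q = np.column_stack(
            [
                dirs[:, 0] ** 2,
                dirs[:, 1] ** 2,
                dirs[:, 2] ** 2,
                2 * dirs[:, 0] * dirs[:, 1],
                2 * dirs[:, 0] * dirs[:, 2],
                2 * dirs[:, 1] * dirs[:, 2],
            ]
        )
        _check_rank(q, 6, "quadratic-ADC tensor")
        problem = _solver.RegularizedProblem(
            ata=q.T @ q,
            aty=adcs @ q,
            mask=volume.mask,
            gamma=gamma_dt,
            penalty_weights=DT_PENALTY_WEIGHTS[1:],
            tol=tol,
            maxiter=maxiter,
        )
        x, info = _solver.solve(problem)
        params = np.column_stack([c0, x])
    elif adc_mode == "joint":
        design = build_dti_design(sub)
        _check_rank(design, 7, "diffusion-tensor")
        problem = _solver.RegularizedProblem(
            ata=design.T @ design,
            aty=y @ design,
            mask=volume.mask,
            gamma=gamma_dt,
            penalty_weights=DT_PENALTY_WEIGHTS,
            tol=tol,
            maxiter=maxiter,
        )
        params, info = _solver.solve(problem)
    else:
        raise ValueError(f"unknown adc_mode {adc_mode!r}")

    if not info.converged:
        raise RuntimeError(
            "conjugate gradients did not converge in the diffusion-tensor fit "
            f"(iterations={info.iterations}, relative residual={info.residual:.3e})"
        )
    return DiffusionTensorField(
        params=params,
        mask=volume.mask,
        info=info,
        meta={"gamma_dt": gamma_dt, "adc_mode": adc_mode},
    )


def principal_axis(tensor_field: DiffusionTensorField) -> AxisField:
    """Principal eigenvector per voxel with a deterministic sign convention.

    The eigenvector of the largest eigenvalue is returned with its first
    non-zero component made positive.  Degenerate voxels (λ1 ≈ λ2) are
    assigned the computed eigenvector without special handling; such axes
    are arbitrary under noise, and all consumers are sign-invariant.
    """
    t = tensor_field.tensors()
    if not np.all(np.isfinite(t)):
        raise ValueError("tensor field contains non-finite entries")
    _, vecs = np.linalg.eigh(t)  # ascending eigenvalues
    v = vecs[:, :, 2]
    sign = np.where(
        np.abs(v[:, 0]) > 1e-12,
        np.sign(v[:, 0]),
        np.where(np.abs(v[:, 1]) > 1e-12, np.sign(v[:, 1]), np.sign(v[:, 2])),
    )
    sign = np.where(sign == 0, 1.0, sign)
    return AxisField(axes=v * sign[:, None], mask=tensor_field.mask)


def compute_axes(
    volume: SignalVolume,
    scheme: GradientScheme,
    strategy: str = "AFAB",
    gamma_dt: float = 0.5,
    low_b_max: float = 1.5,
    adc_mode: str = "joint",
    tol: float = 1e-8,
    maxiter: int = 500,
) -> AxisBundle:
    """Symmetry-axis field(s) under one of the pooling strategies.

    AFAB performs a single tensor fit on all volumes and shares the
    resulting axis field across frequencies; SFAB fits per frequency with
    all shells; SFLB fits per frequency with the low shell (b ≤
    ``low_b_max`` ms/µm²) plus b0 volumes.  SFLB subsets contain a single
    non-zero shell, so they always use the joint data model.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}")
    freqs = scheme.unique_frequencies
    kw = dict(gamma_dt=gamma_dt, tol=tol, maxiter=maxiter)
    axes: dict = {}
    fields: dict = {}
    if strategy == "AFAB":
        tf = fit_dti_regularized(volume, scheme, adc_mode=adc_mode, **kw)
        ax = principal_axis(tf)
        ax.strategy = strategy
        for f in freqs:
            axes[float(f)] = ax
            fields[float(f)] = tf
    else:
        for f in freqs:
            sel = scheme.volumes_for_frequency(f)
            if strategy == "SFLB":
                sel = sel & (scheme.bvalues <= low_b_max)
                mode = "joint"
            else:
                mode = adc_mode
            tf = fit_dti_regularized(volume, scheme, subset=sel, adc_mode=mode, **kw)
            ax = principal_axis(tf)
            ax.strategy = strategy
            ax.frequency = float(f)
            axes[float(f)] = ax
            fields[float(f)] = tf
    return AxisBundle(strategy=strategy, axes=axes, tensor_fields=fields)
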