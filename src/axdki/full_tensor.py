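"""Baseline 22-parameter kurtosis-tensor fit and tensor-derived metrics.

The full DKI representation fits, per voxel, log S0, the six diffusion
tensor components and the fifteen independent components of the fully
symmetric fourth-order kurtosis tensor — 22 free parameters, versus 8
(six linear parameters plus a two-angle axis) for the axisymmetric
model.  The signal term is the same cumulant expansion used everywhere
in this package:

    log S = log S0 − b·n_i n_j D_ij + (b²/6)·D̄²·W(n),
    W(n) = n_i n_j n_k n_l W_ijkl

so both fitting routes share one forward model.  To keep the fit linear
the scaled components u_ijkl = D̄²·W_ijkl are the fitted unknowns; D̄ is
then computed from the fitted tensor block and W_ijkl = u_ijkl/D̄²
(standard two-pass convention).

Tensor-derived axisymmetric metrics: W∥ is the contraction along the
axis, W̄ the uniform sphere average, and W⊥ the average over the unit
circle perpendicular to the axis, with closed forms

    W̄  = (1/5)[W_1111 + W_2222 + W_3333 + 2(W_1122 + W_1133 + W_2233)]
    W⊥ = (3/8)(W̃_2222 + W̃_3333) + (3/4)·W̃_2233      (axis-aligned frame)

from the trigonometric moment integrals ⟨cos⁴⟩ = 3/8 and
⟨cos²sin²⟩ = 1/8 on the circle; both closed forms are locked by
quadrature oracles in the tests rather than trusted from external code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement, permutations
from math import factorial

import numpy as np

from .dti import AxisField, DiffusionTensorField, principal_axis
from .io import SignalVolume
from .model import Metrics, fractional_anisotropy
from .schemes import GradientScheme

__all__ = [
    "KurtosisTensorField",
    "W_INDICES",
    "W_MULTIPLICITY",
    "build_full_design",
    "fit_full_dki",
    "directional_w_full",
    "axisym_metrics_from_full",
]

#: the 6 unique diffusion-tensor index pairs and their multiplicities
D_INDICES = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
D_MULTIPLICITY = np.array([1, 1, 1, 2, 2, 2], dtype=float)

#: the 15 unique kurtosis-tensor index quartets (sorted) and multiplicities
W_INDICES = list(combinations_with_replacement(range(3), 4))


def _multiplicity(quartet) -> float:
    counts = [quartet.count(i) for i in set(quartet)]
    m = factorial(4)
    for c in counts:
        m //= factorial(c)
    return float(m)


W_MULTIPLICITY = np.array([_multiplicity(q) for q in W_INDICES])


@dataclass
class KurtosisTensorField:
    """Per-voxel 22-vector: log S0, 6 tensor, 15 scaled kurtosis components.

    Kurtosis columns hold u_ijkl = D̄²·W_ijkl in the order of
    ``W_INDICES``.
    """

    params: np.ndarray  # (nvox, 22)
    mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def tensor_field(self) -> DiffusionTensorField:
        return DiffusionTensorField(params=self.params[:, :7].copy(), mask=self.mask)

    def d_mean(self) -> np.ndarray:
        return self.params[:, 1:4].sum(axis=1) / 3.0

    def w_components(self) -> np.ndarray:
        """(nvox, 15) unscaled kurtosis components W_ijkl = u_ijkl/D̄²."""
        dm2 = self.d_mean() ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.params[:, 7:] / np.where(dm2 > 0, dm2, np.nan)[:, None]

    def w_tensors(self) -> np.ndarray:
        """Full symmetric (nvox, 3, 3, 3, 3) kurtosis tensors."""
        return w_full_tensor(self.w_components())


def w_full_tensor(w15: np.ndarray) -> np.ndarray:
    """Expand (..., 15) unique components into full symmetric tensors."""
    w15 = np.asarray(w15, dtype=float)
    out = np.zeros(w15.shape[:-1] + (3, 3, 3, 3))
    for k, q in enumerate(W_INDICES):
        val = w15[..., k]
        seen = set()
        for perm in permutations(q):
            if perm not in seen:
                seen.add(perm)
                out[(...,) + perm] = val
    return out


def build_full_design(scheme: GradientScheme, subset=None) -> np.ndarray:
    """The 22-column design matrix of the full kurtosis-tensor model."""
    if subset is None:
        subset = np.ones(len(scheme), dtype=bool)
    subset = np.asarray(subset)
    idx = np.where(subset)[0] if subset.dtype == bool else subset
    sub = scheme.subset(idx)
    n = sub.unit_directions
    b = sub.bvalues
    cols = [np.ones(len(sub))]
    for (i, j), m in zip(D_INDICES, D_MULTIPLICITY):
        cols.append(-b * m * n[:, i] * n[:, j])
    for q, m in zip(W_INDICES, W_MULTIPLICITY):
        quart = n[:, q[0]] * n[:, q[1]] * n[:, q[2]] * n[:, q[3]]
        cols.append((b**2 / 6.0) * m * quart)
    return np.column_stack(cols)


def fit_full_dki(
    volume: SignalVolume, scheme: GradientScheme, subset=None
) -> KurtosisTensorField:
    """Per-voxel ordinary least squares fit of the 22-parameter model.

    Requires a full-rank design: at least two non-zero shells and 15
    distinct well-distributed directions.
    """
    design = build_full_design(scheme, subset)
    rank = np.linalg.matrix_rank(design)
    if rank < 22:
        raise ValueError(
            f"full kurtosis-tensor design is rank-deficient (rank {rank} < 22); "
            "need >=2 non-zero shells and >=15 distinct directions"
        )
    if subset is None:
        subset = np.ones(len(scheme), dtype=bool)
    subset = np.asarray(subset)
    idx = np.where(subset)[0] if subset.dtype == bool else subset
    y = volume.log_signals()[:, idx]
    sol, *_ = np.linalg.lstsq(design, y.T, rcond=None)
    return KurtosisTensorField(params=sol.T, mask=volume.mask, meta={"method": "full_tensor"})


def directional_w_full(w15: np.ndarray, direction) -> np.ndarray | float:
    """Directional kurtosis W(n): full symmetric contraction of W_ijkl.

    ``w15`` holds the 15 unique components (ordering of ``W_INDICES``);
    multiplicities 1/4/6/12 account for index permutations.
    """
    n = np.asarray(direction, dtype=float)
    n = n / np.linalg.norm(n)
    w15 = np.asarray(w15, dtype=float)
    quartics = np.array(
        [n[q[0]] * n[q[1]] * n[q[2]] * n[q[3]] for q in W_INDICES]
    )
    return w15 @ (W_MULTIPLICITY * quartics)


def _sphere_mean_w(w15: np.ndarray) -> np.ndarray:
    """Closed-form uniform sphere average of W(n) (frame-invariant)."""
    comp = {q: w15[..., k] for k, q in enumerate(W_INDICES)}
    return (
        comp[(0, 0, 0, 0)]
        + comp[(1, 1, 1, 1)]
        + comp[(2, 2, 2, 2)]
        + 2.0 * (comp[(0, 0, 1, 1)] + comp[(0, 0, 2, 2)] + comp[(1, 1, 2, 2)])
    ) / 5.0


def _rotate_w(w_full: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Express full tensors (..., 3,3,3,3) in a new orthonormal basis.

    ``basis`` columns (..., 3, 3) are the new basis vectors in the old
    frame; component (p,q,r,s) of the result is the contraction with
    e'_p e'_q e'_r e'_s.
    """
    return np.einsum("...ijkl,...ip,...jq,...kr,...ls->...pqrs", w_full, basis, basis, basis, basis)


def _perp_basis(axes: np.ndarray) -> np.ndarray:
    """Orthonormal bases (..., 3, 3) with column 0 along each axis."""
    a = axes / np.linalg.norm(axes, axis=-1, keepdims=True)
    helper = np.zeros_like(a)
    # pick the world axis least aligned with a to build the perpendicular pair
    smallest = np.argmin(np.abs(a), axis=-1)
    helper[np.arange(a.shape[0]), smallest] = 1.0
    e2 = np.cross(a, helper)
    e2 /= np.linalg.norm(e2, axis=-1, keepdims=True)
    e3 = np.cross(a, e2)
    return np.stack([a, e2, e3], axis=-1)


def axisym_metrics_from_full(
    field: KurtosisTensorField, axis_field: AxisField | None = None
) -> Metrics:
    """Axisymmetric-defined metrics (D̄, FA, K∥, K⊥, W̄) from the full fit.

    The axis defaults to the principal eigenvector of this fit's own
    diffusion-tensor block.  D∥ is the axial eigenvalue and D⊥ the mean
    of the two radial eigenvalues; K∥ = W∥·D̄²/D∥², K⊥ = W⊥·D̄²/D⊥².
    """
    if axis_field is None:
        axis_field = principal_axis(field.tensor_field())
    axes = axis_field.axes
    tensors = field.tensor_field().tensors()
    evals, evecs = np.linalg.eigh(tensors)
    # axial/radial eigenvalues relative to the supplied axis: project
    # eigenvalues by eigenvector alignment with the axis
    align = np.abs(np.einsum("vi,vij->vj", axes, evecs))
    par_idx = np.argmax(align, axis=1)
    nvox = tensors.shape[0]
    d_par = evals[np.arange(nvox), par_idx]
    d_perp = (evals.sum(axis=1) - d_par) / 2.0
    dmean = evals.mean(axis=1)

    w15 = field.w_components()
    w_mean = _sphere_mean_w(w15)
    wfull = w_full_tensor(w15)
    # W parallel: contraction along the axis
    w_par = np.einsum("vijkl,vi,vj,vk,vl->v", wfull, axes, axes, axes, axes)
    # W perpendicular: circle average in the axis-aligned frame
    basis = _perp_basis(axes)
    wrot = _rotate_w(wfull, basis)
    w_perp = 0.375 * (wrot[:, 1, 1, 1, 1] + wrot[:, 2, 2, 2, 2]) + 0.75 * wrot[:, 1, 1, 2, 2]

    with np.errstate(invalid="ignore", divide="ignore"):
        k_par = np.where(d_par != 0, w_par * dmean**2 / d_par**2, np.nan)
        k_perp = np.where(d_perp != 0, w_perp * dmean**2 / d_perp**2, np.nan)
    return Metrics(
        d_mean=dmean,
        fa=fractional_anisotropy(d_perp, d_par),
        k_par=k_par,
        k_perp=k_perp,
        w_mean=w_mean,
        meta=dict(field.meta, method="full_tensor"),
    )
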