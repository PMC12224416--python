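"""Regularized linear inversion engine for masked image volumes.

Minimizes, jointly over all masked voxels,

    ||A x − y||² + γ ||T x||²

where the data operator A is voxel-separable (one small design matrix
per voxel, or one shared design) and the penalty T takes weighted
spatial first differences of selected parameter components, coupling
each voxel to its grid neighbors.  The problem is solved via conjugate
gradients on the normal equations

    (AᵀA + γ TᵀT) x = Aᵀ y

with a matrix-free normal operator — the full matrix is never formed.

Boundary convention: the forward difference is defined only where both
the voxel and its +1 neighbor lie inside the mask, and is zero
otherwise (Neumann-style), so the penalty never couples masked to
unmasked voxels.  The adjoint implemented here is the exact transpose
of that masked forward difference; the pairing ⟨Tu, v⟩ = ⟨u, Tᵀv⟩ is
locked by an adjoint unit test, which is the single most bug-prone
contract in this module.

γ = 0 reduces exactly to independent per-voxel ordinary least squares.
The solver is deterministic: identical inputs give identical iterates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.linalg import LinearOperator, cg

__all__ = ["RegularizedProblem", "SolveInfo", "solve", "apply_normal_operator"]


@dataclass
class SolveInfo:
    """Diagnostics of one conjugate-gradient solve."""

    iterations: int
    residual: float
    converged: bool

    def as_dict(self) -> dict:
        return {
            "iterations": self.iterations,
            "residual": self.residual,
            "converged": self.converged,
        }


@dataclass
class RegularizedProblem:
    """A voxel-separable least-squares problem with a spatial-difference penalty.

    Parameters
    ----------
    ata : (P, P) or (nvox, P, P) array
        Per-voxel normal matrices AᵀA (shared when the design does not
        vary across voxels).
    aty : (nvox, P) array
        Per-voxel right-hand sides Aᵀy.
    mask : 3D bool array
        Fit domain; ``mask.sum() == nvox`` and masked voxels are ordered
        as by ``np.where(mask)``.
    gamma : float
        Regularization weight γ ≥ 0.
    penalty_weights : (P,) array
        Per-component weight w_p inside the penalty (entries w_p·d_a·x_p);
        a weight of 0 removes the component from the penalty (log S0 is
        never penalized).
    """

    ata: np.ndarray
    aty: np.ndarray
    mask: np.ndarray
    gamma: float
    penalty_weights: np.ndarray
    tol: float = 1e-8
    maxiter: int = 500

    def __post_init__(self) -> None:
        self.ata = np.asarray(self.ata, dtype=float)
        self.aty = np.asarray(self.aty, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.penalty_weights = np.asarray(self.penalty_weights, dtype=float)
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")
        nvox, p = self.aty.shape
        if int(self.mask.sum()) != nvox:
            raise ValueError("aty rows must match the number of masked voxels")
        if self.penalty_weights.shape != (p,):
            raise ValueError("penalty_weights must have one entry per parameter")

    @property
    def n_params(self) -> int:
        return self.aty.shape[1]


# ----------------------------------------------------------------- gradients


def masked_forward_diff(u: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Forward first differences of (P, nx, ny, nz) fields along x, y, z.

    Returns a (3, P, nx, ny, nz) array.  Entry a at voxel m is
    u[m + e_a] − u[m] when both voxels are inside the mask, else 0.
    """
    g = np.zeros((3,) + u.shape)
    for a in range(3):
        ax = a + 1  # spatial axis in u
        lo = tuple(slice(0, -1) if i == ax else slice(None) for i in range(u.ndim))
        hi = tuple(slice(1, None) if i == ax else slice(None) for i in range(u.ndim))
        mlo = tuple(slice(0, -1) if i == a else slice(None) for i in range(3))
        mhi = tuple(slice(1, None) if i == a else slice(None) for i in range(3))
        valid = mask[mlo] & mask[mhi]
        g[a][lo] = (u[hi] - u[lo]) * valid
    return g


def masked_forward_diff_adjoint(g: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Exact adjoint of :func:`masked_forward_diff`."""
    u = np.zeros(g.shape[1:])
    for a in range(3):
        ax = a + 1
        lo = tuple(slice(0, -1) if i == ax else slice(None) for i in range(u.ndim))
        hi = tuple(slice(1, None) if i == ax else slice(None) for i in range(u.ndim))
        mlo = tuple(slice(0, -1) if i == a else slice(None) for i in range(3))
        mhi = tuple(slice(1, None) if i == a else slice(None) for i in range(3))
        valid = mask[mlo] & mask[mhi]
        z = g[a][lo] * valid
        u[hi] += z
        u[lo] -= z
    return u


def _scatter(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """(nvox, P) masked parameters -> (P, nx, ny, nz) grid, zeros outside."""
    grid = np.zeros((x.shape[1],) + mask.shape)
    grid[:, mask] = x.T
    return grid


def penalty_normal_apply(x: np.ndarray, problem: RegularizedProblem) -> np.ndarray:
    """TᵀT x for the weighted masked-difference penalty, as (nvox, P)."""
    grid = _scatter(x, problem.mask)
    g = masked_forward_diff(grid, problem.mask)
    u = masked_forward_diff_adjoint(g, problem.mask)
    out = u[:, problem.mask].T * problem.penalty_weights[None, :] ** 2
    return out


def _data_normal_apply(x: np.ndarray, ata: np.ndarray) -> np.ndarray:
    if ata.ndim == 2:
        return x @ ata  # symmetric
    return np.einsum("vij,vj->vi", ata, x)


def apply_normal_operator(x: np.ndarray, problem: RegularizedProblem) -> np.ndarray:
    """Matrix-free evaluation of (AᵀA + γTᵀT)x on a (nvox, P) field."""
    x = np.asarray(x, dtype=float)
    if x.shape != problem.aty.shape:
        raise ValueError(
            f"parameter field shape {x.shape} does not match problem "
            f"layout {problem.aty.shape}"
        )
    out = _data_normal_apply(x, problem.ata)
    if problem.gamma > 0:
        out = out + problem.gamma * penalty_normal_apply(x, problem)
    return out


def solve(
    problem: RegularizedProblem, initial: np.ndarray | None = None
) -> tuple[np.ndarray, SolveInfo]:
    """Solve the normal equations by conjugate gradients.

    Returns the (nvox, P) parameter field and diagnostics.  A solve that
    exhausts ``maxiter`` returns the best iterate flagged non-converged;
    callers decide whether that is an error.
    """
    nvox, p = problem.aty.shape
    shape = (nvox * p, nvox * p)

    def matvec(v: np.ndarray) -> np.ndarray:
        return apply_normal_operator(v.reshape(nvox, p), problem).ravel()

    op = LinearOperator(shape, matvec=matvec, dtype=float)
    b = problem.aty.ravel()
    x0 = None if initial is None else np.asarray(initial, dtype=float).ravel()
    count = {"n": 0}

    def cb(_xk):
        count["n"] += 1

    x, info = cg(
        op, b, x0=x0, rtol=problem.tol, atol=0.0, maxiter=problem.maxiter, callback=cb
    )
    res = float(np.linalg.norm(matvec(x) - b))
    bnorm = float(np.linalg.norm(b))
    rel = res / bnorm if bnorm > 0 else res
    return x.reshape(nvox, p), SolveInfo(
        iterations=count["n"], residual=rel, converged=(info == 0)
    )
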