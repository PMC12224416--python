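"""Independent dense/brute-force oracles used to check the solver and tensors.

Everything here is deliberately written as directly as possible — explicit
sparse assembly and dense linear algebra — and shares no code with the
matrix-free implementation it checks.
"""

import numpy as np
import scipy.sparse as sp


def dense_penalty_matrix(mask: np.ndarray, penalty_weights: np.ndarray) -> sp.csr_matrix:
    """Explicit sparse T: weighted forward differences of masked voxels.

    Unknown ordering matches the solver layout: index = voxel*P + param,
    voxels ordered as np.where(mask).
    """
    mask = np.asarray(mask, dtype=bool)
    p = len(penalty_weights)
    vox_index = -np.ones(mask.shape, dtype=int)
    vox_index[mask] = np.arange(mask.sum())
    rows, cols, vals = [], [], []
    r = 0
    offsets = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
    for (i, j, k) in np.argwhere(mask):
        m = vox_index[i, j, k]
        for di, dj, dk in offsets:
            ii, jj, kk = i + di, j + dj, k + dk
            inside = (
                ii < mask.shape[0] and jj < mask.shape[1] and kk < mask.shape[2]
                and mask[ii, jj, kk]
            )
            for q in range(p):
                w = penalty_weights[q]
                if inside and w != 0:
                    n = vox_index[ii, jj, kk]
                    rows += [r, r]
                    cols += [n * p + q, m * p + q]
                    vals += [w, -w]
                r += 1
    return sp.csr_matrix((vals, (rows, cols)), shape=(r, mask.sum() * p))


def dense_regularized_solve(ata, aty, mask, gamma, penalty_weights):
    """Direct dense solve of (AᵀA + γTᵀT)x = Aᵀy over all masked voxels."""
    aty = np.asarray(aty, dtype=float)
    nvox, p = aty.shape
    ata = np.asarray(ata, dtype=float)
    if ata.ndim == 2:
        blocks = [ata] * nvox
    else:
        blocks = [ata[v] for v in range(nvox)]
    normal = sp.block_diag(blocks).toarray()
    if gamma > 0:
        t = dense_penalty_matrix(mask, np.asarray(penalty_weights, dtype=float))
        normal = normal + gamma * (t.T @ t).toarray()
    x = np.linalg.solve(normal, aty.ravel())
    return x.reshape(nvox, p)


def brute_force_w_contraction(w_full: np.ndarray, n: np.ndarray) -> float:
    """W(n) by an explicit quadruple loop over all 81 index tuples."""
    n = np.asarray(n, dtype=float)
    n = n / np.linalg.norm(n)
    total = 0.0
    for i in range(3):
        for j in range(3):
            for k in range(3):
                for l in range(3):
                    total += w_full[i, j, k, l] * n[i] * n[j] * n[k] * n[l]
    return total


def fibonacci_sphere(n: int, seed: int = 0) -> np.ndarray:
    """Quasi-uniform directions for quadrature checks (jittered by seed)."""
    rng = np.random.default_rng(seed)
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5**0.5) * i
    z = 1 - 2 * i / n
    r = np.sqrt(np.maximum(0.0, 1 - z**2))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    if seed:
        pts += 1e-9 * rng.standard_normal(pts.shape)
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts
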