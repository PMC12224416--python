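"""Diffusion gradient encoding schemes and geometry helpers.

The central object is :class:`GradientScheme`, one entry per acquired
volume: an encoding direction, a b-value, an oscillation frequency
(0 Hz denotes PGSE) and a b0 flag.  Directions are stored in the
channel-amplitude convention in which a component of 1 means that
gradient channel is at its maximum amplitude; they are unit-normalized
internally wherever the b-matrix is formed, and the per-volume b-value
is always taken as authoritative.

Units: b-values are carried in ms/µm² internally.  FSL-style bval files
(s/mm²) are converted on read (1000 s/mm² = 1 ms/µm²).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GradientScheme",
    "ten_direction_scheme",
    "multi_shell_scheme",
    "b_matrix_row",
    "b_efficiency_ratio",
    "effective_diffusion_time",
    "central_angle",
    "fibonacci_directions",
]

# The efficient 10-direction scheme: an efficient 6-direction scheme
# (two channels simultaneously at maximum) combined with a tetrahedral
# scheme at 2/3 amplitude on all three channels.
_TEN_DIRECTIONS = np.array(
    [
        [0.0, 1.0, 1.0],
        [0.0, 1.0, -1.0],
        [1.0, 0.0, 1.0],
        [1.0, 0.0, -1.0],
        [1.0, 1.0, 0.0],
        [1.0, -1.0, 0.0],
        [2 / 3, 2 / 3, 2 / 3],
        [2 / 3, 2 / 3, -2 / 3],
        [2 / 3, -2 / 3, 2 / 3],
        [-2 / 3, 2 / 3, 2 / 3],
    ]
)


def ten_direction_scheme() -> np.ndarray:
    """Return the efficient 10-direction set as a (10, 3) array.

    Rows are channel amplitudes (1 = maximum single-channel amplitude),
    in the canonical order: the six two-channel directions followed by
    the four tetrahedral directions at amplitude 2/3.
    """
    return _TEN_DIRECTIONS.copy()


@dataclass
class GradientScheme:
    """Per-volume encoding directions, b-values and oscillation frequencies.

    Parameters
    ----------
    directions : (N, 3) array
        Channel-amplitude direction vectors.  b0 volumes may have zero rows.
    bvalues : (N,) array
        Diffusion weightings in ms/µm².
    frequencies : (N,) array
        Oscillation frequency per volume in Hz; 0 denotes PGSE.
    """

    directions: np.ndarray
    bvalues: np.ndarray
    frequencies: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.directions = np.atleast_2d(np.asarray(self.directions, dtype=float))
        self.bvalues = np.asarray(self.bvalues, dtype=float).ravel()
        if self.frequencies is None:
            self.frequencies = np.zeros_like(self.bvalues)
        self.frequencies = np.asarray(self.frequencies, dtype=float).ravel()
        n = len(self.bvalues)
        if self.directions.shape != (n, 3) or len(self.frequencies) != n:
            raise ValueError(
                "directions, bvalues and frequencies must have one entry per volume"
            )
        if np.any(self.bvalues < 0):
            raise ValueError("b-values must be non-negative")
        norms = np.linalg.norm(self.directions, axis=1)
        if np.any((self.bvalues > 0) & (norms == 0)):
            raise ValueError("non-b0 volumes must have a nonzero direction")

    def __len__(self) -> int:
        return len(self.bvalues)

    @property
    def is_b0(self) -> np.ndarray:
        return self.bvalues == 0

    @property
    def unit_directions(self) -> np.ndarray:
        """Directions normalized to unit length; b0 rows are left at zero."""
        norms = np.linalg.norm(self.directions, axis=1, keepdims=True)
        out = np.zeros_like(self.directions)
        nz = norms[:, 0] > 0
        out[nz] = self.directions[nz] / norms[nz]
        return out

    def subset(self, index) -> "GradientScheme":
        index = np.asarray(index)
        return GradientScheme(
            self.directions[index], self.bvalues[index], self.frequencies[index]
        )

    def volumes_for_frequency(self, frequency: float, atol: float = 1e-9) -> np.ndarray:
        """Boolean selector of all volumes (b0 included) at one frequency."""
        return np.isclose(self.frequencies, frequency, atol=atol)

    @property
    def unique_frequencies(self) -> np.ndarray:
        return np.unique(self.frequencies)

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_fsl(
        cls,
        bval_path: str | Path,
        bvec_path: str | Path,
        freq_path: str | Path | None = None,
        renormalize_tol: float = 1e-3,
    ) -> "GradientScheme":
        """Read an FSL bval/bvec pair plus an optional frequency table.

        bval entries are interpreted as s/mm² and converted to ms/µm².
        bvec rows are x/y/z components, one column per volume; directions
        whose norm deviates from 1 by more than ``renormalize_tol`` are
        flagged with a warning and unit-normalized internally wherever
        the b-matrix is formed (b0 zero-columns excepted).  A missing
        frequency table yields an all-zero (pure PGSE) frequency vector.
        """
        bvals = np.loadtxt(bval_path, ndmin=1).ravel() / 1000.0
        bvecs = np.loadtxt(bvec_path, ndmin=2)
        if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
            bvecs = bvecs.T
        elif bvecs.shape == (3, 3):
            # ambiguous; FSL convention is 3 rows x N columns
            bvecs = bvecs.T
        norms = np.linalg.norm(bvecs, axis=1)
        off = (bvals > 0) & (np.abs(norms - 1) > renormalize_tol)
        if np.any(off):
            warnings.warn(
                f"{off.sum()} bvec column(s) deviate from unit norm "
                "(channel-amplitude convention?); directions are "
                "unit-normalized internally for b-matrix use",
                stacklevel=2,
            )
        freqs = None
        if freq_path is not None and Path(freq_path).exists():
            freqs = np.loadtxt(freq_path, ndmin=1).ravel()
        return cls(bvecs, bvals, freqs)

    def to_fsl(
        self,
        bval_path: str | Path,
        bvec_path: str | Path,
        freq_path: str | Path | None = None,
    ) -> None:
        """Write bval (s/mm²), bvec (3 rows × N columns) and frequency files."""
        np.savetxt(bval_path, (self.bvalues * 1000.0)[None, :], fmt="%.6g")
        np.savetxt(bvec_path, self.directions.T, fmt="%.10g")
        if freq_path is not None:
            np.savetxt(freq_path, self.frequencies[None, :], fmt="%.6g")


def multi_shell_scheme(
    directions: np.ndarray | None = None,
    bvalues: tuple[float, ...] = (1.0, 2.5),
    frequencies: tuple[float, ...] = (0.0,),
    n_b0: int = 2,
) -> GradientScheme:
    """Build a multi-frequency, multi-shell scheme from one direction set.

    For each frequency the block is ``n_b0`` b0 volumes followed by every
    direction at every shell, mirroring a typical frequency-dependent DKI
    protocol (shells 1.0 and 2.5 ms/µm², 2 b0s per frequency).  b0 volumes
    carry the frequency label of their block.
    """
    if directions is None:
        directions = ten_direction_scheme()
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    dirs, bs, fs = [], [], []
    for f in frequencies:
        for _ in range(n_b0):
            dirs.append(np.zeros(3))
            bs.append(0.0)
            fs.append(f)
        for b in bvalues:
            for d in directions:
                dirs.append(d)
                bs.append(b)
                fs.append(f)
    return GradientScheme(np.array(dirs), np.array(bs), np.array(fs))


def b_matrix_row(direction, b: float) -> np.ndarray:
    """b-matrix entries (b_xx, b_yy, b_zz, b_xy, b_xz, b_yz) for one volume.

    The direction is unit-normalized internally, so b_ij = b·n̂_i·n̂_j and
    the trace equals b.  A zero direction is only valid for b = 0.
    """
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        if b > 0:
            raise ValueError("zero direction with b > 0 is not a valid volume")
        return np.zeros(6)
    n = d / norm
    return b * np.array(
        [n[0] ** 2, n[1] ** 2, n[2] ** 2, n[0] * n[1], n[0] * n[2], n[1] * n[2]]
    )


def b_efficiency_ratio(direction) -> float:
    """b-value of a channel-amplitude direction relative to a single channel at max.

    For fixed waveform timing b ∝ |G|², so a direction given in channel
    amplitudes (max per channel = 1) achieves ``|G|²`` times the b-value of
    a single-channel-at-maximum direction.  (0,1,1) gives exactly 2.
    """
    d = np.asarray(direction, dtype=float)
    return float(d @ d)


def effective_diffusion_time(frequency: float) -> float:
    """Effective diffusion time Δt_eff = 9/(64·f) of cosine OGSE, in ms.

    Only defined for oscillating encodings (frequency > 0); the PGSE
    diffusion time is a sequence parameter and must be supplied explicitly.
    """
    if frequency <= 0:
        raise ValueError(
            "effective diffusion time is defined for f > 0; "
            "supply the PGSE diffusion time explicitly"
        )
    return 1000.0 * 9.0 / (64.0 * frequency)


def central_angle(v1, v2) -> float:
    """Great-circle angle between two axes in degrees, in [0, 90].

    Eigenvector axes are sign-indeterminate, so the angle is computed from
    the absolute dot product and antipodal vectors are 0° apart.
    """
    a = np.asarray(v1, dtype=float)
    b = np.asarray(v2, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("central angle undefined for a zero vector")
    c = abs(float(a @ b) / (na * nb))
    return float(np.degrees(np.arccos(min(c, 1.0))))


def fibonacci_directions(n: int) -> np.ndarray:
    """n approximately uniformly distributed unit directions (spiral construction).

    Deterministic golden-angle spiral on the sphere.  Note the spiral's
    symmetry makes it slightly non-generic for high-order design matrices;
    use :func:`repulsion_directions` where genericity matters.
    """
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5**0.5) * i
    z = 1 - 2 * i / n
    r = np.sqrt(np.maximum(0.0, 1 - z**2))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def repulsion_directions(n: int, seed: int = 0, iterations: int = 200, step: float = 0.05) -> np.ndarray:
    """n uniformly distributed unit directions by electrostatic repulsion.

    Antipodally symmetric Coulomb repulsion (each point repels both the
    others and their antipodes), the standard construction for diffusion
    encoding direction sets.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    p = rng.standard_normal((n, 3))
    p /= np.linalg.norm(p, axis=1, keepdims=True)
    for _ in range(iterations):
        force = np.zeros_like(p)
        for sign in (1.0, -1.0):
            d = p[:, None, :] - sign * p[None, :, :]  # (n, n, 3)
            r = np.linalg.norm(d, axis=2)
            np.fill_diagonal(r, np.inf)
            r[r < 1e-9] = np.inf
            force += (d / r[:, :, None] ** 3).sum(axis=1)
        p += step * force
        p /= np.linalg.norm(p, axis=1, keepdims=True)
    return p
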