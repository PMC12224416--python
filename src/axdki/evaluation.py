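"""Quantitative map evaluation: CSR, SNR, axis agreement, smoothing baseline.

The contrast-to-standard-deviation ratio between two regions of
interest of a parameter map is

    CSR = (mean_A − mean_B) / sqrt(σ²_A + σ²_B)

Undefined (NaN) voxels — e.g. blackened negative-kurtosis voxels marked
undefined downstream — are excluded from ROI statistics and counted
separately, since their prevalence is itself a noise indicator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import SignalVolume

__all__ = [
    "RoiPair",
    "roi_stats",
    "csr",
    "snr_map",
    "axis_agreement_histogram",
    "gaussian_presmooth",
]

#: FA bin edges separating low / moderate (0.2 < FA < 0.4) / high anisotropy
DEFAULT_FA_BINS = (0.0, 0.2, 0.4, 1.0)


@dataclass
class RoiPair:
    """Two disjoint, non-empty labeled voxel sets (e.g. WM and GM)."""

    a: np.ndarray
    b: np.ndarray
    name_a: str = "WM"
    name_b: str = "GM"

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=bool)
        self.b = np.asarray(self.b, dtype=bool)
        if not self.a.any() or not self.b.any():
            raise ValueError("both ROIs must be non-empty")
        if np.any(self.a & self.b):
            raise ValueError("ROIs must be disjoint")


def roi_stats(values: np.ndarray, roi: np.ndarray) -> dict:
    """Mean/std over finite ROI voxels, with the undefined-voxel count."""
    v = np.asarray(values, dtype=float)[np.asarray(roi, dtype=bool)]
    finite = np.isfinite(v)
    n = int(finite.sum())
    if n == 0:
        raise ValueError("ROI contains no finite values")
    return {
        "mean": float(v[finite].mean()),
        "std": float(v[finite].std(ddof=0)),
        "n": n,
        "n_undefined": int((~finite).sum()),
    }


def csr(values: np.ndarray, rois: RoiPair) -> float:
    """Contrast-to-standard-deviation ratio of a map between two ROIs."""
    sa = roi_stats(values, rois.a)
    sb = roi_stats(values, rois.b)
    return (sa["mean"] - sb["mean"]) / np.sqrt(sa["std"] ** 2 + sb["std"] ** 2)


def snr_map(b0_stack: np.ndarray, roi: np.ndarray | None = None):
    """Per-voxel SNR across repeated b0 acquisitions (mean/std over axis 0).

    Zero-std voxels are flagged with +inf rather than raising; they are
    excluded from the ROI mean.  Requires ≥3 repetitions.

    Returns (snr grid, ROI mean or None).
    """
    stack = np.asarray(b0_stack, dtype=float)
    if stack.shape[0] < 3:
        raise ValueError("SNR estimation requires at least 3 b0 repetitions")
    mean = stack.mean(axis=0)
    std = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(std > 0, mean / std, np.inf)
    roi_mean = None
    if roi is not None:
        vals = snr[np.asarray(roi, dtype=bool)]
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            raise ValueError("ROI contains no finite SNR values")
        roi_mean = float(vals.mean())
    return snr, roi_mean


def axis_agreement_histogram(
    axes_by_frequency: dict,
    fa: np.ndarray,
    fa_bins=DEFAULT_FA_BINS,
    angle_bins=None,
) -> pd.DataFrame:
    """Central-angle histograms between per-frequency axis fields, by FA bin.

    ``axes_by_frequency`` maps frequency → (nvox, 3) unit axes; ``fa`` is
    the (nvox,) anisotropy used for binning.  Returns a long-format table
    with one row per (frequency pair, FA bin, angle bin).
    """
    freqs = sorted(axes_by_frequency)
    if len(freqs) < 2:
        raise ValueError("need axis fields at >=2 frequencies")
    if angle_bins is None:
        angle_bins = np.arange(0.0, 91.0, 5.0)
    angle_bins = np.asarray(angle_bins, dtype=float)
    fa = np.asarray(fa, dtype=float)
    rows = []
    for i, fa_lo in enumerate(fa_bins[:-1]):
        fa_hi = fa_bins[i + 1]
        in_bin = (fa >= fa_lo) & (fa < fa_hi) & np.isfinite(fa)
        for j, f1 in enumerate(freqs):
            for f2 in freqs[j + 1 :]:
                a1 = axes_by_frequency[f1][in_bin]
                a2 = axes_by_frequency[f2][in_bin]
                angles = _central_angles(a1, a2)
                counts, _ = np.histogram(angles, bins=angle_bins)
                for k, c in enumerate(counts):
                    rows.append(
                        {
                            "freq_a": f1,
                            "freq_b": f2,
                            "fa_low": fa_lo,
                            "fa_high": fa_hi,
                            "angle_low": angle_bins[k],
                            "angle_high": angle_bins[k + 1],
                            "count": int(c),
                        }
                    )
    return pd.DataFrame(rows)


def _central_angles(a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
    """Vectorized antipodally invariant great-circle angles, degrees."""
    n1 = np.linalg.norm(a1, axis=1)
    n2 = np.linalg.norm(a2, axis=1)
    c = np.abs(np.sum(a1 * a2, axis=1)) / np.maximum(n1 * n2, np.finfo(float).tiny)
    return np.degrees(np.arccos(np.clip(c, 0.0, 1.0)))


def median_pair_angle(axes_by_frequency: dict, select: np.ndarray | None = None) -> float:
    """Median central angle pooled over all frequency pairs (optionally masked)."""
    freqs = sorted(axes_by_frequency)
    angles = []
    for j, f1 in enumerate(freqs):
        for f2 in freqs[j + 1 :]:
            a1 = axes_by_frequency[f1]
            a2 = axes_by_frequency[f2]
            if select is not None:
                a1, a2 = a1[select], a2[select]
            angles.append(_central_angles(a1, a2))
    return float(np.median(np.concatenate(angles)))


def gaussian_presmooth(volume: SignalVolume, sigma: float) -> SignalVolume:
    """3D Gaussian filtering of every magnitude volume before fitting.

    ``sigma`` is in voxels; 0 returns a bitwise-identical copy.  The
    kernel is truncated at 4σ with reflect boundary handling — the
    dialect matters only for edge voxels and is stated here for
    reproducibility.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return SignalVolume(
            data=volume.data.copy(), mask=volume.mask.copy(), affine=volume.affine.copy()
        )
    out = np.empty_like(volume.data)
    for v in range(volume.n_volumes):
        out[..., v] = ndimage.gaussian_filter(
            volume.data[..., v], sigma=sigma, truncate=4.0, mode="reflect"
        )
    return SignalVolume(data=out, mask=volume.mask.copy(), affine=volume.affine.copy())
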