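"""Dataset containers and NIfTI / gradient-table / sidecar I/O.

A dataset is a 4D diffusion-weighted stack (NIfTI), an FSL bval/bvec
pair, an optional single-row oscillation-frequency table (Hz per
volume) and a binary brain mask.  Directions are taken in image
coordinates; gradient-versus-image frame reorientation is out of scope
for this package and must be handled upstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .schemes import GradientScheme

__all__ = ["SignalVolume", "read_dataset", "write_dataset", "save_map", "save_sidecar"]

LOG_FLOOR_EPS = 1e-6


@dataclass
class SignalVolume:
    """A 4D magnitude image stack with mask and voxel geometry.

    ``data`` has shape (nx, ny, nz, nvol); ``mask`` is a 3D boolean fit
    domain.  The log-transformed masked view feeds every fit.
    """

    data: np.ndarray
    mask: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("signal data must be a 4D (x, y, z, volume) array")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:3], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must match the spatial grid")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def masked_signals(self) -> np.ndarray:
        """(nvox, nvol) magnitude signals of the masked voxels."""
        return self.data[self.mask, :]

    def log_signals(self) -> np.ndarray:
        """Floored log transform y = log(max(S, ε·S0_est)) of masked signals.

        S0_est is the per-voxel maximum signal; the floor (ε = 1e-6)
        guards against non-positive intensities produced by noise.  The
        number of guarded samples is recorded in ``last_guard_count``.
        """
        s = self.masked_signals()
        s0 = np.maximum(s.max(axis=1, keepdims=True), np.finfo(float).tiny)
        floor = LOG_FLOOR_EPS * s0
        guarded = s < floor
        self.last_guard_count = int(guarded.sum())
        return np.log(np.maximum(s, floor))

    def scatter(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Place per-masked-voxel values onto the 3D grid (``fill`` outside)."""
        grid = np.full(self.mask.shape, fill, dtype=float)
        grid[self.mask] = values
        return grid


def read_dataset(
    image_path: str | Path,
    bval_path: str | Path,
    bvec_path: str | Path,
    freq_path: str | Path | None = None,
    mask_path: str | Path | None = None,
) -> tuple[SignalVolume, GradientScheme]:
    """Load a diffusion dataset; b-values are converted s/mm² → ms/µm².

    A missing frequency table yields a pure-PGSE (all-zero) frequency
    vector, under which the AFAB and SFAB axis strategies coincide.
    """
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    scheme = GradientScheme.from_fsl(bval_path, bvec_path, freq_path)
    if data.ndim != 4 or data.shape[3] != len(scheme):
        raise ValueError(
            f"volume count mismatch: image has shape {data.shape}, "
            f"gradient table lists {len(scheme)} volumes"
        )
    mask = None
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    vol = SignalVolume(data=data, mask=mask, affine=np.asarray(img.affine))
    if not np.all(np.isfinite(vol.masked_signals())):
        raise ValueError("non-finite voxel intensities inside the mask")
    return vol, scheme


def write_dataset(
    volume: SignalVolume,
    scheme: GradientScheme,
    out_dir: str | Path,
    stem: str = "dwi",
) -> dict:
    """Write image + mask + bval/bvec/frequency files; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out / f"{stem}.nii.gz",
        "mask": out / f"{stem}_mask.nii.gz",
        "bval": out / f"{stem}.bval",
        "bvec": out / f"{stem}.bvec",
        "freq": out / f"{stem}.freq",
    }
    nib.save(nib.Nifti1Image(volume.data.astype(np.float32), volume.affine), str(paths["image"]))
    nib.save(
        nib.Nifti1Image(volume.mask.astype(np.uint8), volume.affine), str(paths["mask"])
    )
    scheme.to_fsl(paths["bval"], paths["bvec"], paths["freq"])
    return {k: str(v) for k, v in paths.items()}


def save_map(
    grid: np.ndarray,
    affine: np.ndarray,
    path: str | Path,
    sidecar: dict | None = None,
    description: str = "",
) -> None:
    """Write a scalar or vector map as NIfTI, with an optional JSON sidecar.

    NaN sentinels (undefined metric values) are preserved verbatim.
    """
    img = nib.Nifti1Image(np.asarray(grid, dtype=np.float32), np.asarray(affine))
    if description:
        img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))
    if sidecar is not None:
        stem = Path(str(path)).name.removesuffix(".gz").removesuffix(".nii")
        save_sidecar(sidecar, Path(str(path)).parent / f"{stem}.json")


def save_sidecar(payload: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=_default))
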