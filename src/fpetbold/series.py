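"""4D frame-series container shared by fPET and fMRI, with NIfTI round-trip."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .protocol import FrameTiming

__all__ = ["FrameSeries"]


@dataclass
class FrameSeries:
    """A masked 4D image time series on a uniform frame grid.

    ``data`` has shape (x, y, z, frames); ``brain_mask`` is a boolean 3D
    grid.  Values outside the mask are held at 0 by every operation in the
    package.  ``voxel_size`` is mm per axis.
    """

    data: np.ndarray
    timing: FrameTiming
    voxel_size: tuple[float, float, float]
    brain_mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (x, y, z, frames)")
        if self.data.shape[:3] != self.brain_mask.shape:
            raise ValueError("mask shape does not match data grid")
        if self.data.shape[3] != self.timing.n_frames:
            raise ValueError("number of frames does not match timing")
        if not np.all(np.isfinite(self.data[self.brain_mask])):
            raise ValueError("non-finite values inside the brain mask")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def in_mask(self) -> np.ndarray:
        """Voxel-by-frame matrix (n_mask_voxels, n_frames) of in-mask data."""
        return self.data[self.brain_mask]

    def with_data(self, data: np.ndarray) -> "FrameSeries":
        """Copy of this series carrying new data on the same grid/timing."""
        return FrameSeries(data, self.timing, self.voxel_size, self.brain_mask)

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size) + [1.0])
        return aff

    # ---- NIfTI round-trip -------------------------------------------------

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine())
        img.header.set_zooms(tuple(self.voxel_size) + (self.timing.frame_duration,))
        nib.save(img, str(path))

    def save(self, path: str | Path, mask_path: str | Path | None = None) -> None:
        self.to_nifti(path)
        if mask_path is not None:
            nib.save(
                nib.Nifti1Image(self.brain_mask.astype(np.uint8), self.affine()),
                str(mask_path),
            )

    @classmethod
    def from_nifti(
        cls,
        path: str | Path,
        mask: np.ndarray | str | Path,
        frame_duration: float | None = None,
        start: float = 0.0,
    ) -> "FrameSeries":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=float)
        zooms = img.header.get_zooms()
        voxel_size = tuple(float(z) for z in zooms[:3])
        if frame_duration is None:
            frame_duration = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
        if isinstance(mask, (str, Path)):
            mask = np.asanyarray(nib.load(str(mask)).dataobj) > 0
        timing = FrameTiming.uniform(data.shape[3], frame_duration, start=start)
        return cls(data, timing, voxel_size, np.asarray(mask, dtype=bool))
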