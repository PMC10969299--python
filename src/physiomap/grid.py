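"""Volume containers shared by every mapping stage.

A :class:`VolumeGrid` is a 3-D scalar field plus its voxel geometry; it is the
carrier type for every biomarker map in the pipeline.  4-D dynamic data gets
its own container in :mod:`physiomap.perfusion`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeGrid"]


@dataclass
class VolumeGrid:
    """A 3-D scalar field with voxel spacing and a world affine.

    Parameters
    ----------
    data
        3-D array of voxel values.
    voxel_size_mm
        Isotropic or per-axis spacing in millimetres.
    affine
        4x4 voxel-to-world transform.  When omitted, a diagonal affine built
        from ``voxel_size_mm`` is used.
    meta
        Free-form provenance (units, formula parse identifiers, ...).
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"VolumeGrid expects 3-D data, got shape {self.data.shape}")
        if np.isscalar(self.voxel_size_mm):
            self.voxel_size_mm = (float(self.voxel_size_mm),) * 3
        else:
            self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size_mm, 1.0])
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def like(self, data: np.ndarray, **meta) -> "VolumeGrid":
        """New grid with the same geometry but different voxel values."""
        merged = {**self.meta, **meta}
        return VolumeGrid(np.asarray(data), self.voxel_size_mm, self.affine.copy(), merged)

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)
        img.header.set_zooms(self.voxel_size_mm)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "VolumeGrid":
        img = nib.load(str(path))
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asanyarray(img.dataobj).astype(float), zooms, np.asarray(img.affine))
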