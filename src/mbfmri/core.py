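"""Shared containers: 4D time series, 3D statistic maps, NIfTI round-tripping."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeSeries", "StatMap", "save_series", "load_series", "save_map", "load_map"]


@dataclass
class VolumeSeries:
    """One run's 4D BOLD data with grid metadata.

    ``data`` is (x, y, z, t); ``mask`` is the brain mask on the same grid.
    """

    data: np.ndarray
    affine: np.ndarray
    tr: float
    mask: np.ndarray | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("VolumeSeries.data must be 4D (x, y, z, t)")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.mask is not None and self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must match spatial grid")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def voxel_sizes(self) -> np.ndarray:
        """Voxel edge lengths in mm from the affine."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def masked_matrix(self) -> np.ndarray:
        """(voxels, time) matrix of in-mask time courses."""
        m = self.mask if self.mask is not None else np.ones(self.shape, bool)
        return self.data[m.astype(bool)]

    def truncated(self, n_keep: int) -> "VolumeSeries":
        return VolumeSeries(
            data=self.data[..., :n_keep], affine=self.affine, tr=self.tr,
            mask=self.mask, name=self.name,
        )


@dataclass
class StatMap:
    """A 3D statistic map (t, p, variance, tSNR ...) with provenance.

    ``dof`` carries the degrees of freedom for t maps; ``threshold_info``
    records how any thresholding was done (q level, t cutoff, cluster size).
    """

    values: np.ndarray
    kind: str = "t"
    affine: np.ndarray | None = None
    dof: float | None = None
    threshold_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("StatMap.values must be 3D")


def save_series(series: VolumeSeries, path: str | Path) -> None:
    img = nib.Nifti1Image(series.data.astype(np.float32), series.affine)
    img.header.set_zooms((*series.voxel_sizes(), series.tr))
    nib.save(img, str(path))


def load_series(path: str | Path, tr: float | None = None,
                mask: np.ndarray | None = None) -> VolumeSeries:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if tr is None:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 else 1.0
    return VolumeSeries(data=data, affine=np.asarray(img.affine), tr=tr, mask=mask)


def save_map(statmap: StatMap, path: str | Path) -> None:
    affine = statmap.affine if statmap.affine is not None else np.eye(4)
    nib.save(nib.Nifti1Image(statmap.values.astype(np.float32), affine), str(path))


def load_map(path: str | Path, kind: str = "t") -> StatMap:
    img = nib.load(str(path))
    return StatMap(values=np.asarray(img.dataobj, dtype=np.float32),
                   kind=kind, affine=np.asarray(img.affine))
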