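"""Voxel-grid containers and NIfTI round-tripping.

All volumes in a single analysis share one grid: same shape and (to a small
tolerance) the same affine.  Voxel indexing is 0-based; the world position of
voxel ``(i, j, k)`` is ``affine @ (i, j, k, 1)``, so a voxel *center* sits at
``index * spacing`` for the default diagonal affine.  All distances are in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["Volume", "read_volume", "write_volume", "check_same_grid", "GridMismatchError"]

AFFINE_ATOL = 1e-4


class GridMismatchError(ValueError):
    """Two volumes that must be co-registered are not on the same grid."""


@dataclass
class Volume:
    """A 3D array with a world affine.

    Parameters
    ----------
    data:
        3D array; integer dtypes for label/mask volumes, floats for metrics.
    affine:
        4x4 voxel-to-world matrix. Defaults to identity (1 mm isotropic).
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (norm of the affine columns)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def astype(self, dtype) -> "Volume":
        return Volume(self.data.astype(dtype), self.affine.copy())

    def like(self, data: np.ndarray) -> "Volume":
        """New volume with the same grid but different data."""
        data = np.asarray(data)
        if data.shape != self.data.shape:
            raise GridMismatchError(
                f"data shape {data.shape} does not match grid {self.data.shape}"
            )
        return Volume(data, self.affine.copy())


def check_same_grid(*volumes: Volume, names: list[str] | None = None) -> None:
    """Raise :class:`GridMismatchError` unless all volumes share one grid.

    Affines may differ by up to ``1e-4`` per entry (file round-trip slack);
    shapes must agree exactly.
    """
    if len(volumes) < 2:
        return
    ref = volumes[0]
    labels = names or [f"volume[{i}]" for i in range(len(volumes))]
    for vol, name in zip(volumes[1:], labels[1:]):
        if vol.shape != ref.shape:
            raise GridMismatchError(
                f"{labels[0]} has shape {ref.shape} but {name} has shape {vol.shape}"
            )
        if not np.allclose(vol.affine, ref.affine, atol=AFFINE_ATOL, rtol=0):
            raise GridMismatchError(
                f"{labels[0]} and {name} have affines differing by more than {AFFINE_ATOL}"
            )


def read_volume(path) -> Volume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return Volume(data, np.asarray(img.affine))


def write_volume(vol: Volume, path) -> None:
    data = vol.data
    # Integer masks/labels round-trip exactly; floats are stored as float32.
    if not np.issubdtype(data.dtype, np.integer) and data.dtype != np.float32:
        data = data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, vol.affine), str(path))
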