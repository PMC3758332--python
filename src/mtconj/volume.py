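"""3D scalar volume carrier shared by every stage of the pipeline.

A :class:`Volume` is a 3D array plus the affine mapping 0-based voxel
indices to world millimetres.  Invalid voxels (e.g. excluded by an
intensity floor) are carried as NaN; helpers below build and combine the
corresponding boolean validity masks.  All stages refuse grid mismatches
rather than resampling: spatial alignment is assumed done upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Volume", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Raised when volumes that must share a voxel grid do not."""


@dataclass
class Volume:
    """A 3D scalar field with voxel-to-world geometry.

    Parameters
    ----------
    data:
        3D float array; NaN marks invalid voxels.
    affine:
        4x4 matrix mapping 0-based voxel indices to world mm.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis voxel edge length in mm (column norms of the affine)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm^3 (|det| of the linear part)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.data)

    def same_grid(self, other: "Volume", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def with_data(self, data: np.ndarray) -> "Volume":
        """New Volume on the same grid with different data."""
        return Volume(np.asarray(data), self.affine.copy())

    def voxel_centers_mm(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape grid + (3,)."""
        idx = np.indices(self.shape, dtype=float)
        ijk1 = np.stack([*idx, np.ones(self.shape)], axis=-1)
        return ijk1 @ self.affine.T[:, :3]


def check_same_grid(*volumes: Volume, names: tuple[str, ...] | None = None) -> None:
    """Raise :class:`GridMismatchError` unless all volumes share one grid."""
    ref = volumes[0]
    for i, v in enumerate(volumes[1:], start=1):
        if not ref.same_grid(v):
            a = names[0] if names else "volume 0"
            b = names[i] if names else f"volume {i}"
            raise GridMismatchError(
                f"{a} and {b} are not on the same grid "
                f"(shapes {ref.shape} vs {v.shape})"
            )
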