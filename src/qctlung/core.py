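"""Core containers shared by every pipeline stage.

All arrays follow a fixed axis convention: 0-based voxel indices in
``(slice, row, column)`` order (superior->inferior, anterior->posterior,
subject-left->right for phantoms).  Physical positions in mm are obtained as
``index * spacing + origin``.  Attenuation is stored as float Hounsfield
units regardless of the integer type of the source file.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CTVolume", "RegionMask"]


@dataclass
class CTVolume:
    """A 3-D attenuation volume in Hounsfield units.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Attenuation in HU, stored as float.
    spacing : tuple of float
        Voxel size in mm per axis, ``(slice, row, column)`` order.
    origin : tuple of float
        Physical position of voxel ``(0, 0, 0)`` in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite HU values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_mm(self, idx: np.ndarray) -> np.ndarray:
        """Convert (possibly fractional) voxel indices to mm positions."""
        return np.asarray(idx, dtype=float) * np.array(self.spacing) + np.array(self.origin)


@dataclass
class RegionMask:
    """A boolean voxel mask aligned to a :class:`CTVolume`.

    ``label`` records what the mask delineates: ``lung``, ``airway_lumen``,
    ``airway_wall``, ``analysis`` or ``other``.
    """

    mask: np.ndarray
    label: str = "other"
    volume_shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {self.mask.shape}")
        if self.volume_shape is None:
            self.volume_shape = self.mask.shape
        elif tuple(self.volume_shape) != self.mask.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match linked volume "
                f"shape {tuple(self.volume_shape)}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def check_aligned(self, volume: CTVolume) -> None:
        if self.mask.shape != volume.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} not aligned to volume shape {volume.shape}"
            )
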