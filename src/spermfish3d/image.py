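"""Multi-channel anisotropic 3D image container.

The whole package uses one axis convention: voxel grids are indexed
``(z, y, x)``, channels are a leading axis, and physical coordinates in µm
are ``index * spacing`` with ``spacing = (dz, dy, dx)``.  The default voxel
size matches typical confocal acquisition of sperm heads:
0.093 × 0.093 µm in-plane, 0.244 µm between planes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DEFAULT_SPACING", "ImageStack"]

#: default (dz, dy, dx) voxel size in µm
DEFAULT_SPACING: tuple[float, float, float] = (0.244, 0.093, 0.093)


@dataclass(frozen=True)
class ImageStack:
    """An 8-bit multi-channel 3D stack with physical voxel spacing.

    ``voxels`` has shape (C, Z, Y, X) and dtype uint8; ``spacing`` is
    (dz, dy, dx) in µm and must be strictly positive.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.voxels.ndim != 4:
            raise ValueError("voxels must have shape (C, Z, Y, X)")
        if self.voxels.dtype != np.uint8:
            raise ValueError("voxels must be uint8 (8-bit intensities)")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        if not self.channel_names:
            object.__setattr__(
                self, "channel_names", tuple(f"ch{i}" for i in range(self.voxels.shape[0]))
            )
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ValueError("channel_names length must match the channel axis")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        """(Z, Y, X) shape of each channel."""
        return tuple(self.voxels.shape[1:])

    def channel(self, name: str) -> np.ndarray:
        """The (Z, Y, X) array of one channel, by name."""
        try:
            i = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"no channel {name!r}; available: {list(self.channel_names)}"
            ) from None
        return self.voxels[i]

    def has_channel(self, name: str) -> bool:
        return name in self.channel_names
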