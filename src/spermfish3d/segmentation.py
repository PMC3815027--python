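"""Global-threshold segmentation of nuclei and FISH signals in 3D stacks.

All objects are detected as connected components of voxels above a single
global intensity threshold per channel, either set manually or chosen
automatically by maximizing the between-class intensity variance (Otsu).
This mirrors the interactive threshold-then-inspect workflow of classic
3D-FISH quantification tools, with the automatic threshold standing in for
the operator's visual adjustment.

Conventions: stacks are indexed ``(z, y, x)``; physical coordinates in µm are
``index * spacing`` with ``spacing = (dz, dy, dx)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .image import ImageStack

__all__ = [
    "SegmentationError",
    "SegmentedObject",
    "SegmentationConfig",
    "otsu_threshold",
    "auto_threshold",
    "segment_nucleus",
    "segment_signals",
]


class SegmentationError(RuntimeError):
    """Raised when a stack cannot be segmented (e.g. empty nucleus)."""


# scikit-image "connectivity" argument per 3D neighborhood size
_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholding and labeling parameters.

    ``manual_threshold`` maps channel name to an 8-bit threshold; channels
    absent from the map fall back to the automatic threshold when
    ``threshold_mode == "auto"``.  ``min_object_voxels`` suppresses
    single-voxel noise in signal channels (it is not applied to the nucleus).
    """

    threshold_mode: str = "auto"  # "auto" | "manual"
    manual_threshold: dict[str, float] = field(default_factory=dict)
    min_object_voxels: int = 5
    connectivity: int = 26  # 6 | 18 | 26
    # Otsu validity check: FISH objects occupy a small minority of the stack,
    # so an automatic threshold leaving more than this fraction of voxels
    # "foreground" indicates the histogram has no bright minority class and
    # Otsu split the background with itself (typical for channels with only a
    # handful of small spots).  Such channels fall back to a robust
    # background-statistics threshold: median + background_k * 1.4826 * MAD.
    max_foreground_fraction: float = 0.25
    background_k: float = 5.0

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("auto", "manual"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        for ch, t in self.manual_threshold.items():
            if not 0 <= t <= 255:
                raise ValueError(f"manual threshold for {ch!r} outside [0, 255]: {t}")
        if self.min_object_voxels < 1:
            raise ValueError("min_object_voxels must be >= 1")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError("connectivity must be one of 6, 18, 26")
        if not 0 < self.max_foreground_fraction <= 1:
            raise ValueError("max_foreground_fraction must be in (0, 1]")
        if self.background_k <= 0:
            raise ValueError("background_k must be positive")


@dataclass(frozen=True)
class SegmentedObject:
    """One labeled connected voxel component.

    ``voxels`` is an (N, 3) integer array of (z, y, x) indices into the grid
    of shape ``shape``; ``centroid`` and ``volume`` are in physical units
    (µm and µm³).
    """

    label: int
    channel: str
    voxels: np.ndarray
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.voxels.ndim != 2 or self.voxels.shape[1] != 3 or len(self.voxels) == 0:
            raise ValueError("voxels must be a non-empty (N, 3) index array")

    @property
    def voxel_count(self) -> int:
        return len(self.voxels)

    @property
    def volume(self) -> float:
        """Physical volume in µm³."""
        dz, dy, dx = self.spacing
        return self.voxel_count * dz * dy * dx

    @property
    def centroid(self) -> np.ndarray:
        """Physical centroid (z, y, x) in µm."""
        return self.voxels.mean(axis=0) * np.asarray(self.spacing)

    @property
    def physical_coords(self) -> np.ndarray:
        """(N, 3) physical voxel-center coordinates in µm."""
        return self.voxels * np.asarray(self.spacing)

    @property
    def flat_indices(self) -> np.ndarray:
        """Raveled voxel indices (sorted), for fast set operations."""
        return np.sort(
            np.ravel_multi_index(tuple(self.voxels.T), self.shape)
        )

    def mask(self) -> np.ndarray:
        """Boolean occupancy grid of this object."""
        m = np.zeros(self.shape, dtype=bool)
        m[tuple(self.voxels.T)] = True
        return m


def otsu_threshold(values: np.ndarray) -> float:
    """Threshold maximizing the between-class intensity variance (Otsu).

    Deterministic for identical input.  Raises ``SegmentationError`` on
    constant input, for which no threshold separates two classes.
    """
    values = np.asarray(values)
    if values.min() == values.max():
        raise SegmentationError("constant intensities; no threshold exists")
    return float(threshold_otsu(values))


def auto_threshold(
    stack: ImageStack,
    channel: str,
    max_foreground_fraction: float = 0.25,
    background_k: float = 5.0,
) -> float:
    """Automatic global threshold for one channel, with a validity check.

    Uses Otsu's between-class-variance criterion, which assumes the channel
    histogram holds two populations of comparable weight.  FISH signal
    channels with only a few small objects violate that assumption: nearly
    every voxel is background, the histogram is effectively unimodal, and the
    Otsu threshold lands inside the background mode.  Such a split is
    detected by its implausibly large foreground fraction
    (> ``max_foreground_fraction``) and replaced by a robust
    background-statistics threshold ``median + background_k * 1.4826 * MAD``,
    where 1.4826 * MAD estimates the background standard deviation without
    being skewed by the bright minority.
    """
    data = stack.channel(channel)
    if data.min() == data.max():
        raise SegmentationError(f"channel {channel!r} is constant; no threshold exists")
    thr = otsu_threshold(data)
    if float(np.mean(data > thr)) <= max_foreground_fraction:
        return thr
    med = float(np.median(data))
    mad = float(np.median(np.abs(data.astype(np.float64) - med)))
    sigma = 1.4826 * mad if mad > 0 else float(data.std())
    return med + background_k * sigma


def _channel_threshold(stack: ImageStack, channel: str, cfg: SegmentationConfig) -> float:
    if cfg.threshold_mode == "manual":
        try:
            return float(cfg.manual_threshold[channel])
        except KeyError:
            raise SegmentationError(
                f"manual threshold mode but no threshold given for channel {channel!r}"
            ) from None
    if channel in cfg.manual_threshold:
        return float(cfg.manual_threshold[channel])
    return auto_threshold(stack, channel, cfg.max_foreground_fraction, cfg.background_k)


def _labeled_components(mask: np.ndarray, connectivity: int) -> np.ndarray:
    return cc_label(mask, connectivity=_CONNECTIVITY_RANK[connectivity])


def _objects_from_labels(
    labels: np.ndarray,
    channel: str,
    spacing: tuple[float, float, float],
    min_voxels: int,
) -> list[SegmentedObject]:
    """Extract objects sorted by descending voxel count (ties: first raster voxel)."""
    shape = labels.shape
    objs: list[tuple[int, int, np.ndarray]] = []
    for lab in range(1, labels.max() + 1):
        idx = np.argwhere(labels == lab)
        if len(idx) < min_voxels:
            continue
        first = int(np.ravel_multi_index(tuple(idx[0]), shape))
        objs.append((len(idx), first, idx))
    objs.sort(key=lambda t: (-t[0], t[1]))
    return [
        SegmentedObject(label=i + 1, channel=channel, voxels=idx, shape=shape, spacing=spacing)
        for i, (_, _, idx) in enumerate(objs)
    ]


def _fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill internal holes slice-wise in z, then in full 3D."""
    filled = np.empty_like(mask)
    for z in range(mask.shape[0]):
        filled[z] = ndimage.binary_fill_holes(mask[z])
    return ndimage.binary_fill_holes(filled)


def segment_nucleus(
    stack: ImageStack,
    cfg: SegmentationConfig | None = None,
    channel: str = "dna",
) -> SegmentedObject:
    """Segment the nucleus from the DNA counterstain channel.

    Returns the largest connected above-threshold component with internal
    holes filled.  Raises ``SegmentationError`` when no voxel exceeds the
    threshold ("empty nucleus").
    """
    cfg = cfg or SegmentationConfig()
    data = stack.channel(channel)
    if data.min() == data.max():
        raise SegmentationError("empty nucleus: counterstain channel is constant")
    thr = _channel_threshold(stack, channel, cfg)
    mask = data > thr
    if not mask.any():
        raise SegmentationError("empty nucleus: no voxel above threshold")
    labels = _labeled_components(mask, cfg.connectivity)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    largest = int(counts.argmax())
    nucleus_mask = _fill_holes(labels == largest)
    return SegmentedObject(
        label=1,
        channel=channel,
        voxels=np.argwhere(nucleus_mask),
        shape=stack.grid_shape,
        spacing=stack.spacing,
    )


def segment_signals(
    stack: ImageStack,
    channel: str,
    nucleus: SegmentedObject,
    cfg: SegmentationConfig | None = None,
) -> list[SegmentedObject]:
    """Segment FISH signal objects within the nucleus mask.

    Connected components of above-threshold voxels restricted to the nucleus,
    filtered by ``min_object_voxels`` and returned sorted by descending
    volume with deterministic labels 1..n.  An empty list is a valid result.
    """
    cfg = cfg or SegmentationConfig()
    data = stack.channel(channel)
    if data.min() == data.max():
        return []
    thr = _channel_threshold(stack, channel, cfg)
    mask = (data > thr) & nucleus.mask()
    if not mask.any():
        return []
    labels = _labeled_components(mask, cfg.connectivity)
    return _objects_from_labels(labels, channel, stack.spacing, cfg.min_object_voxels)
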