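"""Per-nucleus spatial statistics for 3D-FISH objects.

Implements the quantities used to describe sperm nuclear architecture:

* spot/chromocenter cluster counts per channel;
* object-based pair classification (colocalized / adjacent / distant):
  colocalized when two objects share at least two voxels, adjacent when the
  edge gap is under one in-plane pixel, distant otherwise;
* cross-channel chromocenter association counting (greedy one-to-one);
* the antero-posterior (AP) axis frame of the paddle-shaped nucleus and
  normalized AP% (0 posterior pole, 100 anterior pole) and medio-lateral ML%
  (0 on the axis, 100 at the nuclear border) positions;
* chromosome-territory morphology classing (round vs elongated) from
  principal second moments;
* centroid-to-border distances in µm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .image import ImageStack
from .segmentation import SegmentationConfig, SegmentedObject, segment_nucleus, segment_signals

__all__ = [
    "PairCategory",
    "AxisFrame",
    "NormalizedPosition",
    "NucleusRecord",
    "MeasureConfig",
    "AxisUndefinedError",
    "count_clusters",
    "classify_pair",
    "classify_masks",
    "count_associations",
    "fit_axis_frame",
    "ap_position",
    "ml_position",
    "classify_morphology",
    "border_distance",
    "measure_nucleus",
]

#: default in-plane pixel size (µm) used by the adjacency rule
DEFAULT_IN_PLANE_PIXEL = 0.093

COLOCALIZED = "colocalized"
ADJACENT = "adjacent"
DISTANT = "distant"
PAIR_CATEGORIES = (COLOCALIZED, ADJACENT, DISTANT)

ROUND = "round"
ELONGATED = "elongated"


class AxisUndefinedError(RuntimeError):
    """Raised when a nucleus mask has no dominant principal axis."""


@dataclass(frozen=True)
class NormalizedPosition:
    """Normalized intra-nuclear position in percent.

    ``ap_percent``: 0 at the posterior pole, 100 at the anterior pole.
    ``ml_percent``: unsigned radial coordinate, 0 on the AP axis and 100 at
    the nuclear border (the medio-lateral axis is not lateralized).
    """

    ap_percent: float
    ml_percent: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ap_percent <= 100.0 and 0.0 <= self.ml_percent <= 100.0):
            raise ValueError("normalized positions must lie in [0, 100]")


@dataclass(frozen=True)
class AxisFrame:
    """Antero-posterior axis frame of one nucleus.

    ``origin`` is the point of the axis line at the posterior extreme of the
    mask, ``ap_direction`` the unit vector pointing anterior, ``ap_length``
    the posterior-to-anterior extent in µm.
    """

    origin: np.ndarray
    ap_direction: np.ndarray
    ap_length: float

    def __post_init__(self) -> None:
        if not np.isclose(np.linalg.norm(self.ap_direction), 1.0, atol=1e-6):
            raise ValueError("ap_direction must be a unit vector")
        if self.ap_length <= 0:
            raise ValueError("ap_length must be positive")


def count_clusters(objects: Sequence[SegmentedObject]) -> int:
    """Number of signal clusters: each connected component is one cluster."""
    return len(objects)


def _min_center_distance(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimum voxel-center distance (µm) between two physical point sets."""
    if len(coords_a) > len(coords_b):
        coords_a, coords_b = coords_b, coords_a
    tree = cKDTree(coords_b)
    d, _ = tree.query(coords_a, k=1)
    return float(np.min(d))


def _edge_gap(coords_a: np.ndarray, coords_b: np.ndarray, in_plane_pixel: float) -> float:
    """Physical edge-to-edge gap: min center distance minus one voxel, floored at 0."""
    return max(0.0, _min_center_distance(coords_a, coords_b) - in_plane_pixel)


def classify_masks(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    spacing: Sequence[float],
    in_plane_pixel: float = DEFAULT_IN_PLANE_PIXEL,
    min_overlap_voxels: int = 2,
) -> str:
    """Classify two boolean occupancy grids on the same voxel grid.

    Colocalized when they share at least ``min_overlap_voxels`` voxels,
    adjacent when the edge gap is below one in-plane pixel, distant
    otherwise.  Used both by the analysis path (via ``classify_pair``) and by
    the synthetic generator to guarantee a placed category by construction.
    """
    if not mask_a.any() or not mask_b.any():
        raise ValueError("cannot classify an empty object")
    overlap = int(np.count_nonzero(mask_a & mask_b))
    if overlap >= min_overlap_voxels:
        return COLOCALIZED
    sp = np.asarray(spacing, dtype=float)
    coords_a = np.argwhere(mask_a) * sp
    coords_b = np.argwhere(mask_b) * sp
    if _edge_gap(coords_a, coords_b, in_plane_pixel) < in_plane_pixel:
        return ADJACENT
    return DISTANT


def classify_pair(
    a: SegmentedObject,
    b: SegmentedObject,
    in_plane_pixel: float = DEFAULT_IN_PLANE_PIXEL,
    min_overlap_voxels: int = 2,
) -> str:
    """Classify two segmented objects of one nucleus as colocalized, adjacent or distant.

    Symmetric in its arguments.  Overlap is counted in shared voxels on the
    common grid; the adjacency gap is the minimum voxel-center distance minus
    one in-plane pixel (floored at zero for touching voxels), compared
    against one in-plane pixel.
    """
    if a.shape != b.shape:
        raise ValueError("objects must come from the same stack grid")
    overlap = len(np.intersect1d(a.flat_indices, b.flat_indices, assume_unique=True))
    if overlap >= min_overlap_voxels:
        return COLOCALIZED
    gap = _edge_gap(a.physical_coords, b.physical_coords, in_plane_pixel)
    return ADJACENT if gap < in_plane_pixel else DISTANT


def count_associations(
    set_a: Sequence[SegmentedObject],
    set_b: Sequence[SegmentedObject],
    in_plane_pixel: float = DEFAULT_IN_PLANE_PIXEL,
) -> int:
    """Number of cross-channel chromocenter associations.

    A pair counts as associated when it classifies colocalized or adjacent.
    Each object participates in at most one association; candidate pairs are
    consumed greedily by smallest edge gap, ties broken by smaller labels.
    """
    candidates: list[tuple[float, int, int]] = []
    for i, a in enumerate(set_a):
        for j, b in enumerate(set_b):
            cat = classify_pair(a, b, in_plane_pixel=in_plane_pixel)
            if cat == DISTANT:
                continue
            gap = 0.0 if cat == COLOCALIZED else _edge_gap(
                a.physical_coords, b.physical_coords, in_plane_pixel
            )
            candidates.append((gap, a.label, b.label, i, j))
    candidates.sort(key=lambda t: t[:3])
    used_a: set[int] = set()
    used_b: set[int] = set()
    n = 0
    for _, _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        n += 1
    return n


def fit_axis_frame(
    nucleus: SegmentedObject,
    anterior_hint: Sequence[float] | None = None,
    dominance_tol: float = 1.2,
) -> AxisFrame:
    """Fit the antero-posterior axis frame from the nucleus voxel cloud.

    The AP direction is the dominant principal axis of the physical voxel
    coordinates.  ``anterior_hint``, when given, is a (z, y, x) vector whose
    sign fixes which end is anterior (for synthetic data it comes from the
    ground-truth manifest).  Without a hint, the end with the smaller
    cross-sectional area near the pole is taken as anterior -- a
    low-confidence heuristic based on the tapering of the paddle shape.

    Raises ``AxisUndefinedError`` when the two largest principal extents
    differ by less than ``dominance_tol`` (e.g. a spherical mask).
    """
    coords = nucleus.physical_coords
    center = coords.mean(axis=0)
    cov = np.cov((coords - center).T)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    if eigvals[1] <= 0 or np.sqrt(eigvals[0] / eigvals[1]) < dominance_tol:
        raise AxisUndefinedError(
            "axis undefined: nucleus mask has no dominant principal axis"
        )
    axis = eigvecs[:, 0]
    if anterior_hint is not None:
        hint = np.asarray(anterior_hint, dtype=float)
        if float(hint @ axis) < 0:
            axis = -axis
    else:
        axis = _orient_by_taper(coords, center, axis)
    proj = (coords - center) @ axis
    t_min, t_max = float(proj.min()), float(proj.max())
    origin = center + t_min * axis
    return AxisFrame(origin=origin, ap_direction=axis, ap_length=t_max - t_min)


def _orient_by_taper(coords: np.ndarray, center: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Point ``axis`` toward the more tapered (smaller cross-section) end."""
    proj = (coords - center) @ axis
    t_min, t_max = proj.min(), proj.max()
    length = t_max - t_min
    lo_slab = proj <= t_min + 0.1 * length
    hi_slab = proj >= t_max - 0.1 * length
    radial = coords - center - np.outer(proj, axis)
    r = np.linalg.norm(radial, axis=1)
    # anterior = the narrower pole
    if r[hi_slab].mean() <= r[lo_slab].mean():
        return axis
    return -axis


def ap_position(ct_centroid: Sequence[float], frame: AxisFrame) -> float:
    """Normalized antero-posterior position (0 posterior .. 100 anterior)."""
    c = np.asarray(ct_centroid, dtype=float)
    t = float((c - frame.origin) @ frame.ap_direction)
    return float(np.clip(100.0 * t / frame.ap_length, 0.0, 100.0))


def _point_in_mask(p: np.ndarray, mask: np.ndarray, spacing: np.ndarray) -> bool:
    idx = np.rint(p / spacing).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(mask.shape)):
        return False
    return bool(mask[tuple(idx)])


def ml_position(
    ct_centroid: Sequence[float],
    frame: AxisFrame,
    nucleus_mask: np.ndarray,
    spacing: Sequence[float],
) -> float:
    """Normalized medio-lateral position (0 on the AP axis .. 100 at the border).

    Projects the centroid onto the AP axis line, casts the ray from that axis
    point through the centroid, marches it to the border of the voxel mask,
    and returns 100 × (centroid offset) / (border offset).
    """
    sp = np.asarray(spacing, dtype=float)
    c = np.asarray(ct_centroid, dtype=float)
    if not _point_in_mask(c, nucleus_mask, sp):
        raise ValueError("centroid lies outside the nucleus mask")
    t = float((c - frame.origin) @ frame.ap_direction)
    a = frame.origin + t * frame.ap_direction
    v = c - a
    r_c = float(np.linalg.norm(v))
    if r_c < 1e-9:
        return 0.0
    direction = v / r_c
    step = 0.25 * float(sp[1:].min())
    # march outward from the centroid until the ray leaves the mask
    r = r_c
    r_last_inside = r_c
    max_r = float(np.asarray(nucleus_mask.shape) @ sp)  # safe upper bound
    while r < max_r:
        r += step
        if _point_in_mask(a + r * direction, nucleus_mask, sp):
            r_last_inside = r
        else:
            break
    # bisection refinement between last inside and first outside
    lo, hi = r_last_inside, r
    for _ in range(6):
        mid = 0.5 * (lo + hi)
        if _point_in_mask(a + mid * direction, nucleus_mask, sp):
            lo = mid
        else:
            hi = mid
    r_border = 0.5 * (lo + hi)
    return float(np.clip(100.0 * r_c / r_border, 0.0, 100.0))


def classify_morphology(
    ct: SegmentedObject,
    ratio_threshold: float = 1.5,
) -> str:
    """Classify a chromosome territory as round or elongated.

    The principal axis lengths are the square roots of the eigenvalues of
    the covariance of the physical voxel coordinates; a territory is
    elongated iff largest/second-largest strictly exceeds ``ratio_threshold``
    (a ratio exactly at the threshold is round).
    """
    coords = ct.physical_coords
    cov = np.cov((coords - coords.mean(axis=0)).T)
    eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    if eigvals[1] <= 1e-12:
        return ELONGATED  # degenerate line-like object
    ratio = float(np.sqrt(eigvals[0] / eigvals[1]))
    return ELONGATED if ratio > ratio_threshold else ROUND


def border_distance(
    ct_centroid: Sequence[float],
    nucleus_mask: np.ndarray,
    spacing: Sequence[float],
) -> float:
    """Minimum physical distance (µm) from a centroid to the nucleus border.

    Border voxels are nucleus voxels adjacent (6-connectivity) to background.
    """
    sp = np.asarray(spacing, dtype=float)
    c = np.asarray(ct_centroid, dtype=float)
    if not _point_in_mask(c, nucleus_mask, sp):
        raise ValueError("centroid lies outside the nucleus mask")
    eroded = ndimage.binary_erosion(nucleus_mask)  # 6-connected structuring element
    border = nucleus_mask & ~eroded
    coords = np.argwhere(border) * sp
    tree = cKDTree(coords)
    d, _ = tree.query(c, k=1)
    return float(d)


# ---------------------------------------------------------------------------
# Per-nucleus composition


@dataclass(frozen=True)
class MeasureConfig:
    """Channel roles and metric parameters for measuring one nucleus.

    ``spot_channels`` are counted as clusters; ``association_channels``, when
    both present, are additionally scored for cross-channel chromocenter
    associations; ``paint_pair`` names the two chromosome-paint channels to
    classify as a territory pair (one territory = largest object per channel).
    ``central_ml_cutoff`` operationalizes "central part of the nucleus" as
    ML% below the cutoff.
    """

    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    counterstain: str = "dna"
    spot_channels: tuple[str, ...] = ("telomeres",)
    association_channels: tuple[str, str] | None = None
    paint_pair: tuple[str, str] | None = ("ssc13", "ssc17")
    in_plane_pixel: float = DEFAULT_IN_PLANE_PIXEL
    morphology_ratio_threshold: float = 1.5
    central_ml_cutoff: float = 50.0


@dataclass
class NucleusRecord:
    """One measurement row per nucleus; absent measures are None."""

    nucleus_id: str
    cluster_counts: dict[str, int] = field(default_factory=dict)
    association_count: int | None = None
    pair_category: str | None = None
    ct_positions: dict[str, NormalizedPosition] = field(default_factory=dict)
    ct_morphologies: dict[str, str] = field(default_factory=dict)
    ct_border_um: dict[str, float] = field(default_factory=dict)
    carrier: bool | None = None

    def to_row(self, central_ml_cutoff: float = 50.0) -> dict:
        """Flatten to a CSV/DataFrame-friendly dict with unit-suffixed columns."""
        row: dict = {"nucleus_id": self.nucleus_id}
        for ch, n in sorted(self.cluster_counts.items()):
            row[f"{ch}_clusters"] = n
        if self.association_count is not None:
            row["associations"] = self.association_count
        if self.pair_category is not None:
            row["pair_category"] = self.pair_category
        for ch, pos in sorted(self.ct_positions.items()):
            row[f"{ch}_ap_pct"] = pos.ap_percent
            row[f"{ch}_ml_pct"] = pos.ml_percent
            row[f"{ch}_central"] = pos.ml_percent < central_ml_cutoff
        for ch, m in sorted(self.ct_morphologies.items()):
            row[f"{ch}_morphology"] = m
        for ch, d in sorted(self.ct_border_um.items()):
            row[f"{ch}_border_um"] = d
        if self.carrier is not None:
            row["carrier"] = self.carrier
        return row


def measure_nucleus(
    stack: ImageStack,
    cfg: MeasureConfig | None = None,
    nucleus_id: str = "nucleus",
    anterior_hint: Sequence[float] | None = None,
    carrier: bool | None = None,
) -> NucleusRecord:
    """Segment one stack and compute its full NucleusRecord.

    Deterministic for a fixed stack and config.  Channels named in the
    config but absent from the stack are skipped, so a stack without paint
    channels still yields its cluster counts.
    """
    cfg = cfg or MeasureConfig()
    try:
        nucleus = segment_nucleus(stack, cfg.segmentation, channel=cfg.counterstain)
    except Exception as exc:
        raise RuntimeError(f"[{nucleus_id}] nucleus segmentation failed: {exc}") from exc
    record = NucleusRecord(nucleus_id=nucleus_id, carrier=carrier)

    for ch in cfg.spot_channels:
        if stack.has_channel(ch):
            objs = segment_signals(stack, ch, nucleus, cfg.segmentation)
            record.cluster_counts[ch] = count_clusters(objs)

    if cfg.association_channels is not None:
        ch_a, ch_b = cfg.association_channels
        if stack.has_channel(ch_a) and stack.has_channel(ch_b):
            objs_a = segment_signals(stack, ch_a, nucleus, cfg.segmentation)
            objs_b = segment_signals(stack, ch_b, nucleus, cfg.segmentation)
            record.association_count = count_associations(
                objs_a, objs_b, in_plane_pixel=cfg.in_plane_pixel
            )

    paint_channels = [
        ch for ch in (cfg.paint_pair or ()) if stack.has_channel(ch)
    ]
    if paint_channels:
        try:
            frame = fit_axis_frame(nucleus, anterior_hint=anterior_hint)
        except AxisUndefinedError as exc:
            raise RuntimeError(f"[{nucleus_id}] {exc}") from exc
        nucleus_mask = nucleus.mask()
        cts: dict[str, SegmentedObject] = {}
        for ch in paint_channels:
            objs = segment_signals(stack, ch, nucleus, cfg.segmentation)
            if not objs:
                warnings.warn(f"[{nucleus_id}] no territory found in channel {ch!r}")
                continue
            cts[ch] = objs[0]  # the territory is the largest object
        for ch, ct in cts.items():
            centroid = ct.centroid
            record.ct_positions[ch] = NormalizedPosition(
                ap_percent=ap_position(centroid, frame),
                ml_percent=ml_position(centroid, frame, nucleus_mask, stack.spacing),
            )
            record.ct_morphologies[ch] = classify_morphology(
                ct, ratio_threshold=cfg.morphology_ratio_threshold
            )
            record.ct_border_um[ch] = border_distance(centroid, nucleus_mask, stack.spacing)
        if cfg.paint_pair and all(ch in cts for ch in cfg.paint_pair):
            record.pair_category = classify_pair(
                cts[cfg.paint_pair[0]], cts[cfg.paint_pair[1]],
                in_plane_pixel=cfg.in_plane_pixel,
            )
    return record
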