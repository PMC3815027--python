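"""Thresholding and connected-component segmentation against brute-force oracles."""

from collections import deque

import numpy as np
import pytest

from spermfish3d.image import ImageStack
from spermfish3d.segmentation import (
    SegmentationConfig,
    SegmentationError,
    auto_threshold,
    otsu_threshold,
    segment_nucleus,
    segment_signals,
)

# ---------------------------------------------------------------------------
# Oracles


def _neighborhood(connectivity):
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dz, dy, dx))
    return offs


def flood_fill_components(mask, connectivity=26):
    """Brute-force BFS flood fill; returns sorted component sizes."""
    offs = _neighborhood(connectivity)
    seen = np.zeros_like(mask, dtype=bool)
    sizes = []
    zmax, ymax, xmax = mask.shape
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        queue = deque([start])
        seen[start] = True
        size = 0
        while queue:
            z, y, x = queue.popleft()
            size += 1
            for dz, dy, dx in offs:
                p = (z + dz, y + dy, x + dx)
                if (0 <= p[0] < zmax and 0 <= p[1] < ymax and 0 <= p[2] < xmax
                        and mask[p] and not seen[p]):
                    seen[p] = True
                    queue.append(p)
        sizes.append(size)
    return sorted(sizes)


def between_class_variance(data, thr):
    """Between-class variance of the split data <= thr vs data > thr."""
    lo = data[data <= thr].astype(float)
    hi = data[data > thr].astype(float)
    if len(lo) == 0 or len(hi) == 0:
        return 0.0
    w0 = len(lo) / data.size
    w1 = 1.0 - w0
    return w0 * w1 * (lo.mean() - hi.mean()) ** 2


def exhaustive_otsu_max(data):
    """Maximum between-class variance over every possible integer threshold."""
    return max(between_class_variance(data, t) for t in np.unique(data)[:-1])


def _signal_stack(mask, channel="sig", high=200):
    data = np.where(mask, high, 0).astype(np.uint8)
    return ImageStack(voxels=data[None], channel_names=(channel,))


def _full_grid_nucleus(shape, spacing=(0.244, 0.093, 0.093)):
    from conftest import make_object

    idx = np.argwhere(np.ones(shape, dtype=bool))
    return make_object(idx, shape=shape, spacing=spacing)


# ---------------------------------------------------------------------------
# Connected components vs flood fill


@pytest.mark.parametrize("connectivity", [6, 18, 26])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_components_match_flood_fill(connectivity, seed):
    rng = np.random.default_rng(seed)
    shape = (12, 20, 20)
    mask = rng.random(shape) < 0.18
    stack = _signal_stack(mask)
    nucleus = _full_grid_nucleus(shape)
    cfg = SegmentationConfig(
        threshold_mode="manual", manual_threshold={"sig": 100},
        min_object_voxels=1, connectivity=connectivity,
    )
    objs = segment_signals(stack, "sig", nucleus, cfg)
    oracle = flood_fill_components(mask, connectivity)
    assert len(objs) == len(oracle)
    assert sorted(o.voxel_count for o in objs) == oracle


def test_components_match_flood_fill_dense_64():
    rng = np.random.default_rng(7)
    shape = (16, 64, 64)
    mask = rng.random(shape) < 0.35
    stack = _signal_stack(mask)
    cfg = SegmentationConfig(threshold_mode="manual", manual_threshold={"sig": 100},
                             min_object_voxels=1)
    objs = segment_signals(stack, "sig", _full_grid_nucleus(shape), cfg)
    assert sorted(o.voxel_count for o in objs) == flood_fill_components(mask, 26)


def test_diagonal_voxels_connectivity():
    shape = (4, 4, 4)
    mask = np.zeros(shape, dtype=bool)
    mask[1, 1, 1] = mask[2, 2, 2] = True  # touch only diagonally
    stack = _signal_stack(mask)
    nucleus = _full_grid_nucleus(shape)
    base = dict(threshold_mode="manual", manual_threshold={"sig": 100},
                min_object_voxels=1)
    assert len(segment_signals(stack, "sig", nucleus,
                               SegmentationConfig(connectivity=26, **base))) == 1
    assert len(segment_signals(stack, "sig", nucleus,
                               SegmentationConfig(connectivity=6, **base))) == 2


# ---------------------------------------------------------------------------
# Thresholding


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_otsu_matches_exhaustive_maximization(seed):
    rng = np.random.default_rng(seed)
    data = np.concatenate([
        rng.normal(40, 8, 4000), rng.normal(170, 12, 2500)
    ])
    data = np.clip(np.rint(data), 0, 255).astype(np.uint8)
    thr = otsu_threshold(data)
    # variance equality handles argmax ties between equivalent thresholds
    assert between_class_variance(data, thr) == pytest.approx(
        exhaustive_otsu_max(data), rel=1e-12
    )


def test_otsu_constant_raises():
    with pytest.raises(SegmentationError):
        otsu_threshold(np.full(100, 7, dtype=np.uint8))
    stack = ImageStack(voxels=np.full((1, 4, 4, 4), 7, np.uint8),
                       channel_names=("c",))
    with pytest.raises(SegmentationError):
        auto_threshold(stack, "c")


def test_auto_threshold_valid_bimodal_is_otsu():
    rng = np.random.default_rng(0)
    data = np.where(rng.random((8, 16, 16)) < 0.1, 200, 20).astype(np.uint8)
    stack = ImageStack(voxels=data[None], channel_names=("c",))
    assert auto_threshold(stack, "c") == otsu_threshold(data)


def test_auto_threshold_sparse_foreground_fallback():
    # Sparse-spot channel: Poisson-like background everywhere, a single tiny
    # bright blob.  Plain Otsu splits the background with itself; the
    # validated threshold must land between background and blob.
    rng = np.random.default_rng(1)
    data = np.clip(rng.poisson(10.0, (16, 64, 64))
                   + rng.normal(0, 3, (16, 64, 64)), 0, 255)
    data = np.rint(data).astype(np.uint8)
    data[8, 30:33, 30:33] = 180
    stack = ImageStack(voxels=data[None], channel_names=("c",))
    thr = auto_threshold(stack, "c")
    background_max_typical = 10 + 6 * np.sqrt(10 + 9)  # mean + 6 sigma
    assert thr > 20  # above the background mode
    assert thr < 180  # below the blob
    assert thr < background_max_typical * 2
    mask = data > thr
    assert mask[8, 31, 31]
    assert mask.mean() < 0.01


# ---------------------------------------------------------------------------
# Nucleus and signal extraction


def _two_blob_stack(shape=(8, 24, 24)):
    data = np.zeros(shape, dtype=np.uint8)
    data[2:6, 2:12, 2:12] = 150   # large blob with a hole
    data[4, 6, 6] = 0
    data[2:4, 16:20, 16:20] = 150  # smaller blob
    return ImageStack(voxels=data[None], channel_names=("dna",))


def test_segment_nucleus_takes_largest_and_fills_holes():
    stack = _two_blob_stack()
    nuc = segment_nucleus(stack, SegmentationConfig(
        threshold_mode="manual", manual_threshold={"dna": 100}))
    mask = nuc.mask()
    assert mask[4, 6, 6]          # hole filled
    assert not mask[3, 17, 17]    # smaller blob excluded
    assert nuc.voxel_count == 4 * 10 * 10


def test_segment_nucleus_empty_raises():
    stack = ImageStack(voxels=np.zeros((1, 4, 4, 4), np.uint8),
                       channel_names=("dna",))
    with pytest.raises(SegmentationError, match="empty nucleus"):
        segment_nucleus(stack)


def test_min_object_voxels_boundary():
    shape = (6, 12, 12)
    mask = np.zeros(shape, dtype=bool)
    mask[1, 1, 1:6] = True        # 5 voxels: kept at min 5
    mask[4, 8, 1:5] = True        # 4 voxels: dropped at min 5
    stack = _signal_stack(mask)
    nucleus = _full_grid_nucleus(shape)
    cfg = SegmentationConfig(threshold_mode="manual",
                             manual_threshold={"sig": 100}, min_object_voxels=5)
    objs = segment_signals(stack, "sig", nucleus, cfg)
    assert [o.voxel_count for o in objs] == [5]


def test_signals_restricted_to_nucleus():
    shape = (6, 12, 12)
    mask = np.zeros(shape, dtype=bool)
    mask[2, 2, 2:7] = True       # inside the nucleus half
    mask[2, 10, 2:7] = True      # outside
    stack = _signal_stack(mask)
    from conftest import make_object

    half = np.argwhere(np.indices(shape)[1] < 8)
    nucleus = make_object(half, shape=shape, spacing=(0.244, 0.093, 0.093))
    cfg = SegmentationConfig(threshold_mode="manual",
                             manual_threshold={"sig": 100}, min_object_voxels=1)
    objs = segment_signals(stack, "sig", nucleus, cfg)
    assert len(objs) == 1
    assert objs[0].voxels[:, 1].max() < 8


def test_manual_mode_requires_threshold():
    stack = _two_blob_stack()
    cfg = SegmentationConfig(threshold_mode="manual", manual_threshold={})
    with pytest.raises(SegmentationError, match="manual threshold"):
        segment_nucleus(stack, cfg)


def test_config_validation():
    with pytest.raises(ValueError):
        SegmentationConfig(threshold_mode="magic")
    with pytest.raises(ValueError):
        SegmentationConfig(connectivity=4)
    with pytest.raises(ValueError):
        SegmentationConfig(min_object_voxels=0)
    with pytest.raises(ValueError):
        SegmentationConfig(manual_threshold={"c": 300})


def test_deterministic_labels_sorted_by_volume():
    shape = (6, 16, 16)
    mask = np.zeros(shape, dtype=bool)
    mask[1, 1:3, 1:3] = True       # 4 voxels
    mask[3, 8:12, 8:12] = True     # 16 voxels
    stack = _signal_stack(mask)
    cfg = SegmentationConfig(threshold_mode="manual",
                             manual_threshold={"sig": 100}, min_object_voxels=1)
    objs = segment_signals(stack, "sig", _full_grid_nucleus(shape), cfg)
    assert [o.label for o in objs] == [1, 2]
    assert objs[0].voxel_count > objs[1].voxel_count
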