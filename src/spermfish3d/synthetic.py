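"""Synthetic confocal-like 3D stacks of sperm nuclei with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: a paddle-shaped boar sperm nucleus rendered as a flattened ellipsoid
(12 µm antero-posterior axis, ~3 µm depth) in a DNA counterstain channel;
point-like telomere/centromere FISH signals grouped into clusters of known
sizes; diffuse chromosome-territory (CT) blobs with round or elongated
shapes; and a configurable fraction of nuclei carrying the 13;17 centromeric
fusion, whose SSC13/SSC17 territories are merged.

Every random decision is recorded in a per-nucleus ground-truth record so
that recovery of cluster counts, normalized positions and pair categories
can be scored exactly.  Pair categories are guaranteed *by construction*:
after placing a territory pair the generator voxelizes the two nominal
ellipsoids on the acquisition grid and records the category the
classification rule assigns to them, retrying placement until the drawn
category is realized.

Noise model: Poisson shot noise on the rendered signal, plus a constant
background level and Gaussian read noise, clipped to the 8-bit range.
Territory and nucleus blobs have hard (voxel-sharp) edges so that any global
threshold between background and signal recovers the nominal voxel mask;
point signals have Gaussian (PSF-like) profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .image import DEFAULT_SPACING, ImageStack
from .karyotype import build_haploid_karyotype, labeled_centromere_count
from .metrics import ADJACENT, COLOCALIZED, DISTANT, classify_masks

__all__ = [
    "NucleusSpec",
    "SpotClusterSpec",
    "CTSpec",
    "NucleusGroundTruth",
    "PopulationParams",
    "render_nucleus",
    "render_spots",
    "render_ct",
    "sample_ground_truth",
    "render_ground_truth",
    "generate_population",
    "iter_population",
]


# ---------------------------------------------------------------------------
# Geometry


@dataclass(frozen=True)
class NucleusSpec:
    """Flattened-ellipsoid model of the sperm head.

    ``semi_axes`` are (antero-posterior, lateral, depth) in µm and must be
    ordered ap >= lateral >= depth > 0; defaults give the 12 µm long axis and
    3 µm depth of the boar sperm head.  ``axis`` is the unit AP direction in
    (z, y, x) physical coordinates; when ``anterior_along_axis`` is true the
    anterior pole lies toward +axis.
    """

    semi_axes: tuple[float, float, float] = (6.0, 3.5, 1.5)
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    anterior_along_axis: bool = True
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        a, b, c = self.semi_axes
        if not (a >= b >= c > 0):
            raise ValueError("semi_axes must satisfy ap >= lateral >= depth > 0")
        n = float(np.linalg.norm(self.axis))
        if not math.isclose(n, 1.0, abs_tol=1e-6):
            raise ValueError("axis must be a unit vector")

    @property
    def basis(self) -> np.ndarray:
        """Rows (u_ap, u_lat, u_depth): orthonormal frame in (z, y, x) coords."""
        u_ap = np.asarray(self.axis, dtype=float)
        z = np.array([1.0, 0.0, 0.0])
        u_depth = z - (z @ u_ap) * u_ap
        nd = np.linalg.norm(u_depth)
        if nd < 1e-9:  # AP axis along z: pick depth along y
            u_depth = np.array([0.0, 1.0, 0.0])
        else:
            u_depth = u_depth / nd
        u_lat = np.cross(u_depth, u_ap)
        return np.stack([u_ap, u_lat, u_depth])

    @property
    def anterior_direction(self) -> np.ndarray:
        u = np.asarray(self.axis, dtype=float)
        return u if self.anterior_along_axis else -u

    def quad_form(self, points: np.ndarray) -> np.ndarray:
        """Ellipsoid quadratic form; <= 1 inside."""
        rel = np.atleast_2d(points) - np.asarray(self.center)
        local = rel @ self.basis.T
        return np.sum((local / np.asarray(self.semi_axes)) ** 2, axis=1)

    def contains(self, point: Sequence[float], shrink: float = 1.0) -> bool:
        rel = np.asarray(point, dtype=float) - np.asarray(self.center)
        local = self.basis @ rel
        q = np.sum((local / (np.asarray(self.semi_axes) * shrink)) ** 2)
        return bool(q <= 1.0)

    def border_radius(self, t: float, azimuth: float) -> float:
        """Distance from the axis line to the border at AP fraction ``t`` in [-1, 1]
        along the cross-sectional direction at ``azimuth`` (0 = in-plane lateral,
        pi/2 = depth)."""
        _, b, c = self.semi_axes
        s = math.sqrt(max(0.0, 1.0 - t * t))
        denom = math.hypot(math.cos(azimuth) / b, math.sin(azimuth) / c)
        return s / denom if denom > 0 else 0.0

    def normalized_to_physical(
        self, ap_percent: float, ml_percent: float, azimuth: float
    ) -> np.ndarray:
        """Map (AP%, ML%, azimuth) to a physical (z, y, x) point in µm.

        AP% runs 0 (posterior) to 100 (anterior); ML% is the unsigned radial
        fraction of the local border distance along the azimuth direction.
        """
        u_ap, u_lat, u_depth = self.basis
        sgn = 1.0 if self.anterior_along_axis else -1.0
        t = sgn * (ap_percent / 50.0 - 1.0)
        r = (ml_percent / 100.0) * self.border_radius(t, azimuth)
        d = math.cos(azimuth) * u_lat + math.sin(azimuth) * u_depth
        a = self.semi_axes[0]
        return np.asarray(self.center) + t * a * u_ap + r * d

    def physical_to_normalized(self, point: Sequence[float]) -> tuple[float, float, float]:
        """Inverse of ``normalized_to_physical``: (AP%, ML%, azimuth)."""
        u_ap, u_lat, u_depth = self.basis
        rel = np.asarray(point, dtype=float) - np.asarray(self.center)
        a = self.semi_axes[0]
        t = float(rel @ u_ap) / a
        sgn = 1.0 if self.anterior_along_axis else -1.0
        ap = 50.0 * (sgn * t + 1.0)
        w = rel - (rel @ u_ap) * u_ap
        r = float(np.linalg.norm(w))
        if r < 1e-12:
            return ap, 0.0, 0.0
        azimuth = math.atan2(float(w @ u_depth), float(w @ u_lat))
        rb = self.border_radius(t, azimuth)
        ml = 100.0 * r / rb if rb > 0 else 100.0
        return ap, ml, azimuth


@dataclass(frozen=True)
class SpotClusterSpec:
    """One cluster of point-like FISH signals (telomeres or centromeres).

    ``center`` is (AP%, ML%, azimuth) in the nucleus frame; ``member_count``
    members are rendered as Gaussian spots jittered within
    ``cluster_radius`` µm of the center so that they merge into a single
    connected component after thresholding.
    """

    channel: str
    member_count: int
    center: tuple[float, float, float]
    psf_sigma: tuple[float, float] = (0.35, 0.12)  # (sigma_z, sigma_xy) µm
    amplitude: float = 160.0
    cluster_radius: float = 0.12

    def __post_init__(self) -> None:
        if self.member_count < 1:
            raise ValueError("member_count must be >= 1")
        ap, ml, _ = self.center
        if not (0 <= ap <= 100 and 0 <= ml <= 100):
            raise ValueError("cluster center AP%/ML% must lie in [0, 100]")


@dataclass(frozen=True)
class CTSpec:
    """One chromosome-territory blob.

    The territory is a hard-edged ellipsoid aligned with the nucleus frame:
    semi-axes (along AP, lateral, depth) in µm; ``elongation_ratio`` is the
    ratio of the two in-plane semi-axes (1 for a round territory).  A fused
    SSC13;17 territory renders into both paint channels.
    """

    chromosome: str
    channels: tuple[str, ...]
    center: tuple[float, float, float]  # (AP%, ML%, azimuth)
    shape: str  # "round" | "elongated"
    volume: float  # µm³
    elongation_ratio: float
    semi_axes: tuple[float, float, float]
    amplitude: float = 180.0

    def __post_init__(self) -> None:
        if self.shape not in ("round", "elongated"):
            raise ValueError(f"unknown CT shape {self.shape!r}")
        if self.elongation_ratio < 1:
            raise ValueError("elongation_ratio must be >= 1")


@dataclass
class NucleusGroundTruth:
    """Generator-side truth for one nucleus."""

    nucleus_id: str
    carrier: bool
    gonosome: str  # "X" | "Y"
    nucleus: NucleusSpec
    clusters: dict[str, list[SpotClusterSpec]] = field(default_factory=dict)
    cts: list[CTSpec] = field(default_factory=list)
    pair_category: str | None = None
    association_count: int | None = None

    def cluster_count(self, channel: str) -> int:
        return len(self.clusters.get(channel, []))

    def telomere_total(self) -> int:
        return sum(c.member_count for c in self.clusters.get("telomeres", []))

    def ct_by_channel(self, channel: str) -> CTSpec | None:
        for ct in self.cts:
            if channel in ct.channels:
                return ct
        return None

    def to_dict(self) -> dict:
        return {
            "nucleus_id": self.nucleus_id,
            "carrier": self.carrier,
            "gonosome": self.gonosome,
            "nucleus": {
                "semi_axes": list(self.nucleus.semi_axes),
                "axis": list(self.nucleus.axis),
                "anterior_along_axis": self.nucleus.anterior_along_axis,
                "center": list(self.nucleus.center),
            },
            "clusters": {
                ch: [
                    {
                        "member_count": c.member_count,
                        "center": list(c.center),
                        "psf_sigma": list(c.psf_sigma),
                        "amplitude": c.amplitude,
                        "cluster_radius": c.cluster_radius,
                    }
                    for c in specs
                ]
                for ch, specs in self.clusters.items()
            },
            "cts": [
                {
                    "chromosome": ct.chromosome,
                    "channels": list(ct.channels),
                    "center": list(ct.center),
                    "shape": ct.shape,
                    "volume": ct.volume,
                    "elongation_ratio": ct.elongation_ratio,
                    "semi_axes": list(ct.semi_axes),
                    "amplitude": ct.amplitude,
                }
                for ct in self.cts
            ],
            "pair_category": self.pair_category,
            "association_count": self.association_count,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NucleusGroundTruth":
        nuc = NucleusSpec(
            semi_axes=tuple(d["nucleus"]["semi_axes"]),
            axis=tuple(d["nucleus"]["axis"]),
            anterior_along_axis=d["nucleus"]["anterior_along_axis"],
            center=tuple(d["nucleus"]["center"]),
        )
        clusters = {
            ch: [
                SpotClusterSpec(
                    channel=ch,
                    member_count=c["member_count"],
                    center=tuple(c["center"]),
                    psf_sigma=tuple(c["psf_sigma"]),
                    amplitude=c["amplitude"],
                    cluster_radius=c["cluster_radius"],
                )
                for c in specs
            ]
            for ch, specs in d["clusters"].items()
        }
        cts = [
            CTSpec(
                chromosome=c["chromosome"],
                channels=tuple(c["channels"]),
                center=tuple(c["center"]),
                shape=c["shape"],
                volume=c["volume"],
                elongation_ratio=c["elongation_ratio"],
                semi_axes=tuple(c["semi_axes"]),
                amplitude=c["amplitude"],
            )
            for c in d["cts"]
        ]
        return cls(
            nucleus_id=d["nucleus_id"],
            carrier=d["carrier"],
            gonosome=d["gonosome"],
            nucleus=nuc,
            clusters=clusters,
            cts=cts,
            pair_category=d["pair_category"],
            association_count=d["association_count"],
        )


# ---------------------------------------------------------------------------
# Parameters


@dataclass(frozen=True)
class PopulationParams:
    """Study-condition parameters of the synthetic population.

    Defaults emulate the acquisition and biology the analysis targets:
    0.093 × 0.093 × 0.244 µm voxels, 8-bit intensities, a 12 × 7 × 3 µm
    nucleus, telomere clusters of 2-4 telomeres, acrocentric (AC6)
    chromocenters concentrating 6 centromeres into 1-3 clusters and
    (sub)metacentric (SSCRS2A) chromocenters spreading 11 centromeres over
    3-9 clusters, a control SSC13/SSC17 pair-category distribution of
    16/32/52 % (colocalized/adjacent/distant), and peripheral SSC13 versus
    uniformly-spread SSC17 medio-lateral placement.
    """

    grid_shape: tuple[int, int, int] = (24, 168, 168)
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    channels: tuple[str, ...] = ("dna", "telomeres", "ssc13", "ssc17")

    # nucleus
    semi_axes: tuple[float, float, float] = (6.0, 3.5, 1.5)
    center_jitter_um: float = 0.3
    nucleus_amplitude: float = 120.0

    # noise
    background: float = 10.0
    read_noise_sigma: float = 3.0

    # point signals
    spot_amplitude: float = 160.0
    psf_sigma: tuple[float, float] = (0.35, 0.12)  # (z, xy) µm
    cluster_radius: float = 0.12
    min_cluster_separation: float = 1.0
    spot_placement_shrink: float = 0.85  # keep cluster centers interior

    # cluster-size / cluster-count distributions
    telomere_cluster_size_weights: tuple[tuple[int, float], ...] = (
        (2, 0.35), (3, 0.40), (4, 0.25),
    )
    ac6_cluster_count_weights: tuple[tuple[int, float], ...] = (
        (1, 0.4), (2, 0.5), (3, 0.1),
    )
    ac6_cluster_count_weights_fused: tuple[tuple[int, float], ...] = (
        (1, 0.7), (2, 0.3),
    )
    sscrs2a_cluster_count_weights: tuple[tuple[int, float], ...] = (
        (3, 0.04), (4, 0.08), (5, 0.25), (6, 0.30), (7, 0.25), (8, 0.06), (9, 0.02),
    )
    association_count_weights: tuple[tuple[int, float], ...] = (
        (0, 0.60), (1, 0.32), (2, 0.08),
    )

    # territories
    ct_amplitude: float = 180.0
    ct_depth_semi_axis: float = 0.8
    elongated_ratio: float = 2.5
    ssc13_volume: float = 8.0
    ssc17_volume: float = 4.0
    fused_volume: float = 12.0
    gonosome_volume: float = 3.0
    ssc13_p_round: float = 0.25
    ssc17_p_round: float = 0.70
    fused_p_round: float = 0.70
    # control pair-category proportions (colocalized, adjacent, distant)
    control_pair_probs: tuple[float, float, float] = (0.16, 0.32, 0.52)
    # positional distributions: (mean, sd) of truncated normals in percent
    ssc13_ap: tuple[float, float] = (50.0, 15.0)
    ssc13_ml: tuple[float, float] = (70.0, 15.0)
    ssc17_ap: tuple[float, float] = (50.0, 15.0)
    ssc17_ml_uniform: tuple[float, float] = (5.0, 70.0)
    gonosome_ap: dict = field(
        default_factory=lambda: {"X": (53.0, 15.0), "Y": (59.0, 15.0)}
    )
    gonosome_ml: dict = field(
        default_factory=lambda: {"X": (36.7, 15.0), "Y": (26.7, 15.0)}
    )

    # pair-category adjacency rule parameters (mirrors the analysis defaults)
    in_plane_pixel: float = 0.093

    @property
    def snr(self) -> float:
        """Peak spot amplitude over background-noise standard deviation."""
        return self.spot_amplitude / self.read_noise_sigma


def _weighted_choice(rng: np.random.Generator, weights: tuple[tuple[int, float], ...]) -> int:
    vals = [v for v, _ in weights]
    p = np.array([w for _, w in weights], dtype=float)
    return int(rng.choice(vals, p=p / p.sum()))


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float) -> float:
    for _ in range(100):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


# ---------------------------------------------------------------------------
# Rendering primitives


def _ellipsoid_mask_window(
    grid_shape: tuple[int, int, int],
    spacing: Sequence[float],
    center: Sequence[float],
    semi_axes: Sequence[float],
    basis: np.ndarray,
) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    """Boolean ellipsoid mask computed on a tight sub-window of the grid."""
    sp = np.asarray(spacing, dtype=float)
    c = np.asarray(center, dtype=float)
    extent = float(np.max(semi_axes))
    lo = np.maximum(np.floor((c - extent) / sp).astype(int) - 1, 0)
    hi = np.minimum(np.ceil((c + extent) / sp).astype(int) + 2, np.asarray(grid_shape))
    window = tuple(slice(int(l), int(h)) for l, h in zip(lo, hi))
    zz = (np.arange(lo[0], hi[0]) * sp[0] - c[0])[:, None, None]
    yy = (np.arange(lo[1], hi[1]) * sp[1] - c[1])[None, :, None]
    xx = (np.arange(lo[2], hi[2]) * sp[2] - c[2])[None, None, :]
    sa = np.asarray(semi_axes, dtype=float)
    q = np.zeros((hi - lo).astype(int), dtype=float)
    for row, s in zip(basis, sa):
        q += ((zz * row[0] + yy * row[1] + xx * row[2]) / s) ** 2
    return window, q <= 1.0


def _nucleus_mask(spec: NucleusSpec, grid_shape, spacing) -> np.ndarray:
    window, m = _ellipsoid_mask_window(
        grid_shape, spacing, spec.center, spec.semi_axes, spec.basis
    )
    full = np.zeros(grid_shape, dtype=bool)
    full[window] = m
    return full


def render_nucleus(
    spec: NucleusSpec,
    grid_shape: tuple[int, int, int],
    spacing: Sequence[float] = DEFAULT_SPACING,
    amplitude: float = 120.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render the counterstain channel: a filled flattened ellipsoid.

    Returns (boolean nucleus mask, float intensity contribution).  Raises
    when the nucleus does not fit inside the stack bounds.
    """
    sp = np.asarray(spacing, dtype=float)
    c = np.asarray(spec.center)
    extent = spec.semi_axes[0]
    bounds = (np.asarray(grid_shape) - 1) * sp
    if np.any(c - extent < -sp) or np.any(c + extent > bounds + sp):
        # cheap check on the bounding sphere; exact fit checked via the mask
        pass
    mask = _nucleus_mask(spec, tuple(grid_shape), spacing)
    if not mask.any():
        raise ValueError("nucleus does not intersect the stack")
    # error if the ellipsoid is clipped by the stack boundary
    for ax in range(3):
        idx = np.unique(np.argwhere(mask)[:, ax])
        if idx.min() == 0 or idx.max() == grid_shape[ax] - 1:
            # touching the boundary exactly at one voxel is tolerated only if
            # the continuous ellipsoid stays inside
            if c[ax] - extent < 0 or c[ax] + extent > bounds[ax]:
                raise ValueError("nucleus exceeds stack bounds")
    return mask, mask.astype(float) * amplitude


def _add_gaussian_spot(
    buffer: np.ndarray,
    spacing: np.ndarray,
    center: np.ndarray,
    sigma_z: float,
    sigma_xy: float,
    amplitude: float,
) -> None:
    """Add one anisotropic Gaussian spot in a ±4σ window."""
    shape = np.asarray(buffer.shape)
    sig = np.array([sigma_z, sigma_xy, sigma_xy])
    lo = np.maximum(np.floor((center - 4 * sig) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((center + 4 * sig) / spacing).astype(int) + 1, shape)
    if np.any(lo >= hi):
        return
    zz = (np.arange(lo[0], hi[0]) * spacing[0] - center[0])[:, None, None] / sigma_z
    yy = (np.arange(lo[1], hi[1]) * spacing[1] - center[1])[None, :, None] / sigma_xy
    xx = (np.arange(lo[2], hi[2]) * spacing[2] - center[2])[None, None, :] / sigma_xy
    buffer[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amplitude * np.exp(
        -0.5 * (zz**2 + yy**2 + xx**2)
    )


def render_spots(
    clusters: Sequence[SpotClusterSpec],
    nucleus: NucleusSpec,
    grid_shape: tuple[int, int, int],
    spacing: Sequence[float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Render a signal channel containing Gaussian spot clusters.

    Each cluster contributes ``member_count`` spots jittered uniformly within
    ``cluster_radius`` of the cluster center, so that members of one cluster
    stay within the segmentation merge distance.  Raises when a cluster
    center resolves outside the nucleus.
    """
    sp = np.asarray(spacing, dtype=float)
    buffer = np.zeros(grid_shape, dtype=float)
    for cl in clusters:
        center = nucleus.normalized_to_physical(*cl.center)
        if not nucleus.contains(center):
            raise ValueError(
                f"cluster center {cl.center} resolves outside the nucleus"
            )
        for _ in range(cl.member_count):
            for _try in range(20):
                offset = rng.uniform(-1, 1, size=3)
                if np.linalg.norm(offset) <= 1.0:
                    break
            pos = center + offset * cl.cluster_radius
            if not nucleus.contains(pos):
                pos = center
            _add_gaussian_spot(
                buffer, sp, pos, cl.psf_sigma[0], cl.psf_sigma[1], cl.amplitude
            )
    return buffer


def _ct_mask(
    ct: CTSpec, nucleus: NucleusSpec, grid_shape, spacing
) -> tuple[tuple[slice, ...], np.ndarray]:
    center = nucleus.normalized_to_physical(*ct.center)
    return _ellipsoid_mask_window(
        tuple(grid_shape), spacing, center, ct.semi_axes, nucleus.basis
    )


def render_ct(
    ct: CTSpec,
    nucleus: NucleusSpec,
    grid_shape: tuple[int, int, int],
    spacing: Sequence[float],
    buffer: np.ndarray,
) -> None:
    """Add one hard-edged ellipsoidal territory blob into ``buffer``.

    The sharp edge makes the thresholded region coincide with the nominal
    voxel mask for any global threshold between background and amplitude,
    which is what lets the generator guarantee pair categories exactly.
    Raises when the territory does not fit inside the nucleus.
    """
    center = nucleus.normalized_to_physical(*ct.center)
    # verify fit: all ellipsoid surface extremes along the frame axes inside
    for row, s in zip(nucleus.basis, ct.semi_axes):
        for sgn in (-1.0, 1.0):
            if not nucleus.contains(center + sgn * s * row, shrink=1.005):
                raise ValueError(
                    f"territory {ct.chromosome} does not fit inside the nucleus"
                )
    window, mask = _ct_mask(ct, nucleus, grid_shape, spacing)
    buffer[window][mask] += ct.amplitude


# ---------------------------------------------------------------------------
# Ground-truth sampling


def _partition_into_clusters(
    rng: np.random.Generator, total: int, size_weights
) -> list[int]:
    """Split ``total`` members into cluster sizes drawn from ``size_weights``,
    with any remainder smaller than the smallest drawable size as singletons."""
    sizes: list[int] = []
    remaining = total
    min_size = min(v for v, _ in size_weights)
    while remaining >= min_size:
        s = _weighted_choice(rng, size_weights)
        s = min(s, remaining)
        sizes.append(s)
        remaining -= s
    sizes.extend([1] * remaining)
    return sizes


def _partition_into_k(rng: np.random.Generator, total: int, k: int) -> list[int]:
    """Split ``total`` members into exactly ``k`` non-empty groups."""
    k = min(k, total)
    extra = rng.multinomial(total - k, np.full(k, 1.0 / k))
    return [1 + int(e) for e in extra]


def _sample_interior_points(
    rng: np.random.Generator,
    nucleus: NucleusSpec,
    n: int,
    min_separation: float,
    shrink: float,
    psf_sigma: tuple[float, float] = (0.35, 0.12),
    avoid: Sequence[np.ndarray] = (),
    avoid_separation: float = 0.0,
) -> list[np.ndarray]:
    """Rejection-sample ``n`` points inside the shrunken nucleus with pairwise
    and avoid-set separation constraints.

    Separation is measured in PSF-scaled space: the axial PSF is ~3x wider
    than the lateral one, so a given z offset separates spots less than the
    same in-plane offset; scaling dz by sigma_xy/sigma_z makes the separation
    constraint match the merge behavior of thresholded Gaussian spots.  The
    separation is relaxed by 5% per batch of failed attempts so the procedure
    always terminates.
    """
    pts: list[np.ndarray] = []
    sep = min_separation
    a_sep = avoid_separation
    sa = np.asarray(nucleus.semi_axes) * shrink
    basis = nucleus.basis
    center = np.asarray(nucleus.center)
    w = np.array([psf_sigma[1] / psf_sigma[0], 1.0, 1.0])  # (z, y, x) weights

    def eff_dist(p: np.ndarray, q: np.ndarray) -> float:
        return float(np.linalg.norm((p - q) * w))

    tries = 0
    while len(pts) < n:
        u = rng.uniform(-1, 1, size=3)
        if np.linalg.norm(u) > 1.0:
            continue
        p = center + (u * sa) @ basis
        ok = all(eff_dist(p, q) >= sep for q in pts) and all(
            eff_dist(p, q) >= a_sep for q in avoid
        )
        if ok:
            pts.append(p)
        tries += 1
        if tries > 300:
            sep *= 0.95
            a_sep *= 0.95
            tries = 0
    return pts


def _fit_ct_geometry(
    nucleus: NucleusSpec,
    params: PopulationParams,
    ap: float,
    ml: float,
    volume: float,
    ratio: float,
) -> tuple[float, float, tuple[float, float, float]]:
    """Clamp a territory's (AP%, ML%) and derive semi-axes so it fits.

    The territory is an ellipsoid aligned with the nucleus frame, long
    in-plane axis along AP, with a depth semi-axis capped by the local
    nucleus half-thickness; volume is preserved by rebalancing the in-plane
    semi-axes.
    """
    a, b, c = nucleus.semi_axes

    def semis(depth: float) -> tuple[float, float, float]:
        a2 = math.sqrt(3.0 * volume / (4.0 * math.pi * depth * ratio))
        return ratio * a2, a2, depth

    def fits(t: float, r: float, sa: tuple[float, float, float]) -> bool:
        # all six extreme points of the CT ellipsoid inside the nucleus
        # (local frame: x along AP in µm, y radial in-plane, z depth)
        a1, a2, d = sa
        x, y = t * a, r
        pts = [
            (x + a1, y, 0.0), (x - a1, y, 0.0),
            (x, y + a2, 0.0), (x, y - a2, 0.0),
            (x, y, d), (x, y, -d),
        ]
        return all(
            (px / a) ** 2 + (py / b) ** 2 + (pz / c) ** 2 <= 0.99
            for px, py, pz in pts
        )

    depth = params.ct_depth_semi_axis
    t = float(np.clip(ap / 50.0 - 1.0, -0.95, 0.95))
    ml = float(np.clip(ml, 0.0, 100.0))
    for _ in range(60):
        a1, a2, depth = semis(depth)
        t_max = max(0.0, (0.95 * a - a1) / a)
        t = float(np.clip(t, -t_max, t_max))
        s = math.sqrt(max(1e-6, 1.0 - t * t))
        r_b = b * s
        ml_max = max(0.0, 100.0 * (0.95 * r_b - a2) / r_b)
        ml = float(np.clip(ml, 0.0, ml_max))
        r = ml / 100.0 * r_b
        # cap depth by the local half-thickness at (t, r)
        h = c * math.sqrt(max(1e-6, s * s - (r / b) ** 2))
        if depth > 0.9 * h:
            depth = 0.9 * h
            continue
        if fits(t, r, (a1, a2, depth)):
            break
        # tighten toward the mid-plane center, where there is always room
        ml *= 0.85
        if ml < 1.0:
            ml = 0.0
            t *= 0.9
    else:  # pragma: no cover - geometric fallback
        t, ml = 0.0, 0.0
        a1, a2, depth = semis(params.ct_depth_semi_axis)
    ap = float(50.0 * (t + 1.0))
    return ap, ml, (a1, a2, depth)


def _make_ct(
    nucleus: NucleusSpec,
    params: PopulationParams,
    chromosome: str,
    channels: tuple[str, ...],
    ap: float,
    ml: float,
    azimuth: float,
    volume: float,
    is_round: bool,
) -> CTSpec:
    ratio = 1.0 if is_round else params.elongated_ratio
    ap, ml, semi = _fit_ct_geometry(nucleus, params, ap, ml, volume, ratio)
    return CTSpec(
        chromosome=chromosome,
        channels=channels,
        center=(ap, ml, azimuth),
        shape="round" if is_round else "elongated",
        volume=volume,
        elongation_ratio=ratio,
        semi_axes=semi,
        amplitude=params.ct_amplitude,
    )


def _ct_nominal_mask(ct: CTSpec, nucleus: NucleusSpec, params: PopulationParams):
    return _ct_mask(ct, nucleus, params.grid_shape, params.spacing)


def _pair_masks_category(
    ct_a: CTSpec, ct_b: CTSpec, nucleus: NucleusSpec, params: PopulationParams
) -> str:
    """Category the classification rule assigns to the two nominal voxel masks."""
    win_a, m_a = _ct_nominal_mask(ct_a, nucleus, params)
    win_b, m_b = _ct_nominal_mask(ct_b, nucleus, params)
    lo = [min(wa.start, wb.start) for wa, wb in zip(win_a, win_b)]
    hi = [max(wa.stop, wb.stop) for wa, wb in zip(win_a, win_b)]
    shape = tuple(h - l for l, h in zip(lo, hi))
    full_a = np.zeros(shape, dtype=bool)
    full_b = np.zeros(shape, dtype=bool)
    full_a[tuple(slice(w.start - l, w.stop - l) for w, l in zip(win_a, lo))] = m_a
    full_b[tuple(slice(w.start - l, w.stop - l) for w, l in zip(win_b, lo))] = m_b
    if not full_a.any() or not full_b.any():
        return DISTANT
    return classify_masks(
        full_a, full_b, params.spacing, in_plane_pixel=params.in_plane_pixel
    )


def _shift_ct_along_ap(
    ct: CTSpec, nucleus: NucleusSpec, base_center_phys: np.ndarray, offset_um: float
) -> CTSpec | None:
    """Return a copy of ``ct`` re-centered at base + offset along the AP axis,
    or None when the shifted territory no longer fits in the nucleus."""
    u_ap = nucleus.basis[0]
    new_center = base_center_phys + offset_um * u_ap
    ap, ml, az = nucleus.physical_to_normalized(new_center)
    if not (0 <= ap <= 100):
        return None
    moved = replace(ct, center=(ap, ml, az))
    for row, s in zip(nucleus.basis, moved.semi_axes):
        for sgn in (-1.0, 1.0):
            if not nucleus.contains(new_center + sgn * s * row, shrink=1.0):
                return None
    return moved


def _place_pair(
    rng: np.random.Generator,
    nucleus: NucleusSpec,
    params: PopulationParams,
    target: str,
) -> tuple[CTSpec, CTSpec, str]:
    """Place the SSC13/SSC17 territory pair aiming at ``target`` category.

    Placement is verified on the voxelized nominal masks with the same
    classification rule the analysis applies, so the recorded category is
    true by construction.  If the target cannot be realized after retries
    (rare), the realized category of the last placement is recorded instead.
    """
    px = params.in_plane_pixel
    last_pair: tuple[CTSpec, CTSpec] | None = None
    for attempt in range(12):
        pull = 0.85 ** attempt  # pull toward the nucleus center on retries
        az13 = float(rng.choice([0.0, math.pi]))
        ap13 = 50.0 + (_trunc_normal(rng, *params.ssc13_ap, 15, 85) - 50.0) * pull
        ml13 = _trunc_normal(rng, *params.ssc13_ml, 0, 85) * pull
        ct13 = _make_ct(
            nucleus, params, "SSC13", ("ssc13",), ap13, ml13, az13,
            params.ssc13_volume, rng.random() < params.ssc13_p_round,
        )
        is_round17 = rng.random() < params.ssc17_p_round
        if target == DISTANT:
            ap17 = _trunc_normal(rng, *params.ssc17_ap, 15, 85)
            ml17 = rng.uniform(*params.ssc17_ml_uniform)
            ct17 = _make_ct(
                nucleus, params, "SSC17", ("ssc17",), ap17, ml17,
                float(rng.choice([0.0, math.pi])), params.ssc17_volume, is_round17,
            )
            last_pair = (ct13, ct17)
            # quick accept on bounding spheres (conservative: guarantees a
            # physical gap far above the adjacency threshold)
            d = np.linalg.norm(
                nucleus.normalized_to_physical(*ct13.center)
                - nucleus.normalized_to_physical(*ct17.center)
            )
            if d < max(ct13.semi_axes) + max(ct17.semi_axes) + 4 * px:
                continue
            return ct13, ct17, DISTANT
        # proximal categories: build SSC17 next to SSC13 along the AP axis,
        # on the side with more room
        base = nucleus.normalized_to_physical(*ct13.center)
        t13 = float((base - np.asarray(nucleus.center)) @ nucleus.basis[0])
        side = -1.0 if t13 > 0 else 1.0
        ct17_proto = _make_ct(
            nucleus, params, "SSC17", ("ssc17",), ct13.center[0], ct13.center[1],
            az13, params.ssc17_volume, is_round17,
        )
        last_pair = (ct13, ct17_proto)
        e13, e17 = ct13.semi_axes[0], ct17_proto.semi_axes[0]
        if target == COLOCALIZED:
            offsets = [side * 0.55 * (e13 + e17), side * 0.3 * (e13 + e17), 0.0]
        else:  # ADJACENT: scan boundary gaps around zero
            offsets = [
                side * (e13 + e17 + g)
                for g in (0.04, 0.0, 0.07, -0.02, 0.10, 0.02, -0.05, 0.13, 0.05)
            ]
        for off in offsets:
            ct17 = _shift_ct_along_ap(ct17_proto, nucleus, base, off)
            if ct17 is None:
                continue
            last_pair = (ct13, ct17)
            if _pair_masks_category(ct13, ct17, nucleus, params) == target:
                return ct13, ct17, target
    # fallback (rare): keep the last valid placement, record what it realizes
    ct13, ct17 = last_pair
    realized = _pair_masks_category(ct13, ct17, nucleus, params)
    return ct13, ct17, realized


def _sample_nucleus_spec(
    rng: np.random.Generator, params: PopulationParams
) -> NucleusSpec:
    theta = rng.uniform(0, 2 * math.pi)
    axis = (0.0, math.sin(theta), math.cos(theta))
    sp = np.asarray(params.spacing)
    grid_center = (np.asarray(params.grid_shape) - 1) * sp / 2.0
    jitter = np.array([
        rng.uniform(-0.1, 0.1),
        rng.uniform(-params.center_jitter_um, params.center_jitter_um),
        rng.uniform(-params.center_jitter_um, params.center_jitter_um),
    ])
    return NucleusSpec(
        semi_axes=params.semi_axes,
        axis=axis,
        anterior_along_axis=bool(rng.integers(0, 2)),
        center=tuple(grid_center + jitter),
    )


def _spot_cluster(
    params: PopulationParams,
    nucleus: NucleusSpec,
    channel: str,
    size: int,
    point: np.ndarray,
) -> SpotClusterSpec:
    ap, ml, az = nucleus.physical_to_normalized(point)
    return SpotClusterSpec(
        channel=channel,
        member_count=size,
        center=(float(np.clip(ap, 0, 100)), float(np.clip(ml, 0, 100)), az),
        psf_sigma=params.psf_sigma,
        amplitude=params.spot_amplitude,
        cluster_radius=params.cluster_radius,
    )


def sample_ground_truth(
    nucleus_id: str,
    rng: np.random.Generator,
    params: PopulationParams,
    carrier_fraction: float,
) -> NucleusGroundTruth:
    """Draw the full ground truth of one nucleus (no rendering)."""
    if not 0.0 <= carrier_fraction <= 1.0:
        raise ValueError("carrier_fraction must be in [0, 1]")
    carrier = bool(rng.random() < carrier_fraction)
    gonosome = "X" if rng.random() < 0.5 else "Y"
    nucleus = _sample_nucleus_spec(rng, params)
    kary = build_haploid_karyotype(fused=carrier)
    truth = NucleusGroundTruth(
        nucleus_id=nucleus_id, carrier=carrier, gonosome=gonosome, nucleus=nucleus
    )

    sep = params.min_cluster_separation
    shrink = params.spot_placement_shrink

    if "telomeres" in params.channels:
        sizes = _partition_into_clusters(
            rng, kary.telomere_count, params.telomere_cluster_size_weights
        )
        pts = _sample_interior_points(rng, nucleus, len(sizes), sep, shrink, params.psf_sigma)
        truth.clusters["telomeres"] = [
            _spot_cluster(params, nucleus, "telomeres", s, p)
            for s, p in zip(sizes, pts)
        ]

    ac6_pts: list[np.ndarray] = []
    if "ac6" in params.channels:
        n_cen = labeled_centromere_count(kary, "AC6")
        weights = (
            params.ac6_cluster_count_weights_fused
            if carrier
            else params.ac6_cluster_count_weights
        )
        k = _weighted_choice(rng, weights)
        sizes = _partition_into_k(rng, n_cen, k)
        ac6_pts = _sample_interior_points(rng, nucleus, len(sizes), sep, shrink, params.psf_sigma)
        truth.clusters["ac6"] = [
            _spot_cluster(params, nucleus, "ac6", s, p)
            for s, p in zip(sizes, ac6_pts)
        ]

    if "sscrs2a" in params.channels:
        n_cen = labeled_centromere_count(kary, "SSCRS2A")
        k = _weighted_choice(rng, params.sscrs2a_cluster_count_weights)
        sizes = _partition_into_k(rng, n_cen, k)
        n_assoc = 0
        pts: list[np.ndarray] = []
        if ac6_pts:
            n_assoc = min(
                _weighted_choice(rng, params.association_count_weights),
                len(ac6_pts), len(sizes),
            )
            partners = rng.choice(len(ac6_pts), size=n_assoc, replace=False)
            for j in partners:
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                pts.append(ac6_pts[int(j)] + 0.08 * direction)
        free = _sample_interior_points(
            rng, nucleus, len(sizes) - len(pts), sep, shrink, params.psf_sigma,
            avoid=list(ac6_pts) + pts, avoid_separation=sep,
        )
        pts.extend(free)
        truth.clusters["sscrs2a"] = [
            _spot_cluster(params, nucleus, "sscrs2a", s, p)
            for s, p in zip(sizes, pts)
        ]
        truth.association_count = n_assoc

    if "gonosome" in params.channels:
        ap = _trunc_normal(rng, *params.gonosome_ap[gonosome], 10, 90)
        ml = _trunc_normal(rng, *params.gonosome_ml[gonosome], 0, 85)
        truth.cts.append(
            _make_ct(
                nucleus, params, f"SSC{gonosome}", ("gonosome",),
                ap, ml, rng.choice([0.0, math.pi]), params.gonosome_volume, True,
            )
        )

    if "ssc13" in params.channels and "ssc17" in params.channels:
        if carrier:
            # the fused chromosome forms a single territory painted by both
            # probes: colocalized by construction, SSC17-like position
            ap = _trunc_normal(rng, *params.ssc17_ap, 20, 80)
            ml = rng.uniform(*params.ssc17_ml_uniform)
            fused_ct = _make_ct(
                nucleus, params, "SSC13;17", ("ssc13", "ssc17"),
                ap, ml, rng.choice([0.0, math.pi]), params.fused_volume,
                rng.random() < params.fused_p_round,
            )
            truth.cts.append(fused_ct)
            truth.pair_category = COLOCALIZED
        else:
            probs = np.asarray(params.control_pair_probs, dtype=float)
            target = str(
                rng.choice(
                    [COLOCALIZED, ADJACENT, DISTANT], p=probs / probs.sum()
                )
            )
            ct13, ct17, realized = _place_pair(rng, nucleus, params, target)
            truth.cts.extend([ct13, ct17])
            truth.pair_category = realized
    return truth


# ---------------------------------------------------------------------------
# Full rendering


def render_ground_truth(
    truth: NucleusGroundTruth,
    params: PopulationParams,
    rng: np.random.Generator,
) -> ImageStack:
    """Render one ground-truth record into a noisy multi-channel 8-bit stack."""
    shape = params.grid_shape
    buffers = {ch: np.zeros(shape, dtype=float) for ch in params.channels}

    _, dna = render_nucleus(
        truth.nucleus, shape, params.spacing, amplitude=params.nucleus_amplitude
    )
    if "dna" in buffers:
        buffers["dna"] += dna

    for ch, clusters in truth.clusters.items():
        if ch in buffers:
            buffers[ch] += render_spots(
                clusters, truth.nucleus, shape, params.spacing, rng
            )

    for ct in truth.cts:
        for ch in ct.channels:
            if ch in buffers:
                render_ct(ct, truth.nucleus, shape, params.spacing, buffers[ch])

    channels = []
    for ch in params.channels:
        signal = buffers[ch]
        shot = rng.poisson(np.clip(signal, 0, None)).astype(float)
        img = shot + params.background + rng.normal(0, params.read_noise_sigma, shape)
        channels.append(np.clip(np.rint(img), 0, 255).astype(np.uint8))
    return ImageStack(
        voxels=np.stack(channels),
        spacing=params.spacing,
        channel_names=params.channels,
    )


def iter_population(
    n: int,
    carrier_fraction: float,
    params: PopulationParams | None = None,
    seed: int = 0,
    render: bool = True,
) -> Iterator[tuple[ImageStack | None, NucleusGroundTruth]]:
    """Lazily generate ``n`` nuclei with Bernoulli(carrier_fraction) carriers.

    Fully reproducible for a fixed seed: each nucleus derives its own
    independent substreams (one for the ground truth, one for rendering
    noise) from the master seed, so the manifests of a rendered and a
    manifest-only run coincide.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= carrier_fraction <= 1.0:
        raise ValueError("carrier_fraction must be in [0, 1]")
    params = params or PopulationParams()
    children = np.random.SeedSequence(seed).spawn(n)
    for i, child in enumerate(children):
        truth_seed, noise_seed = child.spawn(2)
        truth = sample_ground_truth(
            f"nucleus_{i:04d}",
            np.random.default_rng(truth_seed),
            params,
            carrier_fraction,
        )
        stack = (
            render_ground_truth(truth, params, np.random.default_rng(noise_seed))
            if render
            else None
        )
        yield stack, truth


def generate_population(
    n: int,
    carrier_fraction: float,
    params: PopulationParams | None = None,
    seed: int = 0,
    render: bool = True,
) -> list[tuple[ImageStack | None, NucleusGroundTruth]]:
    """Materialize ``iter_population`` as a list (small populations)."""
    return list(iter_population(n, carrier_fraction, params, seed, render=render))
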