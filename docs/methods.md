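# Methods

This note documents the models, assumptions, parameters and numerical
choices behind `spermfish3d`. Nothing here is an empirical claim about real
sperm beyond what the package itself computes; quantitative statements about
recovery quality are those verified by the test suite.

## Conventions

Voxel grids are indexed `(z, y, x)`; physical coordinates in µm are
`index * spacing` with `spacing = (dz, dy, dx)`. Default spacing is
0.244 × 0.093 × 0.093 µm (axial × in-plane), typical of confocal acquisition
of sperm heads. Intensities are 8-bit.

## Karyotype model

The haploid boar sperm karyotype is 18 autosomes plus one gonosome: 19
chromosomes and 38 telomeres. Two centromeric satellite probes are modeled:
AC6 labels the 6 acrocentric autosomes (SSC13–SSC18) and SSCRS2A labels the
(sub)metacentric chromosomes SSC2–SSC11 plus the gonosome (11 centromeres);
SSC1 and SSC12 carry neither target. The Robertsonian fusion t(13;17) merges
SSC13 and SSC17 at their centromeres: 18 chromosomes, 36 telomeres (the two
p-terminal telomeres are lost with the satellite arms), and a single
AC6-class centromere on the fusion product (one FISH signal instead of two).

**Segregation model.** A heterozygous carrier produces balanced gametes of
which a fraction `f` carry the fusion (0.5 under Mendelian segregation,
ignoring the rare unbalanced gametes). A fused gamete's SSC13/SSC17
territories are one merged territory, hence always *proximal* (colocalized or
adjacent); a normal gamete is proximal with the baseline probability `b`
observed in controls. Expected proportions:

```
proximal = f + (1 − f) · b        distant = 1 − proximal
```

Defaults `f = b = 0.5` give 75 % / 25 %. `b` defaults to the rounded control
value so the model target is exact; the measured control proximity can be
substituted.

## Segmentation

Objects are connected components of voxels above one global threshold per
channel (26-connectivity by default), mirroring the threshold-then-inspect
workflow of classic 3D-FISH quantification tools. The nucleus is the largest
component of the counterstain channel with internal holes filled (slice-wise,
then in 3D). Signal objects are restricted to the nucleus mask and filtered
by a minimum size (default 5 voxels) to suppress noise.

**Automatic threshold.** Otsu's between-class-variance criterion is used,
*validated*: Otsu assumes two intensity populations of comparable weight,
which sparse FISH channels violate (a few hundred signal voxels in ~10⁵
background voxels make the histogram effectively unimodal, and the Otsu
threshold lands inside the background mode). A split is rejected when it
labels more than 25 % of the stack as foreground — an order of magnitude
above any plausible FISH foreground — and replaced by a robust background
statistic, `median + 5 × 1.4826 × MAD`, which estimates the background mean
plus five standard deviations without being skewed by the bright minority.
Manual per-channel thresholds override both.

## Spatial metrics

- **Cluster counts**: each connected component in a spot channel is one
  cluster (chromocenter).
- **Pair classification**: two objects are *colocalized* when they share at
  least 2 voxels; otherwise the edge gap is
  `max(0, min voxel-center distance − one in-plane pixel)`, and the pair is
  *adjacent* when the gap is below one in-plane pixel (0.093 µm), *distant*
  otherwise. The center-to-edge correction uses the in-plane pixel because it
  is the resolution-limiting unit of the adjacency decision.
- **Associations**: cross-channel chromocenter pairs classifying colocalized
  or adjacent, consumed greedily by smallest gap with each object used at
  most once.
- **Nucleus frame**: the antero-posterior (AP) axis is the dominant principal
  axis of the nucleus voxel cloud (defined when the two largest principal
  extents differ by ≥ 1.2×; a sphere has no axis and raises). The anterior
  sign comes from a caller-provided hint (ground truth for synthetic data) or
  from a low-confidence taper heuristic (the narrower pole is anterior).
  AP% is the normalized position between the posterior (0) and anterior
  (100) extremes of the mask. ML% casts a ray from the axis point through
  the object centroid to the mask border (marching at ¼ in-plane pixel with
  6 bisection refinements) and reports 100 × centroid offset / border
  offset; it is unsigned (no left/right lateralization).
- **Morphology**: a territory is *elongated* when the square root of the
  ratio of the two largest covariance eigenvalues of its physical voxel
  coordinates strictly exceeds 1.5; a tie is round.
- **Border distance**: distance from a centroid to the nearest border voxel
  of the nucleus mask (6-connected border).

## Synthetic generator

The generator emulates the statistical structure the analysis assumes; it is
not a physical microscope simulation.

**What it emulates**
- A paddle-shaped nucleus as a flattened ellipsoid (semi-axes 6.0 × 3.5 ×
  1.5 µm), randomly oriented in-plane, with uniform counterstain
  (amplitude 120).
- Point-like FISH signals as anisotropic Gaussian spots (σz = 0.35 µm,
  σxy = 0.12 µm, amplitude 160) grouped into clusters: telomere clusters of
  2–4 members partitioning the 38 (or 36) telomeres, AC6 chromocenters
  concentrating 6 (or 5) centromeres into 1–3 (1–2) clusters, SSCRS2A
  chromocenters spreading 11 centromeres over 3–9 clusters, and 0–2
  AC6–SSCRS2A associations placed 0.08 µm apart.
- Chromosome territories as hard-edged ellipsoids aligned with the nucleus
  frame (round or elongated at in-plane ratio 2.5), with SSC13 peripheral
  (ML ≈ 70 ± 15), SSC17 spread uniformly, gonosome-specific positions, and a
  control pair-category distribution of 16/32/52 %.
- Carrier nuclei: one merged SSC13;17 territory rendered into both paint
  channels (colocalized by construction), 36 telomeres, 5 AC6 centromeres.
- Noise: Poisson shot noise on the signal, constant background 10, Gaussian
  read noise σ = 3, rounded and clipped to uint8. The nominal SNR
  (spot amplitude / read-noise σ) is ≈ 53.

**What it does not emulate**: optical blur of extended objects (territories
and the nucleus have voxel-sharp edges), depth-dependent attenuation,
chromatic shift between channels, acid-decondensation artifacts, overlapping
nuclei or debris, and intensity variation between probes of one class.

**Numerical choices**
- *Hard-edged territories*: any global threshold between background and
  amplitude recovers the nominal voxel mask exactly. After placing a pair
  the generator voxelizes both nominal masks on the acquisition grid and
  records the category assigned by the same `classify_masks` rule the
  analysis uses, retrying placement until the drawn category is realized —
  so the manifest's pair category is true by construction, not merely
  intended. If retries are exhausted the realized category is recorded.
- *PSF-scaled cluster separation*: cluster centers keep a minimum effective
  distance of 1 µm where the z-component is weighted by σxy/σz ≈ 0.34,
  because two clusters stacked axially merge at ~3× the distance of two
  lateral ones. This guarantees distinct clusters stay distinct after
  thresholding.
- *Joint feasibility of territory placement*: a territory's (AP, ML) target
  and semi-axes are adjusted together, checking all six ellipsoid extremes
  against the nucleus interior, since clamping AP and ML independently can
  violate the joint constraint near the poles.
- *Determinism*: a master `SeedSequence` spawns one child per nucleus, which
  spawns separate streams for ground truth and for rendering noise, so
  manifest-only runs and rendered runs agree and every output is
  byte-reproducible for a fixed seed.

## Statistics

Continuous per-nucleus measures are compared with two-sided pooled-variance
Student t-tests (a Welch variant is available); zero pooled variance with
equal means is reported as no difference, with unequal means it is an error.
Category distributions are compared with chi-squared homogeneity tests on
the contingency table (no continuity correction); observed counts are tested
against model proportions with chi-squared goodness-of-fit on k − 1 degrees
of freedom, requiring every expected count ≥ 1. No multiple-testing
correction is applied; reports record the number of tests run. The derived
summary `mean members per chromocenter` is `labeled centromeres / mean
cluster count`, rounded to 2 decimals (e.g. 6/1.7 = 3.53, 11/5.9 = 1.86).

## Parameters (units, defaults, rationale)

| Parameter | Default | Unit | Rationale |
|---|---|---|---|
| voxel spacing (dz, dy, dx) | 0.244, 0.093, 0.093 | µm | typical confocal sampling of sperm heads |
| nucleus semi-axes | 6.0, 3.5, 1.5 | µm | 12 µm long, ~3 µm thick paddle shape |
| PSF σ (z, xy) | 0.35, 0.12 | µm | confocal point-spread anisotropy ≈ 3× |
| spot amplitude / background / read σ | 160 / 10 / 3 | ADU | SNR ≈ 53, well above the validated regime (≥ 10) |
| min cluster separation | 1.0 | µm | keeps distinct clusters separable after PSF blur |
| adjacency unit (in-plane pixel) | 0.093 | µm | resolution-limiting unit of the gap decision |
| colocalization minimum | 2 | voxels | one shared voxel is within discretization error |
| min object size | 5 | voxels | suppresses single-voxel noise at read σ = 3 |
| max foreground fraction (Otsu validity) | 0.25 | — | FISH foreground ≪ 1 %, counterstain ≈ 9 %; 25 % separates both from a failed split |
| background-k (robust fallback) | 5 | σ | <1 false voxel per stack at Gaussian tails |
| morphology ratio threshold | 1.5 | — | round/elongated boundary on principal extents |
| territory depth semi-axis | 0.8 | µm | fits the 3 µm nuclear thickness |
| control pair categories | 0.16/0.32/0.52 | — | study condition of the control population |
| segregation f, b | 0.5, 0.5 | — | Mendelian segregation; rounded control proximity |

## Limitations

- The AP/ML frame assumes a clearly elongated nucleus; spherical or strongly
  eroded masks raise instead of returning meaningless positions.
- Without an anterior hint, AP polarity relies on the taper heuristic, which
  can flip on noisy masks; ML% and all distances are unaffected by polarity.
- The pair classification operates on thresholded voxel masks, so categories
  near the adjacency boundary are sensitive to the threshold within ±1 voxel.
- The generator's territories are sharp-edged; analysis behavior on blurred,
  overlapping real territories is validated only indirectly.
- Type-I error calibration covers the implemented defaults (n = 30 per group
  for t, 3-category tables of n = 100 for chi-squared).
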