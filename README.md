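# spermfish3d

Quantification of sperm nuclear architecture from multi-channel 3D-FISH
confocal stacks, with a synthetic ground-truth generator for end-to-end
validation.

## Scientific problem

In boar (*Sus scrofa*) sperm, chromatin is not packed randomly: telomeres and
centromeres gather into chromocenters, and each chromosome occupies a
territory at a reproducible position inside the paddle-shaped nucleus. A
Robertsonian translocation t(13;17) — the centromeric fusion of chromosomes
SSC13 and SSC17 — changes this architecture locally: the fused chromosome
forms a single merged territory, one acrocentric centromere signal is lost,
and two telomeres disappear with the satellite arms.

This package implements the measurement chain needed to detect such local
remodeling:

1. **Segmentation** — global-threshold segmentation of the nucleus
   (counterstain), FISH spot clusters and chromosome territories as
   26-connected voxel components, with an automatically validated Otsu
   threshold per channel.
2. **Spatial metrics** — cluster counts per probe; colocalized / adjacent /
   distant classification of territory pairs; cross-channel chromocenter
   associations; normalized antero-posterior (AP%) and medio-lateral (ML%)
   positions in the nucleus frame; territory morphology (round vs elongated);
   centroid-to-border distances.
3. **Karyotype model** — the haploid sperm chromosome set (19 chromosomes,
   38 telomeres; 18 and 36 with the fusion), probe target counts (6
   acrocentric AC6 centromeres, 11 SSCRS2A centromeres), and a segregation
   model predicting the expected proportion of proximal SSC13/SSC17 pairs in
   a heterozygous carrier's sperm: proximal = f + (1 − f)·b = 75 % for
   fusion fraction f = 0.5 and baseline proximity b = 0.5.
4. **Statistics** — pooled Student t-tests on continuous measures,
   chi-squared goodness-of-fit against model proportions, chi-squared
   homogeneity between groups.
5. **Synthetic data** — a generator producing confocal-like 8-bit stacks
   (Poisson shot noise + background + Gaussian read noise) whose full ground
   truth is recorded per nucleus, so the entire chain can be scored exactly:
   pair categories are guaranteed *by construction* by voxelizing the nominal
   territory masks and verifying them with the same classification rule the
   analysis uses.

## Worked example

Generate two small populations (12 control nuclei, 12 carrying the fusion),
measure every nucleus, and compare:

```python
import pandas as pd
from spermfish3d import generate_population, measure_nucleus, compare_populations
from spermfish3d.metrics import MeasureConfig

cfg = MeasureConfig()  # counterstain "dna", telomere spots, ssc13/ssc17 paints

def measure(carrier_fraction, seed):
    rows = []
    for stack, truth in generate_population(12, carrier_fraction, seed=seed):
        record = measure_nucleus(stack, cfg, nucleus_id=truth.nucleus_id,
                                 anterior_hint=truth.nucleus.anterior_direction)
        rows.append(record.to_row())
    return pd.DataFrame(rows)

control = measure(0.0, seed=11)
carrier = measure(1.0, seed=12)

print(control[["nucleus_id", "telomeres_clusters", "pair_category",
               "ssc13_ml_pct"]].head(4).to_string(index=False))

report = compare_populations(control.drop(columns="nucleus_id"),
                             carrier.drop(columns="nucleus_id"),
                             labels=("control", "carrier"))
cols = ["measure", "test", "mean_control", "mean_carrier", "p_value", "significant"]
print(report[cols].round(4).to_string(index=False))
```

Output (verbatim):

```
  nucleus_id  telomeres_clusters pair_category  ssc13_ml_pct
nucleus_0000                  12      adjacent     49.491459
nucleus_0001                  13       distant     67.598427
nucleus_0002                  12      adjacent     48.701494
nucleus_0003                  14   colocalized     44.116575
           measure             test  mean_control  mean_carrier  p_value  significant
telomeres_clusters        student_t       13.5833       12.5833   0.0223         True
      ssc13_ap_pct        student_t       48.9312       47.8824   0.8646        False
      ssc13_ml_pct        student_t       46.8949       30.5566   0.0144         True
      ssc17_ap_pct        student_t       51.7584       47.8824   0.4415        False
      ssc17_ml_pct        student_t       50.5936       30.5566   0.0009         True
   ssc13_border_um        student_t        0.9604        1.1359   0.0009         True
   ssc17_border_um        student_t        0.9923        1.1359   0.0036         True
     pair_category chi2_homogeneity           NaN           NaN   0.0025         True
     ssc13_central chi2_homogeneity           NaN           NaN   0.1316        False
     ssc17_central chi2_homogeneity           NaN           NaN   0.0593        False
  ssc13_morphology chi2_homogeneity           NaN           NaN   0.1025        False
  ssc17_morphology chi2_homogeneity           NaN           NaN   1.0000        False
```

Even at n = 12 per group, the carrier population shows the expected local
signature: the SSC13 territory moves toward the nuclear interior (ML% drops
from ~47 to ~31), pair categories shift toward colocalized, and a telomere
cluster is lost on average — while AP positions are unaffected.

The same workflow is available from the command line:

```bash
spermfish3d run --n 20 --seed 7 --out results/run7     # generate + measure + compare
spermfish3d generate --n 5 --seed 1 --out demo         # stacks + manifest only
spermfish3d segment demo/stacks/nucleus_0000.ome.tif --out demo/seg
spermfish3d measure demo/stacks --out demo/measurements.csv
spermfish3d compare a.csv b.csv --out comparison.csv
```

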