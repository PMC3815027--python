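"""Two-group comparisons of per-nucleus measurements.

Implements the comparisons used for sperm-architecture studies: pooled
two-sided Student t-tests on per-nucleus continuous measures (cluster
counts, normalized positions, border distances), chi-squared goodness-of-fit
of category counts against model proportions, chi-squared homogeneity
between two observed category distributions, and the derived
members-per-chromocenter summary.  No multiple-testing correction is
applied; the comparison report records the number of tests run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CategoryCounts",
    "student_test",
    "chi2_goodness_of_fit",
    "chi2_homogeneity",
    "mean_members_per_cluster",
    "compare_populations",
    "plot_measure_violin",
]

ALPHA = 0.05  # significance level of the reports


@dataclass(frozen=True)
class CategoryCounts:
    """Named category counts, e.g. {colocalized, adjacent, distant}."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("total count must be positive")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def as_arrays(self, order: Sequence[str] | None = None):
        keys = list(order) if order is not None else sorted(self.counts)
        return keys, np.array([self.counts[k] for k in keys], dtype=float)


def student_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided pooled-variance Student t-test.

    Returns (t statistic, p value).  Two samples with zero pooled variance
    and equal means compare as identical (t = 0, p = 1); zero pooled
    variance with unequal means is an error (the statistic is undefined).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means: t undefined")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def welch_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """Welch (unequal-variance) variant, available behind a flag."""
    t, p = sps.ttest_ind(np.asarray(sample_a, float), np.asarray(sample_b, float),
                         equal_var=False)
    return float(t), float(p)


def chi2_goodness_of_fit(
    observed: CategoryCounts, expected_proportions: Mapping[str, float]
) -> tuple[float, float]:
    """Chi-squared test of observed counts against expected proportions.

    Uses k-1 degrees of freedom.  Every expected count must be >= 1; an
    expected proportion of zero with a nonzero observed count is an error.
    """
    keys, obs = observed.as_arrays(order=list(expected_proportions))
    props = np.array([expected_proportions[k] for k in keys], dtype=float)
    if not np.isclose(props.sum(), 1.0):
        props = props / props.sum()
    exp = props * obs.sum()
    for k, o, e in zip(keys, obs, exp):
        if e == 0 and o > 0:
            raise ValueError(f"expected proportion 0 for non-empty category {k!r}")
    if np.any(exp < 1):
        raise ValueError("all expected counts must be >= 1")
    chi2, p = sps.chisquare(obs, f_exp=exp)
    return float(chi2), float(p)


def chi2_homogeneity(
    counts_a: CategoryCounts, counts_b: CategoryCounts
) -> tuple[float, float]:
    """Contingency-table chi-squared test of two category distributions.

    Categories empty in both groups are dropped with a warning; degrees of
    freedom are (rows-1)(cols-1) on the remaining table, without continuity
    correction.
    """
    keys = sorted(set(counts_a.counts) | set(counts_b.counts))
    a = np.array([counts_a.counts.get(k, 0) for k in keys], dtype=float)
    b = np.array([counts_b.counts.get(k, 0) for k in keys], dtype=float)
    keep = (a + b) > 0
    if not keep.all():
        dropped = [k for k, m in zip(keys, keep) if not m]
        warnings.warn(f"dropping categories empty in both groups: {dropped}")
        a, b = a[keep], b[keep]
    table = np.stack([a, b])
    if table.shape[1] < 2:
        raise ValueError("need at least two non-empty categories")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def mean_members_per_cluster(labeled_centromeres: int, mean_clusters: float) -> float:
    """Mean number of labeled centromeres per chromocenter, to 2 decimals.

    E.g. 6 acrocentric centromeres spread over a mean of 1.7 chromocenters
    per nucleus gives 3.53 centromeres per chromocenter.
    """
    if mean_clusters <= 0:
        raise ValueError("mean_clusters must be positive")
    return round(labeled_centromeres / mean_clusters, 2)


def _numeric_measures(df: pd.DataFrame) -> list[str]:
    skip = {"nucleus_id"}
    return [
        c for c in df.columns
        if c not in skip and pd.api.types.is_numeric_dtype(df[c])
        and not pd.api.types.is_bool_dtype(df[c])
    ]


def _categorical_measures(df: pd.DataFrame) -> list[str]:
    skip = {"nucleus_id"}
    return [
        c for c in df.columns
        if c not in skip
        and (pd.api.types.is_bool_dtype(df[c]) or df[c].dtype == object)
    ]


def compare_populations(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    labels: tuple[str, str] = ("a", "b"),
    use_welch: bool = False,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Compare two populations of NucleusRecord rows, measure by measure.

    Continuous measures get a Student t-test (pooled variance by default),
    categorical measures (pair category, morphology, central flags) a
    chi-squared homogeneity test.  Measures absent from either group are
    skipped with a warning.  The result is deterministic and annotates the
    total number of tests run (no multiple-testing correction is applied).
    """
    if len(records_a) == 0 or len(records_b) == 0:
        raise ValueError("both populations must be non-empty")
    rows = []
    for m in _numeric_measures(records_a):
        if m not in records_b.columns:
            warnings.warn(f"measure {m!r} absent from group {labels[1]}; skipped")
            continue
        a = records_a[m].dropna().to_numpy(dtype=float)
        b = records_b[m].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"measure {m!r} has too few values; skipped")
            continue
        try:
            t, p = (welch_test if use_welch else student_test)(a, b)
        except ValueError:
            t, p = float("nan"), 1.0
        rows.append({
            "measure": m, "test": "welch_t" if use_welch else "student_t",
            f"mean_{labels[0]}": float(a.mean()), f"mean_{labels[1]}": float(b.mean()),
            f"n_{labels[0]}": len(a), f"n_{labels[1]}": len(b),
            "statistic": t, "p_value": p, "significant": p < alpha,
        })
    for m in _categorical_measures(records_a):
        if m not in records_b.columns:
            warnings.warn(f"measure {m!r} absent from group {labels[1]}; skipped")
            continue
        va = records_a[m].dropna()
        vb = records_b[m].dropna()
        if va.nunique() + vb.nunique() == 0:
            continue
        ca = CategoryCounts(va.value_counts().to_dict())
        cb = CategoryCounts(vb.value_counts().to_dict())
        try:
            chi2, p = chi2_homogeneity(ca, cb)
        except ValueError:
            continue
        rows.append({
            "measure": m, "test": "chi2_homogeneity",
            f"mean_{labels[0]}": float("nan"), f"mean_{labels[1]}": float("nan"),
            f"n_{labels[0]}": len(va), f"n_{labels[1]}": len(vb),
            "statistic": chi2, "p_value": p, "significant": p < alpha,
        })
    report = pd.DataFrame(rows)
    report.attrs["n_tests"] = len(rows)
    report.attrs["alpha"] = alpha
    return report


def plot_measure_violin(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    measure: str,
    labels: tuple[str, str] = ("control", "carrier"),
    out_path: str | None = None,
):
    """Minimal violin plot of one measure in the two groups."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    data = [records_a[measure].dropna(), records_b[measure].dropna()]
    ax.violinplot(data, showmeans=True)
    ax.set_xticks([1, 2], labels)
    ax.set_ylabel(measure)
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig
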