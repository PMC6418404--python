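"""Nonparametric three-group comparison of the biomarker panel.

Each marker is summarized as median + interquartile range per group and
tested with the Kruskal-Wallis rank test followed by the chi-square
version of the Nemenyi all-pairs post-hoc test (joint ranking over all
three groups, tie-corrected variance).  Significance is flagged at
alpha = 0.05, matching the study's reporting convention.

The default statistical unit is the mean spectrum (272/272/208 per group
under the study design); an alternative per-sample mode aggregates marker
values within each animal first (n = 17/17/13).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import GROUPS
from .biomarkers import MARKERS

__all__ = [
    "GroupComparison",
    "median_iqr",
    "kruskal_wallis",
    "nemenyi_posthoc",
    "compare_biomarkers",
    "comparisons_to_frame",
]

logger = logging.getLogger(__name__)

_PAIRS = tuple(itertools.combinations(GROUPS, 2))


def median_iqr(values) -> tuple[float, float, float]:
    """(median, Q1, Q3) with linear quantile interpolation (type 7)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("median_iqr of an empty sample")
    if not np.all(np.isfinite(v)):
        raise ValueError("median_iqr requires finite values")
    med, q1, q3 = np.percentile(v, [50, 25, 75])
    return float(med), float(q1), float(q3)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p-value.

    Degenerate all-tied input returns (H=0, p=1) rather than raising.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if g.size == 0:
            raise ValueError("every group must contain at least one value")
    pooled = np.concatenate(groups)
    if pooled.size < 3:
        raise ValueError("need at least 3 values in total")
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = sps.kruskal(*groups)
    return float(H), float(p)


def nemenyi_posthoc(groups) -> pd.DataFrame:
    """Chi-square Nemenyi all-pairs test after a Kruskal-Wallis design.

    Values of the three groups are ranked jointly; for a pair (i, j) the
    statistic is

        chi2_ij = (Rbar_i - Rbar_j)^2 / [ N(N+1)/12 * C * (1/n_i + 1/n_j) ]

    with C = 1 - sum(t^3 - t)/(N^3 - N) the tie correction, referred to a
    chi-square distribution with k-1 degrees of freedom.  Returns a
    symmetric DataFrame of p-values with unit diagonal.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 3:
        raise ValueError(
            "Nemenyi post-hoc needs the full 3-group ranking context"
        )
    for g in groups:
        if g.size < 2:
            raise ValueError("every group needs >= 2 values")
    sizes = np.array([g.size for g in groups])
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for n in sizes:
        mean_ranks.append(ranks[start:start + n].mean())
        start += n
    mean_ranks = np.array(mean_ranks)

    _, tie_counts = np.unique(pooled, return_counts=True)
    C = 1.0 - np.sum(tie_counts**3 - tie_counts) / (N**3 - N)

    P = np.ones((k, k))
    if C <= 0:  # everything tied: no evidence of separation
        return pd.DataFrame(P)
    var_base = N * (N + 1) / 12.0 * C
    for i in range(k):
        for j in range(i + 1, k):
            d = mean_ranks[i] - mean_ranks[j]
            chi2 = d**2 / (var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            P[i, j] = P[j, i] = sps.chi2.sf(chi2, df=k - 1)
    return pd.DataFrame(P)


@dataclass
class GroupComparison:
    """Per-marker nonparametric comparison result."""

    marker: str
    medians: dict[str, float]
    q1: dict[str, float]
    q3: dict[str, float]
    n: dict[str, int]
    h_statistic: float
    p_value: float
    pairwise_p: dict[tuple[str, str], float]
    significant: dict[tuple[str, str], bool]
    n_dropped: int = 0
    testable: bool = True
    alpha: float = 0.05
    notes: str = ""
    pairs: tuple = field(default=_PAIRS, repr=False)


def _aggregate_per_sample(panel: pd.DataFrame) -> pd.DataFrame:
    agg = (
        panel.groupby(["sample_id", "group"], as_index=False)[list(MARKERS)]
        .mean()
    )
    return agg


def compare_biomarkers(
    panel: pd.DataFrame,
    alpha: float = 0.05,
    unit: str = "mean_spectrum",
    markers=MARKERS,
) -> list[GroupComparison]:
    """Run KW + Nemenyi on every marker column of a panel table.

    ``unit='mean_spectrum'`` tests the panel rows directly;
    ``unit='sample'`` first averages marker values within each sample.
    Undefined (NaN) marker values are dropped per marker with a logged
    count; a marker whose groups cannot all supply >= 2 defined values is
    reported as not testable instead of raising.
    """
    if unit == "sample":
        panel = _aggregate_per_sample(panel)
    elif unit != "mean_spectrum":
        raise ValueError(f"unknown unit {unit!r}")
    missing = [g for g in GROUPS if g not in set(panel["group"])]
    if missing:
        raise ValueError(f"panel is missing groups: {missing}")

    results = []
    for marker in markers:
        col = panel[marker]
        defined = panel[np.isfinite(col)]
        n_dropped = len(panel) - len(defined)
        if n_dropped:
            logger.info("%s: dropped %d undefined values", marker, n_dropped)
        by_group = {g: defined.loc[defined["group"] == g, marker].to_numpy()
                    for g in GROUPS}
        if any(v.size < 2 for v in by_group.values()):
            results.append(
                GroupComparison(
                    marker=marker,
                    medians={}, q1={}, q3={},
                    n={g: int(v.size) for g, v in by_group.items()},
                    h_statistic=float("nan"), p_value=float("nan"),
                    pairwise_p={}, significant={},
                    n_dropped=n_dropped, testable=False, alpha=alpha,
                    notes="a group has < 2 defined values",
                )
            )
            continue
        med, q1, q3 = {}, {}, {}
        for g, v in by_group.items():
            med[g], q1[g], q3[g] = median_iqr(v)
        H, p = kruskal_wallis([by_group[g] for g in GROUPS])
        P = nemenyi_posthoc([by_group[g] for g in GROUPS]).to_numpy()
        idx = {g: i for i, g in enumerate(GROUPS)}
        pairwise = {pair: float(P[idx[pair[0]], idx[pair[1]]]) for pair in _PAIRS}
        results.append(
            GroupComparison(
                marker=marker,
                medians=med, q1=q1, q3=q3,
                n={g: int(v.size) for g, v in by_group.items()},
                h_statistic=H, p_value=p,
                pairwise_p=pairwise,
                significant={pair: pv < alpha for pair, pv in pairwise.items()},
                n_dropped=n_dropped, alpha=alpha,
            )
        )
    return results


def comparisons_to_frame(results: list[GroupComparison]) -> pd.DataFrame:
    """Flatten GroupComparison results into one row per marker."""
    rows = []
    for r in results:
        row: dict = {"marker": r.marker, "testable": r.testable,
                     "H": r.h_statistic, "p": r.p_value,
                     "n_dropped": r.n_dropped}
        for g in GROUPS:
            row[f"median_{g}"] = r.medians.get(g, float("nan"))
            row[f"q1_{g}"] = r.q1.get(g, float("nan"))
            row[f"q3_{g}"] = r.q3.get(g, float("nan"))
            row[f"n_{g}"] = r.n.get(g, 0)
        for a, b in _PAIRS:
            row[f"p_{a[:4]}_vs_{b[:4]}"] = r.pairwise_p.get((a, b), float("nan"))
            row[f"sig_{a[:4]}_vs_{b[:4]}"] = r.significant.get((a, b), False)
        rows.append(row)
    return pd.DataFrame(rows)
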