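"""Nonparametric comparison of the benchmarked algorithms.

Normality is screened with Shapiro-Wilk; since the benchmark metrics
deviate from normality, groups are described by median and interquartile
range and compared with the Kruskal-Wallis rank test.  Significant
omnibus differences are followed by Dunn's pairwise z-tests with
Benjamini-Hochberg adjustment, summarised as homogeneous subgroups
(maximal cliques of mutually non-significant algorithms).  The effect of
the interference level is tested on per-scenario ACC ratios
(low/high noise) with a two-sided Wilcoxon signed-rank test against a
median ratio of one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupedMetric",
    "describe_median_iqr",
    "normality_gate",
    "kruskal_wallis",
    "dunn_posthoc_bh",
    "acc_ratio_test",
    "homogeneous_subgroups",
    "group_metric",
    "summarize_benchmark",
]

ALPHA = 0.05


@dataclass
class GroupedMetric:
    """Per-algorithm value vectors of one metric at one noise level."""

    metric: str
    noise_level: str  # "low" (r01) or "high" (r02)
    values: dict[str, np.ndarray]

    def groups(self) -> list[np.ndarray]:
        return list(self.values.values())

    def algorithms(self) -> list[str]:
        return list(self.values.keys())


def describe_median_iqr(values) -> tuple[float, float, float]:
    """Sample median and quartiles (linear interpolation)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(med), float(q1), float(q3)


def normality_gate(values) -> tuple[float, float]:
    """Shapiro-Wilk statistic and p-value (3 <= n <= 5000 required)."""
    v = np.asarray(values, dtype=float)
    if not 3 <= v.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(v) == 0:
        raise ValueError("constant sample: variance undefined")
    stat, p = sst.shapiro(v)
    return float(stat), float(p)


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p-value."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sst.kruskal(*groups)
    return float(h), float(p)


def dunn_posthoc_bh(groups: list) -> np.ndarray:
    """All-pairs Dunn z-tests with BH adjustment across the pairs.

    Uses pooled mid-ranks with the standard tie correction
    sum(t^3 - t) / (12 (N - 1)) in the z denominator.  Returns a symmetric
    matrix of adjusted p-values (diagonal 1).
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    sizes = np.array([len(a) for a in arrays])
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = sst.rankdata(pooled)
    mean_ranks = []
    start = 0
    for size in sizes:
        mean_ranks.append(ranks[start:start + size].mean())
        start += size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 *
                                                            (n_total - 1))
    raw = []
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0:
            raw.append(1.0)
            continue
        z = (mean_ranks[i] - mean_ranks[j]) / se
        raw.append(2.0 * sst.norm.sf(abs(z)))
    adjusted = multipletests(raw, method="fdr_bh")[1]
    out = np.ones((k, k))
    for (i, j), p in zip(pairs, adjusted):
        out[i, j] = out[j, i] = p
    return out


def acc_ratio_test(acc_low, acc_high) -> tuple[np.ndarray, float]:
    """Per-scenario low/high ACC ratios and a two-sided signed-rank p-value
    for the null that their median equals one."""
    low = np.asarray(acc_low, dtype=float)
    high = np.asarray(acc_high, dtype=float)
    if low.shape != high.shape:
        raise ValueError("paired vectors must have equal length")
    if np.any(high <= 0):
        raise ValueError("denominators must be positive")
    ratios = low / high
    diffs = ratios - 1.0
    if np.all(diffs == 0):
        warnings.warn("all ACC ratios exactly 1: degenerate signed-rank test")
        return ratios, 1.0
    _, p = sst.wilcoxon(diffs, alternative="two-sided")
    return ratios, float(p)


def homogeneous_subgroups(adjusted_p: np.ndarray, alpha: float = ALPHA,
                          labels: list[str] | None = None) -> list[tuple]:
    """Maximal cliques of the pairwise non-significance graph.

    Algorithms within a subgroup are mutually indistinguishable at
    ``alpha``; an algorithm may belong to several overlapping subgroups.
    """
    p = np.asarray(adjusted_p, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("adjusted_p must be a square matrix")
    k = p.shape[0]
    if labels is None:
        labels = list(range(k))
    graph = nx.Graph()
    graph.add_nodes_from(range(k))
    for i in range(k):
        for j in range(i + 1, k):
            if p[i, j] > alpha:
                graph.add_edge(i, j)
    cliques = [tuple(sorted(labels[i] for i in c))
               for c in nx.find_cliques(graph)]
    return sorted(cliques)


_METRIC_COLS = {
    "ACC_S1": "acc_s1",
    "ACC_S2": "acc_s2",
    "SNR_improvement": "snr_improvement_db",
    "interval_error": "mean_interval_error_ms",
}


def group_metric(df: pd.DataFrame, metric: str, record: str) -> GroupedMetric:
    """Extract per-algorithm value vectors for one metric/record from a
    benchmark result table (per-cell rows only)."""
    col = _METRIC_COLS[metric]
    cells = df[(df["record"] == record)]
    values = {}
    for algorithm, sub in cells.groupby("algorithm", sort=False):
        values[algorithm] = sub[col].to_numpy(dtype=float)
    level = "low" if record == "r01" else "high"
    return GroupedMetric(metric, level, values)


def summarize_benchmark(df: pd.DataFrame,
                        alpha: float = ALPHA) -> pd.DataFrame:
    """Median (IQR) per algorithm/metric/level with the Kruskal-Wallis
    omnibus p and, when significant, the homogeneous subgroups."""
    rows = []
    for metric in _METRIC_COLS:
        for record in ("r01", "r02"):
            grouped = group_metric(df, metric, record)
            clean = {a: v[~np.isnan(v)] for a, v in grouped.values.items()}
            h, p = kruskal_wallis(list(clean.values()))
            subgroups = None
            if p < alpha:
                adj = dunn_posthoc_bh(list(clean.values()))
                subgroups = homogeneous_subgroups(
                    adj, alpha, labels=list(clean.keys()))
            for algorithm, v in clean.items():
                med, q1, q3 = describe_median_iqr(v)
                rows.append({"metric": metric,
                             "noise_level": grouped.noise_level,
                             "algorithm": algorithm, "median": med,
                             "q1": q1, "q3": q3, "kw_p": p,
                             "subgroups": subgroups})
    return pd.DataFrame(rows)
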