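"""Group statistics for helix/dimer metrics.

Two comparison recipes mirror the source study's figure legends: one-way
ANOVA with Tukey's HSD post-hoc, and Kruskal-Wallis with Dunn's multiple
comparisons.  The statistical units are per-monomer (or per-tetramer,
per-pair) window means, never raw frames, to avoid pseudo-replication.

Dunn's test is implemented here directly (rank sums on the pooled sample,
z statistic with tie correction, two-sided normal p-values) with Holm
adjustment by default — the study does not name its adjustment, and Holm is
the conservative standard choice.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import SampleSizeError, SpecError

ANOVA_TUKEY = "anova_tukey"
KW_DUNN = "kw_dunn"


@dataclass
class GroupComparison:
    metric: str
    method: str
    summaries: pd.DataFrame  # group, n, mean, median, q25, q75, min, max
    omnibus_statistic: float
    omnibus_p: float
    pairwise: pd.DataFrame  # group_a, group_b, p_adjusted


def _summaries(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    rows = []
    for name in groups:
        x = np.asarray(groups[name], dtype=float)
        rows.append(
            (
                name,
                len(x),
                x.mean(),
                np.median(x),
                np.percentile(x, 25),
                np.percentile(x, 75),
                x.min(),
                x.max(),
            )
        )
    return pd.DataFrame(
        rows, columns=["group", "n", "mean", "median", "q25", "q75", "min", "max"]
    )


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted


def dunn_test(groups: Mapping[str, Sequence[float]], adjust: str = "holm") -> pd.DataFrame:
    """Dunn's rank-based post-hoc test for all group pairs.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),
    with tie correction T = sum(t^3 - t) / (12 (N - 1)).
    """
    names = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in names]
    pooled = np.concatenate(values)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for name, x in zip(names, values):
        sizes[name] = len(x)
        mean_ranks[name] = ranks[start : start + len(x)].mean()
        start += len(x)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for a, b in combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append((a, b, z, p))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])
    if adjust == "holm":
        df["p_adjusted"] = holm_adjust(df["p_raw"].to_numpy())
    elif adjust == "none":
        df["p_adjusted"] = df["p_raw"]
    else:
        raise SpecError(f"unknown adjustment {adjust!r}")
    return df


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    method: str = KW_DUNN,
    metric: str = "",
) -> GroupComparison:
    """Omnibus test plus pairwise post-hoc comparisons across named groups.

    ``anova_tukey``: one-way ANOVA with Tukey HSD.  ``kw_dunn``:
    Kruskal-Wallis with Dunn's test, Holm-adjusted.  Every group needs
    n >= 3; at least two groups are required.
    """
    if len(groups) < 2:
        raise SampleSizeError("compare_groups needs at least two groups")
    for name, x in groups.items():
        if len(x) < 3:
            raise SampleSizeError(f"group {name!r} has n={len(x)} < 3")
    values = [np.asarray(groups[g], dtype=float) for g in groups]
    summaries = _summaries(groups)

    if method == ANOVA_TUKEY:
        stat, p = sps.f_oneway(*values)
        flat = np.concatenate(values)
        labels = np.concatenate([[g] * len(groups[g]) for g in groups])
        tk = pairwise_tukeyhsd(flat, labels)
        res = tk.summary().data
        pairwise = pd.DataFrame(res[1:], columns=[str(c) for c in res[0]])
        pairwise = pairwise.rename(
            columns={"group1": "group_a", "group2": "group_b", "p-adj": "p_adjusted"}
        )[["group_a", "group_b", "p_adjusted"]]
        pairwise["p_adjusted"] = pairwise["p_adjusted"].astype(float)
    elif method == KW_DUNN:
        stat, p = sps.kruskal(*values)
        pairwise = dunn_test(groups)[["group_a", "group_b", "p_adjusted"]]
    else:
        raise SpecError(f"unknown method {method!r}")

    return GroupComparison(
        metric=metric,
        method=method,
        summaries=summaries,
        omnibus_statistic=float(stat),
        omnibus_p=float(p),
        pairwise=pairwise.reset_index(drop=True),
    )


def pairwise_p(comparison: GroupComparison, a: str, b: str) -> float:
    """Adjusted p-value for one group pair (order-insensitive)."""
    df = comparison.pairwise
    hit = df[
        ((df.group_a == a) & (df.group_b == b)) | ((df.group_a == b) & (df.group_b == a))
    ]
    if hit.empty:
        raise KeyError(f"pair ({a}, {b}) not in comparison")
    return float(hit.iloc[0].p_adjusted)
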