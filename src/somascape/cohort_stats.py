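"""Cohort-comparison statistics: exact rank-sum and Fisher tests, clustering.

The two-group contrasts used throughout the pipeline are the two-sided
Wilcoxon rank-sum test (exact by full enumeration of the rank-sum
distribution for small untied samples, normal approximation with tie and
continuity corrections otherwise) and the two-sided Fisher exact test by
point-probability summation over the hypergeometric distribution. P-values
are not multiplicity-adjusted by default; a Benjamini-Hochberg column is
available on request.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io_formats import CohortManifest

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComparisonResult:
    metric: str
    groups: tuple[str, str]
    statistic: float
    p_two_sided: float
    method: str  # wilcoxon_exact | wilcoxon_normal | fisher_exact
    n: tuple[int, int]
    degenerate: bool = False
    detail: dict | None = None


_EXACT_LIMIT = 20


def _ranksum_distribution(nx: int, n_total: int) -> np.ndarray:
    """Counts of subsets of size nx of ranks 1..n_total by rank sum (DP)."""
    max_sum = nx * n_total
    counts = np.zeros((nx + 1, max_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in range(1, n_total + 1):
        for j in range(min(r, nx), 0, -1):
            counts[j, r:] += counts[j - 1, :-r] if r else counts[j - 1, :]
    return counts[nx]


def wilcoxon_rank_sum(x, y, metric: str = "metric",
                      groups: tuple[str, str] = ("x", "y")) -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact path: when the pooled size is <= 20 and there are no ties, the
    two-sided p is P(|W - E[W]| >= |w_obs - E[W]|) under full enumeration of
    the rank-sum distribution. Otherwise the normal approximation with
    midranks, tie-corrected variance, and a 0.5 continuity correction is
    used. Identical pooled values are degenerate with p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups need at least one value")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return ComparisonResult(metric, groups, float(len(x) * (len(pooled) + 1) / 2),
                                1.0, "wilcoxon_exact", (len(x), len(y)), degenerate=True)
    n, m = len(x), len(y)
    N = n + m
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n].sum())
    has_ties = len(np.unique(pooled)) < N
    mean_w = n * (N + 1) / 2
    if N <= _EXACT_LIMIT and not has_ties:
        dist = _ranksum_distribution(n, N)
        sums = np.arange(len(dist))
        dev = abs(w - mean_w)
        p = float(dist[np.abs(sums - mean_w) >= dev - 1e-9].sum() / comb(N, n))
        return ComparisonResult(metric, groups, w, min(p, 1.0), "wilcoxon_exact", (n, m))
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (N * (N - 1))
    var_w = n * m / 12 * (N + 1 - tie_term)
    dev = abs(w - mean_w)
    z = max(dev - 0.5, 0.0) / np.sqrt(var_w)
    p = float(2 * stats.norm.sf(z))
    return ComparisonResult(metric, groups, w, min(p, 1.0), "wilcoxon_normal", (n, m))


def fisher_exact_2x2(table, metric: str = "metric",
                     groups: tuple[str, str] = ("x", "y")) -> ComparisonResult:
    """Two-sided Fisher exact test by hypergeometric point-probability summation.

    The p-value sums, over all tables with the observed margins, the
    hypergeometric probabilities no greater than the observed table's (within
    1e-7 relative tolerance). A zero margin is degenerate with p = 1.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    a, b = t[0]
    c, d = t[1]
    N = int(t.sum())
    row1, col1 = a + b, a + c
    if row1 == 0 or col1 == 0 or (c + d) == 0 or (b + d) == 0:
        return ComparisonResult(metric, groups, float("nan"), 1.0, "fisher_exact",
                                (row1, c + d), degenerate=True,
                                detail={"table": t.tolist()})
    hg = stats.hypergeom(N, col1, row1)
    k_min, k_max = max(0, row1 + col1 - N), min(row1, col1)
    ks = np.arange(k_min, k_max + 1)
    pmf = hg.pmf(ks)
    p_obs = hg.pmf(a)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    return ComparisonResult(metric, groups, odds, min(p, 1.0), "fisher_exact",
                            (row1, c + d), detail={"table": t.tolist()})


def compare_cohorts(
    metrics: pd.DataFrame,
    manifest: CohortManifest,
    binary_metrics: Sequence[str] = (),
    adjust: bool = False,
) -> pd.DataFrame:
    """One comparison row per metric column between the manifest's two groups.

    Continuous columns go through :func:`wilcoxon_rank_sum`; columns named in
    ``binary_metrics`` are 0/1 event indicators tested with
    :func:`fisher_exact_2x2` on the per-group event table. Samples with a
    missing value are dropped for that metric (logged). ``adjust`` adds a
    Benjamini-Hochberg column; raw p-values are reported either way.
    """
    labels = manifest.group_labels
    if len(labels) != 2:
        raise ValueError("compare_cohorts needs exactly two groups")
    ga, gb = labels
    rows = []
    for col in metrics.columns:
        series = metrics[col]
        missing = series.isna()
        if missing.any():
            logger.info("metric %s: dropping %d samples with missing values",
                        col, int(missing.sum()))
            series = series.dropna()
        xs = series.loc[[s for s in manifest.samples_in(ga) if s in series.index]]
        ys = series.loc[[s for s in manifest.samples_in(gb) if s in series.index]]
        if col in binary_metrics:
            table = [[int(xs.sum()), int((1 - xs).sum())],
                     [int(ys.sum()), int((1 - ys).sum())]]
            res = fisher_exact_2x2(table, metric=col, groups=(ga, gb))
        else:
            res = wilcoxon_rank_sum(xs, ys, metric=col, groups=(ga, gb))
        rows.append({
            "metric": col, "group_a": ga, "group_b": gb,
            "n_a": res.n[0], "n_b": res.n[1],
            "median_a": float(xs.median()) if len(xs) else float("nan"),
            "median_b": float(ys.median()) if len(ys) else float("nan"),
            "statistic": res.statistic, "p_two_sided": res.p_two_sided,
            "method": res.method, "degenerate": res.degenerate,
        })
    out = pd.DataFrame(rows).set_index("metric")
    if adjust:
        p = out["p_two_sided"].to_numpy()
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        bh = np.empty_like(adj)
        bh[order] = np.minimum(adj, 1.0)
        out["p_bh"] = bh
    return out


def hierarchical_cluster(
    features: pd.DataFrame,
    metric: str = "euclidean",
    method: str = "complete",
    n_groups: int = 2,
) -> dict:
    """Agglomerative clustering of a samples x features matrix.

    Returns the linkage matrix, leaf order, and a flat ``n_groups`` cut as a
    sample -> cluster-id mapping. Deterministic given input order (scipy's
    lowest-index merge tie-break). A constant feature matrix yields a single
    cluster and is flagged.
    """
    if len(features) < 2:
        raise ValueError("clustering needs at least two samples")
    X = features.to_numpy(dtype=float)
    constant = bool(np.all(X == X[0]))
    Z = hierarchy.linkage(pdist(X, metric=metric), method=method)
    order = [features.index[i] for i in hierarchy.leaves_list(Z)]
    if constant:
        flat = {s: 1 for s in features.index}
    else:
        cut = hierarchy.fcluster(Z, t=n_groups, criterion="maxclust")
        flat = {s: int(c) for s, c in zip(features.index, cut)}
    return {"linkage": Z, "order": order, "flat": flat, "constant": constant}
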