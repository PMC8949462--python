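"""Gene-category profile clustering with bootstrap cluster support.

Strains are clustered by Euclidean distance on (optionally per-genome
percent-normalized) gene-category counts with average linkage.  Cluster
support follows the multiscale-bootstrap scheme: categories (columns) are
resampled at several scales r (resample size round(r * m)); BP(r) is the
fraction of replicate dendrograms containing the cluster; fitting
``Phi^{-1}(1 - BP) = d * sigma + c / sigma`` with ``sigma = 1 / sqrt(r)`` by
weighted least squares yields the approximately unbiased support
``AU = 1 - Phi(d - c)`` (BP at scale 1 corresponds to ``1 - Phi(d + c)``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import norm

DEFAULT_SCALES = (0.5, 0.75, 1.0, 1.25, 1.5)


def read_category_counts(path: str) -> pd.DataFrame:
    """Long-format TSV (strain, category, count) -> strains x categories."""
    df = pd.read_csv(path, sep="\t")
    need = {"strain", "category", "count"}
    if not need.issubset(df.columns):
        raise ValueError(f"count table needs columns {sorted(need)}")
    wide = df.pivot_table(index="strain", columns="category", values="count",
                          aggfunc="sum", fill_value=0)
    return wide.astype(int)


def normalize(counts: pd.DataFrame, mode: str = "count",
              totals: pd.Series | None = None) -> pd.DataFrame:
    """'count' returns counts unchanged; 'percent' returns 100*count/total."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    if mode == "count":
        return counts.astype(float)
    if mode != "percent":
        raise ValueError(f"unknown mode {mode!r}")
    if totals is None:
        raise ValueError("percent mode requires per-strain totals")
    totals = totals.reindex(counts.index)
    if totals.isna().any() or (totals <= 0).any():
        raise ValueError("percent mode requires positive totals for all strains")
    return 100.0 * counts.div(totals, axis=0)


def hcluster(x: pd.DataFrame, method: str = "average") -> np.ndarray:
    """Average-linkage agglomeration on Euclidean distances (scipy linkage).

    Rows of ``x`` are the items; returns the scipy linkage matrix.
    """
    if x.shape[0] < 2:
        raise ValueError("need >= 2 rows")
    return linkage(x.to_numpy(dtype=float), method=method, metric="euclidean")


def _clusters_of(Z: np.ndarray, n: int) -> list:
    """Tip-index frozensets of every internal cluster of a linkage matrix."""
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for k, (a, b, _, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + k] = merged
        out.append(merged)
    return out


def two_group_cut(Z: np.ndarray, n: int) -> np.ndarray:
    """Labels of the 2-cluster cut of the dendrogram (1-based group ids)."""
    return fcluster(Z, t=2, criterion="maxclust")


@dataclass
class ClusterSupport:
    """Dendrogram plus per-internal-cluster BP and AU support (percent)."""

    linkage: np.ndarray
    strains: list
    clusters: list  # frozensets of strain labels, merge order
    bp: np.ndarray
    au: np.ndarray

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cluster": ["+".join(sorted(c)) for c in self.clusters],
            "bp": self.bp,
            "au": self.au,
        })


def cluster_support(x: pd.DataFrame, B_per_scale: int = 1000,
                    scales=DEFAULT_SCALES, seed: int = 0,
                    method: str = "average") -> ClusterSupport:
    """Multiscale-bootstrap support for every cluster of the point dendrogram.

    Columns (categories) are resampled with replacement; ``scales`` must
    include values below and above 1.0 for the AU extrapolation.
    """
    if x.shape[0] < 3:
        raise ValueError("need >= 3 rows")
    scales = tuple(scales)
    if any(s <= 0 for s in scales):
        raise ValueError("scales must be positive")
    n, m = x.shape
    arr = x.to_numpy(dtype=float)
    Z = hcluster(x, method)
    point_clusters = _clusters_of(Z, n)
    # drop the trivial all-items cluster from support reporting? keep it: BP=100
    rng = np.random.default_rng(seed)
    n_cl = len(point_clusters)
    bp_by_scale = np.zeros((len(scales), n_cl))
    for si, r in enumerate(scales):
        m_r = max(2, int(round(r * m)))
        hits = np.zeros(n_cl)
        for _ in range(B_per_scale):
            cols = rng.integers(0, m, size=m_r)
            Zb = linkage(arr[:, cols], method=method, metric="euclidean")
            rep = set(_clusters_of(Zb, n))
            for ci, cl in enumerate(point_clusters):
                if cl in rep:
                    hits[ci] += 1
        bp_by_scale[si] = hits / B_per_scale
    au, bp1 = _au_from_multiscale(bp_by_scale, np.asarray(scales), B_per_scale)
    strains = list(x.index)
    named = [frozenset(strains[i] for i in cl) for cl in point_clusters]
    return ClusterSupport(Z, strains, named, 100.0 * bp1, 100.0 * au)


def _au_from_multiscale(bp: np.ndarray, scales: np.ndarray, B: int):
    """Fit the signed-distance/curvature model and return (AU, BP at scale 1)."""
    n_scales, n_cl = bp.shape
    sigma = 1.0 / np.sqrt(scales)
    eps = 1.0 / (2.0 * B)
    au = np.empty(n_cl)
    bp1 = np.empty(n_cl)
    one = int(np.argmin(np.abs(scales - 1.0)))
    for ci in range(n_cl):
        p = np.clip(bp[:, ci], eps, 1.0 - eps)
        bp1[ci] = bp[one, ci]
        if (bp[:, ci] >= 1.0 - 1e-12).all():
            au[ci] = 1.0
            continue
        if (bp[:, ci] <= 1e-12).all():
            au[ci] = 0.0
            continue
        z = norm.ppf(1.0 - p)  # = d*sigma + c/sigma
        # weighted LS: var(z) ~ p(1-p) / (B * phi(z)^2)
        w = B * norm.pdf(z) ** 2 / (p * (1.0 - p))
        X = np.column_stack([sigma, 1.0 / sigma])
        WX = X * w[:, None]
        beta, *_ = np.linalg.lstsq(X.T @ WX, X.T @ (w * z), rcond=None)
        d_hat, c_hat = beta
        au[ci] = 1.0 - norm.cdf(d_hat - c_hat)
    return au, bp1


def dendrogram_newick(Z: np.ndarray, labels: list,
                      support: np.ndarray | None = None) -> str:
    """Newick string of a scipy linkage matrix, heights as branch lengths."""
    n = len(labels)
    height = {i: 0.0 for i in range(n)}
    node = {i: labels[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = max(h - height[a], 0.0)
        lb = max(h - height[b], 0.0)
        sup = "" if support is None else f"{support[k]:.0f}"
        node[n + k] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g}){sup}"
        height[n + k] = h
    return node[n + len(Z) - 1] + ";"
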