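"""Shape-based clustering of per-promoter TBP footprints and core promoter
element enrichment per cluster.

To emphasize footprint shape over amplitude, each promoter's stranded
profile is rank-transformed per row before Euclidean k-means.  Element
enrichment per cluster uses two-sided Fisher exact tests on in-cluster vs
out-of-cluster element presence, corrected with Benjamini-Hochberg across
all (cluster, element) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, rankdata
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .coverage import ProfileMatrix

__all__ = [
    "RankProfileMatrix",
    "ClusterResult",
    "EnrichmentResult",
    "select_top_signal",
    "rank_transform",
    "kmeans_profiles",
    "element_enrichment",
]


@dataclass
class RankProfileMatrix:
    """Per-row rank-transformed profiles; values lie in (0, 1]."""

    promoter_ids: list[str]
    values: np.ndarray  # promoters x (pos-strand || neg-strand offsets)


@dataclass
class ClusterResult:
    promoter_ids: list[str]
    assignments: np.ndarray  # cluster ids 1..k, relabeled by descending size
    centroids: np.ndarray
    k: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"promoter_id": self.promoter_ids, "cluster": self.assignments}
        )


@dataclass
class EnrichmentResult:
    cluster: int
    element: str
    in_n: int
    in_total: int
    out_n: int
    out_total: int
    ratio: float  # in_fraction / out_fraction; inf or nan when degenerate
    p: float
    q: float = np.nan

    @property
    def in_fraction(self) -> float:
        return self.in_n / self.in_total

    @property
    def out_fraction(self) -> float:
        return self.out_n / self.out_total


def select_top_signal(
    matrix: ProfileMatrix,
    quantile_keep: float = 0.9,
    window: tuple[int, int] = (-40, 40),
) -> ProfileMatrix:
    """Keep the top fraction of promoters by total signal in a window.

    Totals sum both strand planes over the inclusive offset window.  The
    cut keeps ``ceil(quantile_keep * n)`` promoters; ties at the threshold
    are kept (inclusive), so an all-equal matrix passes through whole.
    """
    sl = matrix.window_slice(*window)
    totals = matrix.sense_positive[:, sl].sum(axis=1) + matrix.sense_negative[
        :, sl
    ].sum(axis=1)
    n = len(totals)
    n_keep = int(np.ceil(quantile_keep * n))
    threshold = np.sort(totals)[::-1][n_keep - 1]
    keep = np.nonzero(totals >= threshold)[0]
    return matrix.subset(keep)


def rank_transform(values: np.ndarray, promoter_ids: list[str] | None = None) -> RankProfileMatrix:
    """Replace each row by (average ranks) / n_columns, mapping into (0, 1]."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] == 0:
        raise ValueError("need a non-empty 2-D matrix")
    ranked = np.apply_along_axis(rankdata, 1, values) / values.shape[1]
    if promoter_ids is None:
        promoter_ids = [str(i) for i in range(values.shape[0])]
    return RankProfileMatrix(promoter_ids=list(promoter_ids), values=ranked)


def profile_features(
    matrix: ProfileMatrix, window: tuple[int, int] = (-40, 40)
) -> np.ndarray:
    """Concatenated (positive || negative) strand features over a window."""
    sl = matrix.window_slice(*window)
    return np.hstack([matrix.sense_positive[:, sl], matrix.sense_negative[:, sl]])


def kmeans_profiles(
    matrix: RankProfileMatrix,
    k: int = 4,
    n_starts: int = 100,
    max_iter: int = 30,
    seed: int = 0,
) -> ClusterResult:
    """Euclidean k-means on rank-transformed profiles.

    The best of ``n_starts`` random initializations (lowest within-cluster
    sum of squares, at most ``max_iter`` Lloyd iterations each) is kept,
    and cluster ids are relabeled 1..k by descending cluster size so runs
    are comparable.
    """
    X = matrix.values
    if X.shape[0] < k:
        raise ValueError("fewer rows than clusters")
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=n_starts,
        max_iter=max_iter,
        random_state=seed,
        algorithm="lloyd",
    )
    raw = km.fit_predict(X)
    sizes = np.bincount(raw, minlength=k)
    # descending size; ties broken by original label for determinism
    order = np.lexsort((np.arange(k), -sizes))
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    return ClusterResult(
        promoter_ids=matrix.promoter_ids,
        assignments=relabel[raw],
        centroids=km.cluster_centers_[order],
        k=k,
        seed=seed,
    )


def element_enrichment(
    assignments: pd.Series | dict,
    element_presence: pd.DataFrame,
) -> list[EnrichmentResult]:
    """Per (cluster, element) enrichment of element presence.

    ``assignments`` maps promoter_id -> cluster id; ``element_presence``
    is a promoter x element boolean frame (zero-mismatch scan results).
    in/out fractions compare promoters in a cluster with all remaining
    promoters; p-values are two-sided Fisher exact tests on the 2x2 table
    and q-values are Benjamini-Hochberg adjusted over all pairs jointly.
    """
    assignments = pd.Series(assignments)
    presence = element_presence.loc[assignments.index].astype(bool)
    results: list[EnrichmentResult] = []
    for cluster in sorted(assignments.unique()):
        in_mask = (assignments == cluster).to_numpy()
        in_total = int(in_mask.sum())
        out_total = int((~in_mask).sum())
        if in_total == 0:
            raise ValueError(f"cluster {cluster} is empty")
        for element in presence.columns:
            col = presence[element].to_numpy()
            in_n = int(col[in_mask].sum())
            out_n = int(col[~in_mask].sum())
            in_frac = in_n / in_total
            out_frac = out_n / out_total if out_total else np.nan
            if out_frac and out_frac > 0:
                ratio = in_frac / out_frac
            elif in_frac > 0:
                ratio = np.inf
            else:
                ratio = np.nan
            table = [[in_n, in_total - in_n], [out_n, out_total - out_n]]
            _, p = fisher_exact(table, alternative="two-sided")
            results.append(
                EnrichmentResult(
                    cluster=int(cluster),
                    element=str(element),
                    in_n=in_n,
                    in_total=in_total,
                    out_n=out_n,
                    out_total=out_total,
                    ratio=ratio,
                    p=float(p),
                )
            )
    pvals = np.array([r.p for r in results])
    qvals = multipletests(pvals, method="fdr_bh")[1]
    for r, q in zip(results, qvals):
        r.q = float(q)
    return results


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cluster": [r.cluster for r in results],
            "element": [r.element for r in results],
            "in_n": [r.in_n for r in results],
            "in_total": [r.in_total for r in results],
            "out_n": [r.out_n for r in results],
            "out_total": [r.out_total for r in results],
            "ratio": [r.ratio for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
        }
    )
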