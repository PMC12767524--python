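"""Transcription-normalized occupancy, between-type tests, binding-level
correlation with hierarchical clustering, and condition-difference
correlations.

Raw footprint signal scales with both occupancy and transcriptional
output, so per-promoter signal is divided by the promoter's CAGE
expression score before comparing factor levels between promoter types.
Binding-level similarity between factors is measured as Pearson
correlation of log2(x+1) window sums, converted to 1-r distances and
clustered with Ward linkage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu, norm, rankdata, tiecorrect

from .coverage import ProfileMatrix

__all__ = [
    "CorrelationMatrix",
    "cage_normalize",
    "compare_types",
    "rank_sum_test",
    "binding_correlation",
    "delta_correlation",
]

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    factors: list[str]
    r: np.ndarray  # symmetric Pearson matrix
    linkage_matrix: np.ndarray  # scipy linkage encoding of the Ward dendrogram

    @property
    def distance(self) -> np.ndarray:
        return 1.0 - self.r

    def to_newick(self) -> str:
        """Serialize the dendrogram as a Newick string."""
        n = len(self.factors)

        def node(i: int) -> str:
            if i < n:
                return self.factors[i]
            a, b, h, _ = self.linkage_matrix[i - n]
            return f"({node(int(a))},{node(int(b))}):{h:.6g}"

        return node(2 * n - 2) + ";" if n > 1 else self.factors[0] + ";"


def cage_normalize(
    matrix: ProfileMatrix,
    cage: dict[str, float] | pd.Series,
    mode: str = "occupancy",
    profile_window: tuple[int, int] = (-150, 150),
    occupancy_window: tuple[int, int] = (-50, 50),
) -> pd.DataFrame | ProfileMatrix:
    """Scale footprint signal by per-promoter CAGE expression.

    ``occupancy`` mode returns one scalar per promoter: the both-strand
    signal sum over ``occupancy_window`` divided by the CAGE score.
    ``profile`` mode divides every base value within ``profile_window`` by
    the CAGE score and returns a new ProfileMatrix.  Promoters with a
    missing or non-positive CAGE score are excluded (logged, not raised).
    """
    cage = pd.Series(cage, dtype=float)
    ids = matrix.promoter_ids
    scores = cage.reindex(ids)
    valid = scores.notna() & (scores > 0)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("cage_normalize: excluded %d promoters without CAGE score", n_dropped)
    idx = np.nonzero(valid.to_numpy())[0]
    sub = matrix.subset(idx)
    s = scores.to_numpy()[idx]
    if mode == "occupancy":
        sl = sub.window_slice(*occupancy_window)
        raw = sub.sense_positive[:, sl].sum(axis=1) + sub.sense_negative[:, sl].sum(axis=1)
        return pd.DataFrame(
            {
                "promoter_id": sub.promoter_ids,
                "raw_signal": raw,
                "cage_score": s,
                "normalized": raw / s,
            }
        )
    if mode == "profile":
        w = sub.window_half_width
        lo = max(profile_window[0], -w)
        hi = min(profile_window[1], w)
        sl = sub.window_slice(lo, hi)
        pos = sub.sense_positive.copy()
        neg = sub.sense_negative.copy()
        pos[:, sl] = pos[:, sl] / s[:, None]
        neg[:, sl] = neg[:, sl] / s[:, None]
        return ProfileMatrix(
            promoter_ids=sub.promoter_ids,
            window_half_width=w,
            sense_positive=pos,
            sense_negative=neg,
            out_of_bounds=sub.out_of_bounds.copy(),
        )
    raise ValueError(f"unknown mode {mode!r}")


def rank_sum_test(x: np.ndarray, y: np.ndarray, max_exact_n: int = 25) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Uses the exact Mann-Whitney null distribution when the pooled sample
    is small and tie-free; otherwise the normal approximation with tie
    correction and no continuity correction (so identical groups give
    exactly p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 observations")
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    if tie_free and len(pooled) <= max_exact_n:
        return float(mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)
    n1, n2 = len(x), len(y)
    ranks = rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    sigma = np.sqrt(tiecorrect(ranks) * n1 * n2 * (n1 + n2 + 1) / 12)
    if sigma == 0:
        return 1.0
    z = (u1 - mu) / sigma
    return float(min(1.0, 2 * norm.sf(abs(z))))


def compare_types(
    occupancies: pd.DataFrame,
    group_col: str = "group",
    value_col: str = "normalized",
) -> pd.DataFrame:
    """Pairwise two-sided rank-sum tests between promoter-type groups.

    All observations enter the test (outlier trimming is a plotting
    concern only).  Returns one row per unordered group pair.
    """
    groups = {g: df[value_col].to_numpy() for g, df in occupancies.groupby(group_col)}
    names = sorted(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "n_a": len(groups[a]),
                    "n_b": len(groups[b]),
                    "median_a": float(np.median(groups[a])),
                    "median_b": float(np.median(groups[b])),
                    "p": rank_sum_test(groups[a], groups[b]),
                }
            )
    return pd.DataFrame(rows)


def binding_correlation(signal_table: pd.DataFrame) -> CorrelationMatrix:
    """Pearson correlation of log2(x+1) binding levels + Ward dendrogram.

    ``signal_table`` holds promoters x factors window sums.  Constant
    factor columns (undefined correlation) are dropped with a warning.
    The 1-r dissimilarity is clustered with the classic Ward criterion
    applied directly to the dissimilarities (R's ward.D), implemented via
    the equivalence ward.D(d) = scipy ward(sqrt(d)).
    """
    if signal_table.shape[0] < 3:
        raise ValueError("need >= 3 promoters")
    logx = np.log2(signal_table.astype(float) + 1.0)
    constant = logx.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            f"dropping constant factor columns: {list(logx.columns[constant])}",
            stacklevel=2,
        )
        logx = logx.loc[:, ~constant]
    if logx.shape[1] < 2:
        raise ValueError("need >= 2 non-constant factors")
    r = np.corrcoef(logx.to_numpy(), rowvar=False)
    dist = np.clip(1.0 - r, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    lm = linkage(np.sqrt(condensed), method="ward")
    return CorrelationMatrix(factors=list(logx.columns), r=r, linkage_matrix=lm)


def delta_correlation(
    control_table: pd.DataFrame,
    treated_table: pd.DataFrame,
    tbp_windows: dict[str, pd.Series] | None = None,
    tbp_control: pd.DataFrame | None = None,
    tbp_treated: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Difference in Pearson correlation (control - treated) between
    window-summed TBP signal and each factor.

    ``tbp_control``/``tbp_treated`` hold one column per named TBP window
    (e.g. upstream [-25,-10], downstream [+25,+40]) indexed like the
    factor tables.  Returns rows (window, factor, r_control, r_treated,
    delta_pcc).
    """
    if not control_table.index.equals(treated_table.index):
        raise ValueError("control and treated tables cover different promoters")
    if tbp_control is None or tbp_treated is None:
        raise ValueError("TBP window sums required for both conditions")
    logc = np.log2(control_table.astype(float) + 1.0)
    logt = np.log2(treated_table.astype(float) + 1.0)
    rows = []
    for window in tbp_control.columns:
        tc = np.log2(tbp_control[window].astype(float) + 1.0)
        tt = np.log2(tbp_treated[window].astype(float) + 1.0)
        for factor in control_table.columns:
            r_c = float(np.corrcoef(tc, logc[factor])[0, 1])
            r_t = float(np.corrcoef(tt, logt[factor])[0, 1])
            rows.append(
                {
                    "window": window,
                    "factor": factor,
                    "r_control": r_c,
                    "r_treated": r_t,
                    "delta_pcc": r_c - r_t,
                }
            )
    return pd.DataFrame(rows)


def tbp_window_sums(
    matrix: ProfileMatrix,
    windows: dict[str, tuple[int, int]] = None,
) -> pd.DataFrame:
    """Both-strand TBP signal sums per named offset window."""
    if windows is None:
        windows = {"upstream": (-25, -10), "downstream": (25, 40)}
    data = {}
    for name, (lo, hi) in windows.items():
        sl = matrix.window_slice(lo, hi)
        data[name] = matrix.sense_positive[:, sl].sum(axis=1) + matrix.sense_negative[
            :, sl
        ].sum(axis=1)
    return pd.DataFrame(data, index=matrix.promoter_ids)
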