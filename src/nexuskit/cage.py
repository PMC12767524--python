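"""CAGE-based TSS annotation: power-law normalization, tag clustering,
interquantile boundaries, cross-replicate consensus and narrow-promoter
selection.

CAGE counts capped transcript 5' ends per genomic base.  Replicates are
normalized onto a referent power law (slope alpha, total T), per-strand
positions are grouped by distance-based clustering, each cluster's central
activity region is delimited by the 10th/90th percentiles of its cumulative
signal, clusters are merged across replicates into consensus clusters with
a dominant TSS, and focused ("narrow") promoters are selected by
interquantile width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PowerLawParams",
    "TagCluster",
    "ConsensusCluster",
    "powerlaw_normalize",
    "cluster_ctss",
    "interquantile_boundaries",
    "aggregate_clusters",
    "select_narrow_promoters",
    "assign_genes",
]


@dataclass(frozen=True)
class PowerLawParams:
    """Referent power law for cross-library CAGE normalization.

    ``alpha`` is the slope magnitude of the referent reverse-cumulative
    count distribution in log-log space and ``T`` its total tag count; the
    line is fitted to observed counts in ``[fit_low, fit_high]``.
    """

    alpha: float = 1.19
    T: float = 1e6
    fit_low: int = 3
    fit_high: int = 40000

    def __post_init__(self) -> None:
        if self.alpha <= 1:
            raise ValueError("alpha must exceed 1")
        if self.fit_low >= self.fit_high:
            raise ValueError("fit_low must be < fit_high")


@dataclass
class TagCluster:
    """A run of nearby CAGE tag positions on one strand."""

    chrom: str
    strand: str
    positions: np.ndarray  # sorted, 0-based
    counts: np.ndarray  # per-position signal (TPM scale after normalization)
    q_low_pos: int | None = None
    q_high_pos: int | None = None

    @property
    def tpm(self) -> float:
        return float(self.counts.sum())

    @property
    def interquantile_width(self) -> int | None:
        if self.q_low_pos is None or self.q_high_pos is None:
            return None
        return self.q_high_pos - self.q_low_pos + 1


@dataclass
class ConsensusCluster:
    """Cross-replicate consensus TSS cluster."""

    chrom: str
    strand: str
    start: int  # 0-based inclusive
    end: int  # 0-based inclusive
    dominant_tss: int
    tpm: float
    interquantile_width: int
    positions: np.ndarray = field(default=None, repr=False)
    counts: np.ndarray = field(default=None, repr=False)
    gene_id: str | None = None
    cluster_id: str = ""

    @property
    def n_positions(self) -> int:
        return 0 if self.positions is None else int(len(self.positions))


def _reverse_cumulative(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distinct count values c and N(c) = number of positions with >= c tags."""
    values, mult = np.unique(np.asarray(counts, dtype=float), return_counts=True)
    # positions with count >= c, for c descending: cumulative sum of multiplicities
    n_ge = np.cumsum(mult[::-1])[::-1]
    return values, n_ge.astype(float)


def powerlaw_normalize(
    counts: np.ndarray, params: PowerLawParams = PowerLawParams()
) -> np.ndarray:
    """Map raw per-position tag counts onto the referent power law.

    A line is least-squares fitted to log N(c) vs log c over distinct
    counts in the fit range, where N(c) is the reverse-cumulative number
    of positions with at least c tags.  Each raw count is then mapped to
    the count that occupies the same reverse-cumulative rank under the
    referent law N_ref(x) = T(alpha-1) * x**(-alpha), whose integral total
    is T.  The mapping is monotone non-decreasing in the raw count.
    """
    counts = np.asarray(counts, dtype=float)
    values, n_ge = _reverse_cumulative(counts)
    in_range = (values >= params.fit_low) & (values <= params.fit_high)
    if np.count_nonzero(in_range) < 2:
        raise ValueError(
            f"need >= 2 distinct counts in [{params.fit_low}, {params.fit_high}]"
        )
    x = np.log(values[in_range])
    y = np.log(n_ge[in_range])
    slope, intercept = np.polyfit(x, y, 1)
    if slope >= 0:
        raise ValueError("reverse-cumulative fit is non-decreasing; not a power law")
    k_ref = params.T * (params.alpha - 1.0)
    # solve N_data(c) = N_ref(c'):  exp(intercept) c^slope = k_ref c'^(-alpha)
    out = np.zeros_like(counts)
    nz = counts > 0
    log_c = np.log(counts[nz])
    log_cprime = -(intercept + slope * log_c - np.log(k_ref)) / params.alpha
    out[nz] = np.exp(log_cprime)
    return out


def cluster_ctss(
    positions: np.ndarray,
    counts: np.ndarray,
    chrom: str,
    strand: str,
    maxdist: int = 30,
) -> list[TagCluster]:
    """Distance-based (distclu-style) clustering of tag positions.

    Consecutive positions with a gap of at most ``maxdist`` bp join the
    same cluster; clustering is independent per strand.
    """
    positions = np.asarray(positions, dtype=int)
    counts = np.asarray(counts, dtype=float)
    if positions.size == 0:
        return []
    order = np.argsort(positions)
    positions, counts = positions[order], counts[order]
    breaks = np.nonzero(np.diff(positions) > maxdist)[0] + 1
    clusters = []
    for pos_chunk, cnt_chunk in zip(
        np.split(positions, breaks), np.split(counts, breaks)
    ):
        clusters.append(TagCluster(chrom, strand, pos_chunk, cnt_chunk))
    return clusters


def interquantile_boundaries(
    cluster: TagCluster, q_low: float = 0.1, q_high: float = 0.9
) -> tuple[int, int, int]:
    """Positions where cumulative signal crosses q_low/q_high of the total.

    Each boundary is the smallest position whose cumulative count reaches
    the quantile threshold; the returned width is inclusive
    (end - start + 1).  Boundaries are stored on the cluster.
    """
    if cluster.positions.size == 0:
        raise ValueError("empty cluster")
    cum = np.cumsum(cluster.counts)
    total = cum[-1]
    lo_idx = int(np.searchsorted(cum, q_low * total, side="left"))
    hi_idx = int(np.searchsorted(cum, q_high * total, side="left"))
    q_low_pos = int(cluster.positions[lo_idx])
    q_high_pos = int(cluster.positions[hi_idx])
    cluster.q_low_pos, cluster.q_high_pos = q_low_pos, q_high_pos
    return q_low_pos, q_high_pos, q_high_pos - q_low_pos + 1


def aggregate_clusters(
    replicate_clusters: list[list[TagCluster]],
    tpm_min: float = 0.5,
    maxdist: int = 100,
    q_low: float = 0.1,
    q_high: float = 0.9,
) -> list[ConsensusCluster]:
    """Merge per-replicate tag clusters into consensus clusters.

    Clusters below ``tpm_min`` TPM in every replicate are dropped.
    Surviving same-chromosome, same-strand clusters whose central
    (interquantile) regions lie within ``maxdist`` bp merge into one
    consensus cluster whose span is the union of the central regions.
    Per-position signal is summed across replicates inside the span, the
    quantile boundaries are recomputed on the summed signal, and the
    dominant TSS is the position with the highest summed signal (5'-most
    on ties).
    """
    survivors: list[TagCluster] = []
    for clusters in replicate_clusters:
        for c in clusters:
            if c.q_low_pos is None:
                interquantile_boundaries(c, q_low, q_high)
            if c.tpm >= tpm_min:
                survivors.append(c)
    if not survivors:
        return []

    by_key: dict[tuple[str, str], list[TagCluster]] = {}
    for c in survivors:
        by_key.setdefault((c.chrom, c.strand), []).append(c)

    consensus: list[ConsensusCluster] = []
    for (chrom, strand), group in sorted(by_key.items()):
        group.sort(key=lambda c: c.q_low_pos)
        runs: list[list[TagCluster]] = [[group[0]]]
        run_end = group[0].q_high_pos
        for c in group[1:]:
            if c.q_low_pos - run_end <= maxdist:
                runs[-1].append(c)
                run_end = max(run_end, c.q_high_pos)
            else:
                runs.append([c])
                run_end = c.q_high_pos
        for run in runs:
            start = min(c.q_low_pos for c in run)
            end = max(c.q_high_pos for c in run)
            summed: dict[int, float] = {}
            for c in run:
                inside = (c.positions >= start) & (c.positions <= end)
                for p, v in zip(c.positions[inside], c.counts[inside]):
                    summed[int(p)] = summed.get(int(p), 0.0) + float(v)
            positions = np.array(sorted(summed))
            counts = np.array([summed[p] for p in positions])
            merged = TagCluster(chrom, strand, positions, counts)
            lo, hi, width = interquantile_boundaries(merged, q_low, q_high)
            # ties at the maximum resolve to the 5'-most position
            maxima = positions[counts == counts.max()]
            dom = int(maxima.min() if strand == "+" else maxima.max())
            consensus.append(
                ConsensusCluster(
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    dominant_tss=dom,
                    tpm=float(counts.sum()),
                    interquantile_width=width,
                    positions=positions,
                    counts=counts,
                )
            )
    for i, c in enumerate(consensus):
        c.cluster_id = c.cluster_id or f"cc{i + 1:05d}"
    return consensus


def assign_genes(
    clusters: list[ConsensusCluster],
    annotated_tss: list,
    max_distance: int = 500,
) -> list[ConsensusCluster]:
    """Label each cluster with the nearest same-strand annotated TSS.

    ``annotated_tss`` are coverage.TSSRecord-like objects (chrom, pos,
    name, strand).  Clusters farther than ``max_distance`` bp from every
    annotated TSS stay unassigned.
    """
    by_key: dict[tuple[str, str], list] = {}
    for t in annotated_tss:
        by_key.setdefault((t.chrom, t.strand), []).append(t)
    for c in clusters:
        candidates = by_key.get((c.chrom, c.strand), [])
        best, best_d = None, max_distance + 1
        for t in candidates:
            d = abs(t.pos - c.dominant_tss)
            if d < best_d:
                best, best_d = t, d
        c.gene_id = best.name if best is not None else None
    return clusters


def select_narrow_promoters(
    clusters: list[ConsensusCluster],
    width_max: int = 11,
    single_tss_tpm_min: float = 3.0,
) -> list[ConsensusCluster]:
    """Keep focused promoters: interquantile width < ``width_max`` bp,
    single-TSS clusters additionally need >= ``single_tss_tpm_min`` TPM,
    and only the highest-TPM cluster per gene survives."""
    kept = []
    for c in clusters:
        if c.interquantile_width >= width_max:
            continue
        if c.n_positions == 1 and c.tpm < single_tss_tpm_min:
            continue
        kept.append(c)
    best_per_gene: dict[str, ConsensusCluster] = {}
    out = []
    for c in kept:
        if c.gene_id is None:
            out.append(c)
            continue
        prev = best_per_gene.get(c.gene_id)
        if prev is None or c.tpm > prev.tpm:
            best_per_gene[c.gene_id] = c
    out.extend(best_per_gene.values())
    out.sort(key=lambda c: (c.chrom, c.start, c.strand))
    return out


def clusters_to_frame(clusters: list[ConsensusCluster]) -> pd.DataFrame:
    """Tabular export (BED-like TSV) of consensus clusters."""
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in clusters],
            "start": [c.start for c in clusters],
            "end": [c.end + 1 for c in clusters],  # half-open on export
            "id": [c.cluster_id for c in clusters],
            "tpm": [c.tpm for c in clusters],
            "strand": [c.strand for c in clusters],
            "dominant_tss": [c.dominant_tss for c in clusters],
            "iq_width": [c.interquantile_width for c in clusters],
            "gene_id": [c.gene_id if c.gene_id else "." for c in clusters],
        }
    )
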