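"""Stranded base-resolution stop-base coverage and TSS-anchored profiles.

ChIP-nexus reads mark protein-DNA crosslinks by the position where the
lambda exonuclease stopped: the 5'-most aligned base of each read.  This
module turns deduplicated aligned reads into per-strand, per-base "stop
base" coverage, normalizes to reads per million, pools replicates, and
extracts promoter x offset profile matrices oriented in transcription
sense.

Coordinates are 0-based half-open throughout (BED/bedGraph convention);
TSS-relative offset 0 is the dominant TSS base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ReadRecord",
    "StrandedCoverage",
    "ProfileMatrix",
    "stop_base_coverage",
    "rpm_normalize",
    "pool_replicates",
    "extract_profile_matrix",
    "read_bed6",
    "write_bed6",
]

STRANDS = ("+", "-")


@dataclass(frozen=True)
class ReadRecord:
    """One aligned ChIP-nexus read with its ligation barcodes."""

    chrom: str
    start: int  # 0-based
    end: int  # exclusive
    strand: str
    fixed_barcode: str = ""
    random_barcode: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"read start {self.start} >= end {self.end}")
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")

    @property
    def stop_base(self) -> int:
        """5'-most aligned position: start for + reads, end-1 for - reads."""
        return self.start if self.strand == "+" else self.end - 1


class StrandedCoverage:
    """Sparse per-chromosome, per-strand position -> value maps."""

    def __init__(self) -> None:
        self.data: dict[str, dict[str, dict[int, float]]] = {}

    def _strand_map(self, chrom: str, strand: str) -> dict[int, float]:
        if strand not in STRANDS:
            raise ValueError(f"unknown strand {strand!r}")
        return self.data.setdefault(chrom, {"+": {}, "-": {}})[strand]

    def add(self, chrom: str, strand: str, pos: int, value: float = 1.0) -> None:
        m = self._strand_map(chrom, strand)
        m[pos] = m.get(pos, 0.0) + value

    def get(self, chrom: str, strand: str, pos: int) -> float:
        return self.data.get(chrom, {}).get(strand, {}).get(pos, 0.0)

    @property
    def total_signal(self) -> float:
        return float(
            sum(
                sum(strand_map.values())
                for per_chrom in self.data.values()
                for strand_map in per_chrom.values()
            )
        )

    def scale(self, factor: float) -> "StrandedCoverage":
        out = StrandedCoverage()
        for chrom, per_strand in self.data.items():
            for strand, posmap in per_strand.items():
                for pos, v in posmap.items():
                    out.add(chrom, strand, pos, v * factor)
        return out

    def chroms(self) -> list[str]:
        return sorted(self.data)

    # --- bedGraph I/O (one file per strand, 0-based half-open) ---

    def write_bedgraph(self, path_pos: str | Path, path_neg: str | Path) -> None:
        for strand, path in zip(STRANDS, (path_pos, path_neg)):
            with open(path, "w") as fh:
                for chrom in sorted(self.data):
                    posmap = self.data[chrom][strand]
                    for pos in sorted(posmap):
                        v = posmap[pos]
                        if v != 0.0:
                            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{v:.10g}\n")

    @classmethod
    def read_bedgraph(
        cls, path_pos: str | Path, path_neg: str | Path
    ) -> "StrandedCoverage":
        cov = cls()
        for strand, path in zip(STRANDS, (path_pos, path_neg)):
            with open(path) as fh:
                for line in fh:
                    if not line.strip() or line.startswith(("track", "#")):
                        continue
                    chrom, start, end, value = line.split()[:4]
                    start, end, value = int(start), int(end), float(value)
                    for pos in range(start, end):
                        cov.add(chrom, strand, pos, value)
        return cov


def stop_base_coverage(reads: list[ReadRecord]) -> StrandedCoverage:
    """Deduplicate reads and accumulate stop-base counts per strand.

    Reads sharing (chrom, start, end, strand, fixed barcode, random
    barcode) are PCR duplicates and count once; the surviving read
    contributes one count at its 5'-most aligned position.  Output is
    independent of input order.
    """
    seen: set[tuple] = set()
    cov = StrandedCoverage()
    for r in reads:
        key = (r.chrom, r.start, r.end, r.strand, r.fixed_barcode, r.random_barcode)
        if key in seen:
            continue
        seen.add(key)
        cov.add(r.chrom, r.strand, r.stop_base, 1.0)
    return cov


def rpm_normalize(cov: StrandedCoverage) -> StrandedCoverage:
    """Scale coverage so the grand total over both strands is 10^6."""
    total = cov.total_signal
    if total <= 0:
        raise ValueError("cannot RPM-normalize empty coverage")
    return cov.scale(1e6 / total)


def pool_replicates(covs: list[StrandedCoverage]) -> StrandedCoverage:
    """Per-position mean across RPM-normalized replicates (missing = 0)."""
    if not covs:
        raise ValueError("no replicates to pool")
    n = len(covs)
    out = StrandedCoverage()
    for cov in covs:
        for chrom, per_strand in cov.data.items():
            for strand, posmap in per_strand.items():
                for pos, v in posmap.items():
                    out.add(chrom, strand, pos, v / n)
    return out


@dataclass
class TSSRecord:
    chrom: str
    pos: int  # 0-based TSS base
    name: str
    strand: str
    score: float = 0.0


def read_bed6(path: str | Path) -> list[TSSRecord]:
    """Read TSSs from BED6 (the TSS base is the start of the 1 bp interval)."""
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            f = line.rstrip("\n").split("\t")
            records.append(
                TSSRecord(
                    chrom=f[0],
                    pos=int(f[1]),
                    name=f[3] if len(f) > 3 else ".",
                    strand=f[5] if len(f) > 5 else "+",
                    score=float(f[4]) if len(f) > 4 and f[4] != "." else 0.0,
                )
            )
    return records


def write_bed6(records: list[TSSRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t{r.name}\t{r.score:.10g}\t{r.strand}\n"
            )


@dataclass
class ProfileMatrix:
    """Promoters x TSS-relative offsets, one plane per transcribed strand.

    Minus-strand promoters are already flipped: ``sense_positive`` is the
    strand whose stop bases fall upstream of the crosslink in transcription
    sense, regardless of genomic strand.
    """

    promoter_ids: list[str]
    window_half_width: int
    sense_positive: np.ndarray  # (n_promoters, 2w+1)
    sense_negative: np.ndarray
    out_of_bounds: np.ndarray = field(default=None)  # bool mask, same shape

    def __post_init__(self) -> None:
        if self.sense_positive.shape != self.sense_negative.shape:
            raise ValueError("strand planes differ in shape")
        if self.out_of_bounds is None:
            self.out_of_bounds = np.zeros(self.sense_positive.shape, dtype=bool)

    @property
    def offsets(self) -> np.ndarray:
        w = self.window_half_width
        return np.arange(-w, w + 1)

    def combined(self) -> np.ndarray:
        """Per-position sum of both strand planes."""
        return self.sense_positive + self.sense_negative

    def window_slice(self, lo: int, hi: int) -> slice:
        """Column slice for inclusive offset range [lo, hi]."""
        w = self.window_half_width
        if lo < -w or hi > w:
            raise ValueError(f"offset range [{lo},{hi}] exceeds window +/-{w}")
        return slice(lo + w, hi + w + 1)

    def subset(self, indices: np.ndarray) -> "ProfileMatrix":
        return ProfileMatrix(
            promoter_ids=[self.promoter_ids[i] for i in indices],
            window_half_width=self.window_half_width,
            sense_positive=self.sense_positive[indices],
            sense_negative=self.sense_negative[indices],
            out_of_bounds=self.out_of_bounds[indices],
        )


def extract_profile_matrix(
    cov: StrandedCoverage,
    tss_records: list[TSSRecord],
    w: int,
    chrom_sizes: dict[str, int] | None = None,
) -> ProfileMatrix:
    """Extract TSS-anchored stranded profiles, flipping minus promoters.

    For a + TSS, sense planes read genomic +/- strands at TSS+offset.  For
    a - TSS, offset o reads genomic position TSS-o and the strand planes
    swap, so downstream offsets point in transcription direction.  Offsets
    off the chromosome (when ``chrom_sizes`` is given) are zero-filled and
    flagged in ``out_of_bounds``.
    """
    if w < 1:
        raise ValueError("window half-width must be >= 1")
    width = 2 * w + 1
    n = len(tss_records)
    pos_plane = np.zeros((n, width))
    neg_plane = np.zeros((n, width))
    oob = np.zeros((n, width), dtype=bool)
    ids = []
    for i, rec in enumerate(tss_records):
        if rec.strand not in STRANDS:
            raise ValueError(f"TSS {rec.name} lacks a valid strand")
        ids.append(rec.name)
        for j, off in enumerate(range(-w, w + 1)):
            gpos = rec.pos + off if rec.strand == "+" else rec.pos - off
            if chrom_sizes is not None:
                size = chrom_sizes.get(rec.chrom, None)
                if size is not None and not (0 <= gpos < size):
                    oob[i, j] = True
                    continue
            if rec.strand == "+":
                pos_plane[i, j] = cov.get(rec.chrom, "+", gpos)
                neg_plane[i, j] = cov.get(rec.chrom, "-", gpos)
            else:
                pos_plane[i, j] = cov.get(rec.chrom, "-", gpos)
                neg_plane[i, j] = cov.get(rec.chrom, "+", gpos)
    return ProfileMatrix(
        promoter_ids=ids,
        window_half_width=w,
        sense_positive=pos_plane,
        sense_negative=neg_plane,
        out_of_bounds=oob,
    )
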