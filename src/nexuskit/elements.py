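"""Core promoter element scanning and rule-based promoter typing.

Drosophila core promoters carry short, position-constrained sequence motifs
(TATA box, Initiator, the downstream elements MTE/DPE/PB, the TCT motif of
ribosomal-protein genes, and the housekeeping elements DRE and Ohler 1/6/7).
This module scans TSS-anchored promoter sequences for IUPAC consensus motifs
inside their characteristic TSS-relative windows, derives the four canonical
promoter types (TATA, DPR, TCT, HK) from the hits, and builds position
probability matrices for de novo element recovery.

Coordinate convention: the base at the dominant TSS is offset 0, and a
motif "hits" a window when its *start* offset falls inside the window
(inclusive).  Minus-strand promoters must be reverse-complemented into
sense orientation before scanning.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IUPAC_SETS",
    "ElementSpec",
    "ElementHit",
    "PromoterClassLabel",
    "PWM",
    "load_element_specs",
    "iupac_mismatches",
    "scan_element",
    "classify_promoter",
    "build_pwm",
    "reverse_complement",
]

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: Elements whose presence/absence defines the four promoter types.
CLASS_RULES: dict[str, dict[str, frozenset[str]]] = {
    # TATA and TCT promoters only require their element; no exclusions.
    "TATA": {"require_any": frozenset({"TATA"}), "forbid": frozenset()},
    "TCT": {"require_any": frozenset({"TCT"}), "forbid": frozenset()},
    "DPR": {
        "require_any": frozenset({"MTE", "DPE", "PB"}),
        "forbid": frozenset({"TATA", "TCT", "Ohler1", "Ohler6", "Ohler7", "DRE"}),
    },
    "HK": {
        "require_any": frozenset({"DRE", "Ohler1", "Ohler6", "Ohler7"}),
        "forbid": frozenset({"TATA", "MTE", "DPE", "PB", "TCT"}),
    },
}

#: Exclusive-label priority when a promoter satisfies several type rules.
CLASS_PRIORITY = ("TATA", "TCT", "DPR", "HK")


@dataclass(frozen=True)
class ElementSpec:
    """An IUPAC consensus with its TSS-relative search window.

    ``window_start``/``window_end`` bound the motif *start* offset
    (inclusive); ``max_mismatches`` is the tolerance used when scanning.
    """

    name: str
    consensus: str
    window_start: int
    window_end: int
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        if self.window_start > self.window_end:
            raise ValueError(f"{self.name}: window_start > window_end")
        if not self.consensus:
            raise ValueError(f"{self.name}: empty consensus")
        bad = set(self.consensus) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"{self.name}: invalid IUPAC codes {sorted(bad)}")


@dataclass(frozen=True)
class ElementHit:
    promoter_id: str
    element: str
    start_offset: int
    mismatches: int


@dataclass
class PromoterClassLabel:
    promoter_id: str
    labels: frozenset[str]
    exclusive_label: str


@dataclass
class PWM:
    """Position probability matrix with per-position information content."""

    name: str
    offsets: np.ndarray
    matrix: np.ndarray  # positions x 4, rows sum to 1, column order ACGT
    information_content: np.ndarray = field(init=False)  # bits per position

    def __post_init__(self) -> None:
        p = np.asarray(self.matrix, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log2(p), 0.0)
        self.information_content = 2.0 + plogp.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=list("ACGT"))
        df.insert(0, "offset", self.offsets)
        df["ic_bits"] = self.information_content
        return df


def load_element_specs(
    tata_mismatches: int = 1, path=None
) -> dict[str, ElementSpec]:
    """Load the canonical element table (name, consensus, start/end window).

    By default the TATA box is scanned with up to one mismatch and every
    other element with zero mismatches; pass ``tata_mismatches=0`` for
    enrichment-mode scanning where all elements require an exact match.
    """
    if path is None:
        path = importlib.resources.files("nexuskit.data").joinpath(
            "core_promoter_elements.tsv"
        )
    table = pd.read_csv(path, sep="\t")
    specs = {}
    for _, row in table.iterrows():
        name = str(row["Name"])
        specs[name] = ElementSpec(
            name=name,
            consensus=str(row["Sequence"]),
            window_start=int(row["Start window"]),
            window_end=int(row["End window"]),
            max_mismatches=tata_mismatches if name == "TATA" else 0,
        )
    return specs


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def iupac_mismatches(seq: str, consensus: str) -> int:
    """Count positions of ``seq`` not contained in the consensus IUPAC sets."""
    if len(seq) != len(consensus):
        raise ValueError("sequence and consensus lengths differ")
    n = 0
    for base, code in zip(seq.upper(), consensus.upper()):
        try:
            allowed = IUPAC_SETS[code]
        except KeyError:
            raise ValueError(f"invalid IUPAC code {code!r}") from None
        if base not in allowed:
            if base not in IUPAC_SETS or base in "RYSWKMBDHVN":
                raise ValueError(f"invalid sequence base {base!r}")
            n += 1
    return n


def scan_element(
    promoter_seq: str,
    spec: ElementSpec,
    tss_index: int,
    promoter_id: str = "",
) -> list[ElementHit]:
    """Scan a sense-oriented, TSS-anchored sequence for one element.

    ``tss_index`` is the string index of the TSS base (offset 0).  One hit
    is reported per window start offset with at most ``max_mismatches``
    mismatches; hits are sorted by (mismatches, distance of the start from
    the window center).
    """
    seq = promoter_seq.upper()
    m = len(spec.consensus)
    lo, hi = spec.window_start, spec.window_end
    if tss_index + lo < 0 or tss_index + hi + m > len(seq):
        raise ValueError(
            f"{spec.name}: window [{lo},{hi}] (+{m} bp motif) outside sequence"
        )
    center = (lo + hi) / 2.0
    hits = []
    for off in range(lo, hi + 1):
        i = tss_index + off
        mm = iupac_mismatches(seq[i : i + m], spec.consensus)
        if mm <= spec.max_mismatches:
            hits.append(ElementHit(promoter_id, spec.name, off, mm))
    hits.sort(key=lambda h: (h.mismatches, abs(h.start_offset - center)))
    return hits


def scan_all_elements(
    promoter_seq: str,
    tss_index: int,
    specs: dict[str, ElementSpec] | None = None,
    promoter_id: str = "",
) -> list[ElementHit]:
    """Scan one promoter for every element in the spec table."""
    if specs is None:
        specs = load_element_specs()
    hits: list[ElementHit] = []
    for spec in specs.values():
        hits.extend(scan_element(promoter_seq, spec, tss_index, promoter_id))
    return hits


def classify_promoter(
    hits: list[ElementHit], promoter_id: str = ""
) -> PromoterClassLabel:
    """Assign promoter-type labels from element hits.

    TATA and TCT promoters only require their element and are not excluded
    for carrying others.  DPR promoters need at least one of MTE/DPE/PB and
    none of TATA, TCT, Ohler1/6/7 or DRE; housekeeping promoters need at
    least one of DRE/Ohler1/6/7 and none of TATA, MTE, DPE, PB or TCT.
    The exclusive label resolves multi-label promoters by the priority
    TATA > TCT > DPR > HK.
    """
    present = {h.element for h in hits}
    if not promoter_id and hits:
        promoter_id = hits[0].promoter_id
    labels = set()
    for cls, rule in CLASS_RULES.items():
        if present & rule["require_any"] and not (present & rule["forbid"]):
            labels.add(cls)
    exclusive = "unclassified"
    for cls in CLASS_PRIORITY:
        if cls in labels:
            exclusive = cls
            break
    return PromoterClassLabel(promoter_id, frozenset(labels), exclusive)


def build_pwm(
    sequences: list[str],
    tss_index: int,
    region: tuple[int, int],
    name: str = "region",
) -> PWM:
    """Base frequencies (pseudocount 0) of TSS-aligned sequences in a region.

    ``region`` is an inclusive TSS-relative offset range; every sequence
    must cover it.  Information content per position is
    ``2 + sum_b p_b log2 p_b`` bits, with ``0*log(0) := 0``.
    """
    if not sequences:
        raise ValueError("empty sequence set")
    lo, hi = region
    if lo > hi:
        raise ValueError("region start > end")
    width = hi - lo + 1
    counts = np.zeros((width, 4), dtype=float)
    order = {b: i for i, b in enumerate("ACGT")}
    for seq in sequences:
        i0 = tss_index + lo
        if i0 < 0 or tss_index + hi >= len(seq):
            raise ValueError("region outside a sequence")
        for j, base in enumerate(seq.upper()[i0 : i0 + width]):
            if base in order:
                counts[j, order[base]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("a region position has no A/C/G/T observations")
    return PWM(name=name, offsets=np.arange(lo, hi + 1), matrix=counts / totals)
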