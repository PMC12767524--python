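"""Synthetic promoters, footprints, CAGE tags and pausing time courses
with planted ground truth.

Every downstream stage of the pipeline is exercised against data whose
truth is known by construction: promoter sequences carry concrete
expansions of the core-promoter-element consensi planted inside their
canonical TSS-relative windows; stranded stop-base footprints are drawn as
symmetric Gaussian peak pairs around factor-specific contact midpoints
(positive strand upstream, negative strand downstream); CAGE tags are
multinomial around the TSS with a controllable kernel width; and pausing
time courses decay exponentially with per-promoter half-lives.

Each synthetic promoter occupies its own contig with the TSS at the exact
center; about half the promoters are emitted on the minus strand so that
strand flipping is exercised everywhere.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import StrandedCoverage, TSSRecord
from .elements import (
    IUPAC_SETS,
    ElementSpec,
    load_element_specs,
    reverse_complement,
)

__all__ = [
    "SyntheticConfig",
    "PlantedTruth",
    "generate_promoter_sequences",
    "simulate_stranded_footprints",
    "simulate_cage",
    "simulate_pausing_timecourse",
    "DEFAULT_CONTACTS",
    "write_fasta",
]

#: TSS-relative contact midpoints per factor and promoter class.  The TBP
#: geometries follow the observed promoter specificity (sharp upstream
#: contact at TATA promoters, downstream-shifted at DPR promoters, diffuse
#: at HK, low and flat at TCT); the generic TFIID subunit carries the five
#: well-separated promoter contacts used for footprint-recovery checks.
DEFAULT_CONTACTS: dict[str, dict[str, list[int]]] = {
    "TBP": {
        "TATA": [-18],
        "DPR": [32],
        "HK": [-30, -10, 10, 30],
        "TCT": [0],
    },
    "subunit": {cls: [-30, -18, 10, 19, 32] for cls in ("TATA", "DPR", "HK", "TCT")},
    "PolII": {cls: [30] for cls in ("TATA", "DPR", "HK", "TCT")},
}

#: Per-class signal scale applied to reads_per_factor (the TCT class acts
#: as the low-signal archetype for TBP).
FACTOR_CLASS_SCALE: dict[str, dict[str, float]] = {
    "TBP": {"TATA": 1.0, "DPR": 1.0, "HK": 1.0, "TCT": 0.1},
}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic pipeline.

    ``promoter_span`` must be odd so the TSS sits at the exact center of
    each promoter contig; ``strand_offset`` is half the distance between
    the paired strand peaks flanking a contact.
    """

    n_promoters_per_class: int = 100
    promoter_span: int = 601
    classes: tuple[str, ...] = ("TATA", "DPR", "TCT", "HK")
    reads_per_factor: int = 10000
    strand_offset: int = 4
    peak_sd: float = 2.0
    cage_tags_per_promoter: int = 1000
    cage_kernel_sd: float = 1.0
    cage_replicates: int = 2
    background_rate: float = 0.0
    minus_strand_fraction: float = 0.5
    expression_log_sd: float = 0.6
    occupancy_noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_promoters_per_class < 1:
            raise ValueError("n_promoters_per_class must be >= 1")
        if self.peak_sd <= 0:
            raise ValueError("peak_sd must be positive")
        if self.promoter_span % 2 == 0:
            raise ValueError("promoter_span must be odd (TSS at exact center)")
        if not 0 <= self.background_rate <= 1:
            raise ValueError("background_rate must lie in [0, 1]")

    @property
    def tss_index(self) -> int:
        return self.promoter_span // 2


@dataclass
class PlantedTruth:
    promoter_id: str
    class_label: str
    strand: str
    planted_elements: list[tuple[str, int]]  # (element, TSS-relative start)
    contact_positions: dict[str, list[int]] = field(default_factory=dict)
    cage_expression: float = 1.0
    half_life_min: float | None = None


def _rng_for(config: SyntheticConfig, stream: str) -> np.random.Generator:
    """Independent deterministic stream per purpose, derived from the seed."""
    return np.random.default_rng([config.seed, zlib.crc32(stream.encode())])


def _expand_iupac(consensus: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(sorted(IUPAC_SETS[c])) for c in consensus)


#: Planting recipes: elements placed for each promoter class.  "choice"
#: entries pick one element per promoter.
_CLASS_RECIPES: dict[str, list] = {
    "TATA": [("TATA",)],
    "DPR": [("MTE", "DPE", "PB"), ("INR",)],
    "TCT": [("TCT",)],
    "HK": [("DRE", "Ohler1", "Ohler6", "Ohler7")],
}

#: Elements whose accidental presence could change the class call.  The
#: scrub check uses classification-mode tolerances (TATA scanned with one
#: mismatch allowed), so a clean promoter classifies exactly as planted.
_CLASS_DEFINING = (
    "TATA",
    "TCT",
    "MTE",
    "DPE",
    "PB",
    "DRE",
    "Ohler1",
    "Ohler6",
    "Ohler7",
)


def _scrub_forbidden(
    class_label: str, planted: set[str], specs: dict[str, ElementSpec]
) -> list[ElementSpec]:
    allowed = set(planted)
    if class_label == "DPR":
        allowed |= {"MTE", "DPE", "PB"}  # within-DPR elements do not conflict
    if class_label == "HK":
        allowed |= {"DRE", "Ohler1", "Ohler6", "Ohler7"}
    return [specs[e] for e in _CLASS_DEFINING if e not in allowed]


def _count_hits(seq: str, spec: ElementSpec, tss_index: int) -> int:
    from .elements import scan_element

    return len(scan_element(seq, spec, tss_index))


def generate_promoter_sequences(
    config: SyntheticConfig,
    scrubbed: bool = True,
    max_attempts: int = 1000,
) -> tuple[dict[str, str], list[PlantedTruth]]:
    """Generate promoter contigs with planted core promoter elements.

    Returns (sequences, truths): ``sequences`` maps promoter_id to the
    genomic (plus-strand) contig sequence; minus-strand promoters carry
    the planted elements on the minus strand, so the emitted contig is
    the reverse complement of the sense design.  In ``scrubbed`` mode the
    background is re-sampled (up to ``max_attempts`` times) until no
    foreign class-defining element occurs in its window at classification
    tolerance, guaranteeing exact class recovery.
    """
    specs = load_element_specs()
    unknown = [c for c in config.classes if c not in _CLASS_RECIPES]
    if unknown:
        raise ValueError(f"unknown promoter class(es): {unknown}")
    span, tss = config.promoter_span, config.tss_index
    widest = max(
        abs(s.window_start) + len(s.consensus) + abs(s.window_end) for s in specs.values()
    )
    if span < 2 * widest:
        raise ValueError(f"promoter_span {span} too small for element windows")

    rng = _rng_for(config, "sequences")
    bases = np.array(list("ACGT"))
    sequences: dict[str, str] = {}
    truths: list[PlantedTruth] = []
    idx = 0
    for cls in config.classes:
        for _ in range(config.n_promoters_per_class):
            idx += 1
            pid = f"prom_{idx:04d}"
            strand = "-" if rng.random() < config.minus_strand_fraction else "+"
            recipe = _CLASS_RECIPES[cls]
            for attempt in range(max_attempts):
                seq = rng.choice(bases, size=span)
                planted: list[tuple[str, int]] = []
                for options in recipe:
                    name = str(rng.choice(list(options)))
                    spec = specs[name]
                    start = int(
                        rng.integers(spec.window_start, spec.window_end + 1)
                    )
                    motif = _expand_iupac(spec.consensus, rng)
                    i0 = tss + start
                    seq[i0 : i0 + len(motif)] = list(motif)
                    planted.append((name, start))
                sense = "".join(seq)
                if not scrubbed:
                    break
                forbidden = _scrub_forbidden(cls, {n for n, _ in planted}, specs)
                if all(_count_hits(sense, s, tss) == 0 for s in forbidden):
                    break
            else:
                raise RuntimeError(
                    f"could not scrub promoter {pid} ({cls}) in {max_attempts} attempts"
                )
            sequences[pid] = sense if strand == "+" else reverse_complement(sense)
            truths.append(
                PlantedTruth(
                    promoter_id=pid,
                    class_label=cls,
                    strand=strand,
                    planted_elements=planted,
                    cage_expression=1.0,
                )
            )
    # per-promoter factor contacts, expression levels and pausing half-lives
    hl_rng = _rng_for(config, "half_lives")
    expr_rng = _rng_for(config, "expression")
    for t in truths:
        t.contact_positions = {
            f: list(per_class.get(t.class_label, []))
            for f, per_class in DEFAULT_CONTACTS.items()
            if t.class_label in per_class
        }
        t.cage_expression = float(np.exp(expr_rng.normal(0.0, config.expression_log_sd)))
        t.half_life_min = float(np.exp(hl_rng.uniform(np.log(2.0), np.log(120.0))))
    return sequences, truths


def sense_sequence(seq: str, strand: str) -> str:
    """Sense-oriented (transcribed-strand) view of a promoter contig."""
    return seq if strand == "+" else reverse_complement(seq)


def truth_tss_records(
    truths: list[PlantedTruth], config: SyntheticConfig
) -> list[TSSRecord]:
    """BED-style TSS records: each promoter contig carries one TSS at its
    center, on the promoter's strand."""
    return [
        TSSRecord(chrom=t.promoter_id, pos=config.tss_index, name=t.promoter_id, strand=t.strand)
        for t in truths
    ]


def _sense_to_genomic(offset: int, strand: str, tss: int) -> int:
    return tss + offset if strand == "+" else tss - offset


def simulate_stranded_footprints(
    truths: list[PlantedTruth],
    config: SyntheticConfig,
    factor: str,
    signal_scale: dict[str, float] | None = None,
) -> StrandedCoverage:
    """Draw stranded stop-base counts around each planted contact.

    For a contact midpoint m (sense coordinates), positive-strand stops
    are Normal(m - strand_offset, peak_sd) and negative-strand stops
    Normal(m + strand_offset, peak_sd), rounded to integer positions and
    clipped to the contig.  A ``background_rate`` fraction of reads lands
    uniformly on both strands.

    The per-promoter read total is ``reads_per_factor`` scaled by the
    promoter's expression level (occupancy tracks transcriptional output),
    any per-class ``signal_scale``, and a lognormal measurement-noise
    factor of sd ``occupancy_noise_sd`` (ChIP efficiency); the realized
    total is exact given those factors, so with unit expression and zero
    noise it equals ``reads_per_factor`` exactly.
    """
    if signal_scale is None:
        signal_scale = FACTOR_CLASS_SCALE.get(factor, {})
    missing = [t.promoter_id for t in truths if factor not in t.contact_positions]
    if missing:
        raise ValueError(f"factor {factor!r} absent from contact_positions "
                         f"(e.g. {missing[0]})")
    rng = _rng_for(config, f"footprints:{factor}")
    span, tss = config.promoter_span, config.tss_index
    cov = StrandedCoverage()
    for t in truths:
        contacts = t.contact_positions[factor]
        noise = (
            float(np.exp(rng.normal(0.0, config.occupancy_noise_sd)))
            if config.occupancy_noise_sd > 0
            else 1.0
        )
        n_reads = int(
            round(
                config.reads_per_factor
                * t.cage_expression
                * signal_scale.get(t.class_label, 1.0)
                * noise
            )
        )
        n_bg = int(round(config.background_rate * n_reads))
        n_signal = n_reads - n_bg
        if contacts:
            per_contact = np.full(len(contacts), n_signal // len(contacts))
            per_contact[: n_signal % len(contacts)] += 1
        else:
            per_contact = np.array([], dtype=int)
            n_bg = n_reads
        for m, n_c in zip(contacts, per_contact):
            n_pos = n_c // 2 + (n_c % 2)
            n_neg = n_c // 2
            for sense_strand, center, count in (
                ("+", m - config.strand_offset, n_pos),
                ("-", m + config.strand_offset, n_neg),
            ):
                if count == 0:
                    continue
                offs = np.rint(rng.normal(center, config.peak_sd, size=count)).astype(int)
                genomic_strand = sense_strand if t.strand == "+" else ("-" if sense_strand == "+" else "+")
                gpos = tss + offs if t.strand == "+" else tss - offs
                np.clip(gpos, 0, span - 1, out=gpos)
                for p, c in zip(*np.unique(gpos, return_counts=True)):
                    cov.add(t.promoter_id, genomic_strand, int(p), float(c))
        if n_bg:
            gpos = rng.integers(0, span, size=n_bg)
            strands = rng.random(n_bg) < 0.5
            for strand, mask in (("+", strands), ("-", ~strands)):
                for p, c in zip(*np.unique(gpos[mask], return_counts=True)):
                    cov.add(t.promoter_id, strand, int(p), float(c))
    return cov


def simulate_cage(
    truths: list[PlantedTruth], config: SyntheticConfig
) -> list[pd.DataFrame]:
    """Per-replicate CTSS tables (chrom, pos, strand, count), 0-based pos.

    Tags per promoter and replicate equal ``cage_expression *
    cage_tags_per_promoter`` exactly, multinomially spread around the TSS
    with a Gaussian kernel of sd ``cage_kernel_sd`` bp (narrow kernels
    yield interquantile widths below the focused-promoter cutoff).
    """
    for t in truths:
        if t.cage_expression <= 0:
            raise ValueError(f"{t.promoter_id}: cage_expression must be positive")
    span, tss = config.promoter_span, config.tss_index
    tables = []
    for rep in range(config.cage_replicates):
        rng = _rng_for(config, f"cage:rep{rep}")
        rows = []
        for t in truths:
            n_tags = int(round(t.cage_expression * config.cage_tags_per_promoter))
            offs = np.rint(rng.normal(0.0, config.cage_kernel_sd, size=n_tags)).astype(int)
            gpos = np.clip(
                [_sense_to_genomic(int(o), t.strand, tss) for o in offs], 0, span - 1
            )
            pos_vals, counts = np.unique(gpos, return_counts=True)
            for p, c in zip(pos_vals, counts):
                rows.append((t.promoter_id, int(p), t.strand, int(c)))
        tables.append(
            pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count"])
        )
    return tables


def simulate_pausing_timecourse(
    truths: list[PlantedTruth],
    timepoints: list[float],
    config: SyntheticConfig,
    poisson_noise: bool = False,
    factor: str = "PolII",
) -> dict[float, StrandedCoverage]:
    """Pol II coverage per timepoint with exponential decay of the pause.

    Expected signal at time t is s(0) * 2**(-t / half_life) per promoter;
    the t = 0 coverage is a noiseless Gaussian-shaped expected footprint
    (so decay is exact position-wise), optionally Poisson-sampled.
    """
    if 0 not in [float(t) for t in timepoints]:
        raise ValueError("timepoints must include 0")
    for t in truths:
        if t.half_life_min is None or t.half_life_min <= 0:
            raise ValueError(f"{t.promoter_id}: non-positive or missing half-life")
    span, tss = config.promoter_span, config.tss_index
    rng = _rng_for(config, "pausing")
    positions = np.arange(span)
    out: dict[float, StrandedCoverage] = {}

    # expected (deterministic) footprint shape at t = 0 per promoter
    base_profiles: dict[str, dict[str, np.ndarray]] = {}
    for t in truths:
        contacts = t.contact_positions.get(factor, [30])
        per_contact = config.reads_per_factor / max(len(contacts), 1)
        prof = {"+": np.zeros(span), "-": np.zeros(span)}
        for m in contacts:
            for sense_strand, center in (
                ("+", m - config.strand_offset),
                ("-", m + config.strand_offset),
            ):
                gcenter = _sense_to_genomic(center, t.strand, tss)
                genomic_strand = sense_strand if t.strand == "+" else ("-" if sense_strand == "+" else "+")
                density = np.exp(-0.5 * ((positions - gcenter) / config.peak_sd) ** 2)
                density /= density.sum()
                prof[genomic_strand] += 0.5 * per_contact * density
        base_profiles[t.promoter_id] = prof

    for tp in sorted(float(x) for x in timepoints):
        cov = StrandedCoverage()
        for t in truths:
            decay = 2.0 ** (-tp / t.half_life_min)
            for strand in "+-":
                expected = base_profiles[t.promoter_id][strand] * decay
                values = rng.poisson(expected).astype(float) if poisson_noise else expected
                nz = np.nonzero(values)[0]
                for p in nz:
                    cov.add(t.promoter_id, strand, int(p), float(values[p]))
        out[tp] = cov
    return out


def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def truths_to_frame(truths: list[PlantedTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "promoter_id": [t.promoter_id for t in truths],
            "class_label": [t.class_label for t in truths],
            "strand": [t.strand for t in truths],
            "planted_elements": [
                ";".join(f"{n}@{s}" for n, s in t.planted_elements) for t in truths
            ],
            "cage_expression": [t.cage_expression for t in truths],
            "half_life_min": [t.half_life_min for t in truths],
        }
    )
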