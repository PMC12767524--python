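"""End-to-end orchestration of the synthetic footprint analysis pipeline.

Each stage is a pure function of (config, earlier stage outputs on disk):
it writes TSV/bedGraph/FASTA artifacts plus a JSON provenance record
(parameters, seed, output checksums) into its own subdirectory of the
output directory.  Re-running with an identical configuration reproduces
every artifact byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cage import (
    PowerLawParams,
    aggregate_clusters,
    assign_genes,
    cluster_ctss,
    clusters_to_frame,
    interquantile_boundaries,
    powerlaw_normalize,
    select_narrow_promoters,
)
from .clustering import (
    element_enrichment,
    enrichment_to_frame,
    kmeans_profiles,
    profile_features,
    rank_transform,
    select_top_signal,
)
from .coverage import (
    StrandedCoverage,
    extract_profile_matrix,
    pool_replicates,
    read_bed6,
    rpm_normalize,
    write_bed6,
)
from .elements import build_pwm, classify_promoter, load_element_specs, scan_all_elements
from .footprints import average_profile, contacts_to_frame, detect_footprint_midpoints
from .occupancy import binding_correlation, cage_normalize, compare_types
from .pausing import (
    assign_quintiles,
    estimates_to_frame,
    fit_half_life,
    pause_window_signal,
    select_paused_promoters,
)
from .synthetic import (
    SyntheticConfig,
    generate_promoter_sequences,
    sense_sequence,
    simulate_cage,
    simulate_pausing_timecourse,
    simulate_stranded_footprints,
    truth_tss_records,
    truths_to_frame,
    write_fasta,
)

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate",
    "coverage",
    "tss",
    "footprints",
    "classify",
    "cluster",
    "occupancy",
    "pausing",
)


@dataclass
class PipelineConfig:
    """Paths, parameters and the root seed for a pipeline run."""

    outdir: Path = Path("pipeline_out")
    seed: int = 0
    synthetic: SyntheticConfig = None
    factors: tuple[str, ...] = ("TBP", "subunit", "PolII")
    profile_half_width: int = 100
    footprint_factor: str = "subunit"
    timepoints: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0, 40.0)
    scrubbed: bool = True

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.synthetic is None:
            self.synthetic = SyntheticConfig(seed=self.seed)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        syn = d.pop("synthetic", None)
        cfg = cls(**{k: v for k, v in d.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if syn is not None:
            cfg.synthetic = SyntheticConfig(**syn)
        cfg.synthetic = dataclasses.replace(cfg.synthetic, seed=cfg.seed)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_provenance(stage_dir: Path, stage: str, params: dict, outputs: list[Path]) -> None:
    record = {
        "stage": stage,
        "version": __version__,
        "parameters": params,
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    (stage_dir / "provenance.json").write_text(json.dumps(record, indent=2, sort_keys=True, default=str) + "\n")


def _stage_dir(config: PipelineConfig, stage: str) -> Path:
    d = config.outdir / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def _load_truth_frame(config: PipelineConfig) -> pd.DataFrame:
    return pd.read_csv(config.outdir / "simulate" / "truth.tsv", sep="\t")


# ---------------------------------------------------------------- stages


def stage_simulate(config: PipelineConfig) -> dict:
    """Generate sequences, truth, footprints, CAGE tags and time courses."""
    d = _stage_dir(config, "simulate")
    syn = config.synthetic
    sequences, truths = generate_promoter_sequences(syn, scrubbed=config.scrubbed)
    outputs = []

    fasta = d / "promoters.fa"
    write_fasta(sequences, fasta)
    outputs.append(fasta)

    tss_bed = d / "tss.bed"
    write_bed6(truth_tss_records(truths, syn), tss_bed)
    outputs.append(tss_bed)

    truth_tsv = d / "truth.tsv"
    truths_to_frame(truths).to_csv(truth_tsv, sep="\t", index=False)
    outputs.append(truth_tsv)

    for factor in config.factors:
        cov = simulate_stranded_footprints(truths, syn, factor)
        p_pos = d / f"{factor}_pos.bedgraph"
        p_neg = d / f"{factor}_neg.bedgraph"
        cov.write_bedgraph(p_pos, p_neg)
        outputs.extend([p_pos, p_neg])

    for rep, table in enumerate(simulate_cage(truths, syn), start=1):
        p = d / f"ctss_rep{rep}.tsv"
        table.to_csv(p, sep="\t", index=False)
        outputs.append(p)

    manifest_rows = []
    timecourse = simulate_pausing_timecourse(truths, list(config.timepoints), syn)
    for tp, cov in timecourse.items():
        p_pos = d / f"polii_t{tp:g}_pos.bedgraph"
        p_neg = d / f"polii_t{tp:g}_neg.bedgraph"
        cov.write_bedgraph(p_pos, p_neg)
        outputs.extend([p_pos, p_neg])
        manifest_rows.append((tp, p_pos.name, p_neg.name))
    manifest = d / "timecourse_manifest.tsv"
    pd.DataFrame(manifest_rows, columns=["timepoint_minutes", "pos_file", "neg_file"]).to_csv(
        manifest, sep="\t", index=False
    )
    outputs.append(manifest)

    _write_provenance(d, "simulate", dataclasses.asdict(syn), outputs)
    return {"truths": truths, "sequences": sequences}


def _load_profile_matrix(config: PipelineConfig, factor: str, normalized: bool = True):
    sim = config.outdir / "simulate"
    cov = StrandedCoverage.read_bedgraph(
        sim / f"{factor}_pos.bedgraph", sim / f"{factor}_neg.bedgraph"
    )
    if normalized:
        cov = rpm_normalize(cov)
    cov = pool_replicates([cov])
    tss = read_bed6(sim / "tss.bed")
    return extract_profile_matrix(cov, tss, config.profile_half_width)


def stage_coverage(config: PipelineConfig) -> dict:
    """RPM-normalize simulated footprints and export TSS-anchored profiles."""
    d = _stage_dir(config, "coverage")
    outputs = []
    matrices = {}
    for factor in config.factors:
        m = _load_profile_matrix(config, factor)
        matrices[factor] = m
        avg = average_profile(m, factor)
        frame = pd.DataFrame(
            {
                "offset": avg.offsets,
                "positive_strand": avg.positive_strand,
                "negative_strand": avg.negative_strand,
            }
        )
        p = d / f"{factor}_average_profile.tsv"
        frame.to_csv(p, sep="\t", index=False, float_format="%.8g")
        outputs.append(p)
    _write_provenance(
        d, "coverage", {"profile_half_width": config.profile_half_width}, outputs
    )
    return {"matrices": matrices}


def stage_tss(config: PipelineConfig) -> dict:
    """CAGE normalization, clustering and narrow-promoter selection."""
    d = _stage_dir(config, "tss")
    sim = config.outdir / "simulate"
    params = PowerLawParams()
    replicate_clusters = []
    rep = 1
    while (sim / f"ctss_rep{rep}.tsv").exists():
        table = pd.read_csv(sim / f"ctss_rep{rep}.tsv", sep="\t")
        try:
            table["tpm"] = powerlaw_normalize(table["count"].to_numpy(), params)
        except ValueError:
            # degenerate synthetic count distributions fall back to raw counts
            table["tpm"] = table["count"].astype(float)
        clusters = []
        for (chrom, strand), grp in table.groupby(["chrom", "strand"]):
            clusters.extend(
                cluster_ctss(grp["pos"].to_numpy(), grp["tpm"].to_numpy(), chrom, strand)
            )
        for c in clusters:
            interquantile_boundaries(c)
        replicate_clusters.append(clusters)
        rep += 1
    consensus = aggregate_clusters(replicate_clusters)
    assign_genes(consensus, read_bed6(sim / "tss.bed"))
    narrow = select_narrow_promoters(consensus)

    outputs = []
    for name, clusters in (("consensus_clusters", consensus), ("narrow_promoters", narrow)):
        p = d / f"{name}.tsv"
        clusters_to_frame(clusters).to_csv(p, sep="\t", index=False, float_format="%.8g")
        outputs.append(p)
    _write_provenance(
        d,
        "tss",
        {"powerlaw": dataclasses.asdict(params), "replicates": rep - 1},
        outputs,
    )
    return {"consensus": consensus, "narrow": narrow}


def stage_footprints(config: PipelineConfig) -> dict:
    """Detect contact midpoints on the averaged footprint profile."""
    d = _stage_dir(config, "footprints")
    m = _load_profile_matrix(config, config.footprint_factor)
    avg = average_profile(m, config.footprint_factor)
    contacts = detect_footprint_midpoints(avg)
    p = d / "contacts.tsv"
    contacts_to_frame(contacts).to_csv(p, sep="\t", index=False, float_format="%.8g")
    _write_provenance(d, "footprints", {"factor": config.footprint_factor}, [p])
    return {"contacts": contacts}


def stage_classify(config: PipelineConfig) -> dict:
    """Scan elements, type promoters and report truth concordance."""
    d = _stage_dir(config, "classify")
    sim = config.outdir / "simulate"
    truth = _load_truth_frame(config)
    sequences = _read_fasta(sim / "promoters.fa")
    specs = load_element_specs()
    tss_index = config.synthetic.tss_index

    rows = []
    pwm_groups: dict[str, list[str]] = {}
    for _, t in truth.iterrows():
        pid = t["promoter_id"]
        sense = sense_sequence(sequences[pid], t["strand"])
        hits = scan_all_elements(sense, tss_index, specs, pid)
        label = classify_promoter(hits, pid)
        rows.append(
            {
                "promoter_id": pid,
                "true_class": t["class_label"],
                "labels": ",".join(sorted(label.labels)) or ".",
                "exclusive_label": label.exclusive_label,
                "concordant": label.exclusive_label == t["class_label"],
            }
        )
        pwm_groups.setdefault(t["class_label"], []).append(sense)

    frame = pd.DataFrame(rows)
    p_labels = d / "promoter_classes.tsv"
    frame.to_csv(p_labels, sep="\t", index=False)
    outputs = [p_labels]

    pwm_frames = []
    for cls, seqs in sorted(pwm_groups.items()):
        for region_name, region in (
            ("upstream", (-40, -20)),
            ("initiator", (-5, 5)),
            ("downstream", (20, 40)),
        ):
            pwm = build_pwm(seqs, tss_index, region, name=f"{cls}_{region_name}")
            pf = pwm.to_frame()
            pf.insert(0, "pwm", pwm.name)
            pwm_frames.append(pf)
    p_pwm = d / "pwms.tsv"
    pd.concat(pwm_frames).to_csv(p_pwm, sep="\t", index=False, float_format="%.8g")
    outputs.append(p_pwm)

    concordance = float(frame["concordant"].mean())
    summary = d / "concordance.json"
    summary.write_text(
        json.dumps({"n": len(frame), "concordance": concordance}, indent=2) + "\n"
    )
    outputs.append(summary)
    _write_provenance(d, "classify", {"scrubbed": config.scrubbed}, outputs)
    return {"classes": frame, "concordance": concordance}


def stage_cluster(config: PipelineConfig) -> dict:
    """Rank-transform TBP profiles, k-means cluster, test element enrichment."""
    d = _stage_dir(config, "cluster")
    sim = config.outdir / "simulate"
    m = _load_profile_matrix(config, "TBP")
    top = select_top_signal(m)
    features = profile_features(top)
    ranked = rank_transform(features, top.promoter_ids)
    result = kmeans_profiles(ranked, seed=config.seed)

    truth = _load_truth_frame(config)
    sequences = _read_fasta(sim / "promoters.fa")
    specs = load_element_specs(tata_mismatches=0)  # enrichment mode: exact match
    tss_index = config.synthetic.tss_index
    presence_rows = {}
    for _, t in truth.iterrows():
        pid = t["promoter_id"]
        sense = sense_sequence(sequences[pid], t["strand"])
        hits = scan_all_elements(sense, tss_index, specs, pid)
        present = {h.element for h in hits}
        presence_rows[pid] = {name: name in present for name in specs}
    presence = pd.DataFrame.from_dict(presence_rows, orient="index")

    assignments = pd.Series(result.assignments, index=result.promoter_ids)
    enrichment = element_enrichment(assignments, presence.loc[result.promoter_ids])

    outputs = []
    p_assign = d / "cluster_assignments.tsv"
    result.to_frame().to_csv(p_assign, sep="\t", index=False)
    outputs.append(p_assign)
    p_enrich = d / "element_enrichment.tsv"
    enrichment_to_frame(enrichment).to_csv(p_enrich, sep="\t", index=False, float_format="%.8g")
    outputs.append(p_enrich)
    p_centroids = d / "centroids.tsv"
    pd.DataFrame(result.centroids).to_csv(p_centroids, sep="\t", index=False, float_format="%.8g")
    outputs.append(p_centroids)
    _write_provenance(d, "cluster", {"k": result.k, "seed": config.seed}, outputs)
    return {"clusters": result, "enrichment": enrichment, "presence": presence}


def stage_occupancy(config: PipelineConfig) -> dict:
    """Transcription-normalized occupancy tests and binding correlations."""
    d = _stage_dir(config, "occupancy")
    sim = config.outdir / "simulate"
    truth = _load_truth_frame(config)
    cage_table = pd.read_csv(sim / "ctss_rep1.tsv", sep="\t")
    cage_scores = cage_table.groupby("chrom")["count"].sum().astype(float)

    outputs = []
    signal_cols = {}
    tests = []
    for factor in config.factors:
        m = _load_profile_matrix(config, factor)
        occ = cage_normalize(m, cage_scores, mode="occupancy")
        occ = occ.merge(
            truth[["promoter_id", "class_label"]], on="promoter_id", how="left"
        )
        res = compare_types(occ, group_col="class_label")
        res.insert(0, "factor", factor)
        tests.append(res)
        signal_cols[factor] = pd.Series(
            occ["raw_signal"].to_numpy(), index=occ["promoter_id"]
        )
    p_tests = d / "type_comparisons.tsv"
    pd.concat(tests).to_csv(p_tests, sep="\t", index=False, float_format="%.8g")
    outputs.append(p_tests)

    signal_table = pd.DataFrame(signal_cols)
    corr = binding_correlation(signal_table)
    p_corr = d / "binding_correlation.tsv"
    pd.DataFrame(corr.r, index=corr.factors, columns=corr.factors).to_csv(
        p_corr, sep="\t", float_format="%.8g"
    )
    outputs.append(p_corr)
    p_newick = d / "binding_dendrogram.nwk"
    p_newick.write_text(corr.to_newick() + "\n")
    outputs.append(p_newick)
    _write_provenance(d, "occupancy", {"factors": list(config.factors)}, outputs)
    return {"tests": pd.concat(tests), "correlation": corr}


def stage_pausing(config: PipelineConfig) -> dict:
    """Select paused promoters, fit half-lives and bin into quintiles."""
    d = _stage_dir(config, "pausing")
    sim = config.outdir / "simulate"
    manifest = pd.read_csv(sim / "timecourse_manifest.tsv", sep="\t")
    tss = read_bed6(sim / "tss.bed")

    matrices = {}
    for _, row in manifest.iterrows():
        cov = StrandedCoverage.read_bedgraph(sim / row["pos_file"], sim / row["neg_file"])
        matrices[float(row["timepoint_minutes"])] = extract_profile_matrix(
            cov, tss, config.profile_half_width
        )
    t0 = matrices[0.0]
    selected = select_paused_promoters(t0)
    passing = [s for s in selected if s.passes_filters]

    estimates = []
    id_to_idx = {pid: i for i, pid in enumerate(t0.promoter_ids)}
    for s in passing:
        i = id_to_idx[s.promoter_id]
        tc = []
        for tp, m in sorted(matrices.items()):
            sig = pause_window_signal(m, s.pause_position)
            tc.append((tp, float(sig[i])))
        estimates.append(fit_half_life(tc, promoter_id=s.promoter_id))
    if len(estimates) >= 5:
        assign_quintiles(estimates)

    p = d / "half_lives.tsv"
    estimates_to_frame(estimates).to_csv(p, sep="\t", index=False, float_format="%.8g")
    _write_provenance(
        d, "pausing", {"n_selected": len(passing), "timepoints": list(config.timepoints)}, [p]
    )
    return {"selected": selected, "estimates": estimates}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "coverage": stage_coverage,
    "tss": stage_tss,
    "footprints": stage_footprints,
    "classify": stage_classify,
    "cluster": stage_cluster,
    "occupancy": stage_occupancy,
    "pausing": stage_pausing,
}


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] = ALL_STAGES) -> dict:
    """Run the requested stages in canonical order; returns stage results.

    Stage inputs must exist on disk (from files or earlier stages in the
    same call); each stage writes its artifacts and a provenance record
    before the next starts, so a failure leaves earlier outputs intact.
    """
    unknown = [s for s in stages if s not in _STAGE_FUNCS]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")
    ordered = [s for s in ALL_STAGES if s in stages]
    needs_simulate = [s for s in ordered if s != "simulate"]
    if needs_simulate and not (
        "simulate" in ordered or (config.outdir / "simulate" / "truth.tsv").exists()
    ):
        raise FileNotFoundError(
            "downstream stages need the simulate outputs; run the simulate stage first"
        )
    results = {}
    for stage in ordered:
        logger.info("running stage %s", stage)
        results[stage] = _STAGE_FUNCS[stage](config)
    return results


def _read_fasta(path: Path) -> dict[str, str]:
    sequences: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        sequences[name] = "".join(chunks)
    return sequences
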