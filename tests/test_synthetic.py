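"""Generator determinism, conservation and round-trip recovery."""

import dataclasses

import numpy as np
import pytest

from nexuskit.cage import (
    aggregate_clusters,
    cluster_ctss,
    interquantile_boundaries,
    select_narrow_promoters,
)
from nexuskit.coverage import extract_profile_matrix, rpm_normalize
from nexuskit.elements import classify_promoter, load_element_specs, scan_all_elements, scan_element
from nexuskit.footprints import average_profile, detect_footprint_midpoints
from nexuskit.pausing import fit_half_life
from nexuskit.synthetic import (
    DEFAULT_CONTACTS,
    PlantedTruth,
    SyntheticConfig,
    generate_promoter_sequences,
    sense_sequence,
    simulate_cage,
    simulate_pausing_timecourse,
    simulate_stranded_footprints,
    truth_tss_records,
)


class TestGeneratePromoterSequences:
    def test_seeded_determinism(self, small_config):
        a = generate_promoter_sequences(small_config)
        b = generate_promoter_sequences(small_config)
        assert a[0] == b[0]
        assert [t.planted_elements for t in a[1]] == [t.planted_elements for t in b[1]]

    def test_planted_starts_inside_canonical_windows(self, small_promoters):
        specs = load_element_specs()
        _, truths = small_promoters
        for t in truths:
            for name, start in t.planted_elements:
                assert specs[name].window_start <= start <= specs[name].window_end

    def test_scrubbed_classification_round_trip(self, small_config, small_promoters):
        sequences, truths = small_promoters
        tss = small_config.tss_index
        for t in truths:
            sense = sense_sequence(sequences[t.promoter_id], t.strand)
            label = classify_promoter(scan_all_elements(sense, tss, promoter_id=t.promoter_id))
            assert label.exclusive_label == t.class_label

    def test_scrubbed_hk_has_no_tata_instance(self, small_config, small_promoters):
        """Exhaustive scan: no TATA hit (even 1-mismatch) in non-TATA classes."""
        sequences, truths = small_promoters
        tata = load_element_specs()["TATA"]
        tss = small_config.tss_index
        for t in truths:
            if t.class_label == "TATA":
                continue
            sense = sense_sequence(sequences[t.promoter_id], t.strand)
            assert scan_element(sense, tata, tss) == []

    def test_both_strands_emitted(self, small_promoters):
        _, truths = small_promoters
        strands = {t.strand for t in truths}
        assert strands == {"+", "-"}

    def test_unknown_class_raises(self):
        with pytest.raises(ValueError):
            generate_promoter_sequences(
                SyntheticConfig(classes=("TATA", "mystery"), n_promoters_per_class=1)
            )

    def test_even_span_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(promoter_span=600)


class TestSimulateStrandedFootprints:
    def test_peak_geometry(self, clean_config, clean_promoters):
        """Contact at m gives a positive peak at m - offset and negative at
        m + offset (checked through profile extraction on plus promoters)."""
        _, truths = clean_promoters
        cfg = dataclasses.replace(clean_config, peak_sd=1e-6)
        cov = simulate_stranded_footprints(truths, cfg, "TBP", signal_scale={})
        tata_plus = [
            t for t in truths if t.class_label == "TATA" and t.strand == "+"
        ]
        m = extract_profile_matrix(cov, truth_tss_records(tata_plus, cfg), w=60)
        avg = average_profile(m)
        assert int(avg.offsets[np.argmax(avg.positive_strand)]) == -18 - 4
        assert int(avg.offsets[np.argmax(avg.negative_strand)]) == -18 + 4

    def test_conservation_of_read_totals(self, clean_config, clean_promoters):
        _, truths = clean_promoters
        cov = simulate_stranded_footprints(truths, clean_config, "subunit")
        expected = len(truths) * clean_config.reads_per_factor
        assert cov.total_signal == expected

    def test_determinism(self, clean_config, clean_promoters):
        _, truths = clean_promoters
        a = simulate_stranded_footprints(truths, clean_config, "subunit")
        b = simulate_stranded_footprints(truths, clean_config, "subunit")
        assert a.data == b.data

    def test_unknown_factor_raises(self, clean_config, clean_promoters):
        _, truths = clean_promoters
        with pytest.raises(ValueError):
            simulate_stranded_footprints(truths, clean_config, "nonexistent")

    def test_midpoint_round_trip(self, clean_config, clean_promoters):
        """detect_footprint_midpoints recovers all planted contacts +/-1 bp."""
        _, truths = clean_promoters
        cov = rpm_normalize(
            simulate_stranded_footprints(truths, clean_config, "subunit")
        )
        m = extract_profile_matrix(cov, truth_tss_records(truths, clean_config), w=100)
        contacts = detect_footprint_midpoints(average_profile(m, "subunit"))
        found = [c.midpoint for c in contacts if c.paired]
        planted = DEFAULT_CONTACTS["subunit"]["TATA"]
        assert len(found) == len(planted)
        for f, p in zip(sorted(found), sorted(planted)):
            assert abs(f - p) <= 1.0


class TestSimulateCage:
    def test_tag_conservation_and_determinism(self, clean_config, clean_promoters):
        _, truths = clean_promoters
        tables = simulate_cage(truths, clean_config)
        assert len(tables) == clean_config.cage_replicates
        for table in tables:
            assert table["count"].sum() == sum(
                round(t.cage_expression * clean_config.cage_tags_per_promoter)
                for t in truths
            )
        again = simulate_cage(truths, clean_config)
        for a, b in zip(tables, again):
            assert a.equals(b)

    @pytest.mark.parametrize("kernel_sd,narrow_expected", [(1.0, True), (12.0, False)])
    def test_narrow_kernel_controls_interquantile_width(
        self, clean_promoters, clean_config, kernel_sd, narrow_expected
    ):
        """Narrow kernels pass the focused-promoter filter; wide ones fail."""
        _, truths = clean_promoters
        cfg = dataclasses.replace(clean_config, cage_kernel_sd=kernel_sd)
        tables = simulate_cage(truths, cfg)
        replicate_clusters = []
        for table in tables:
            clusters = []
            for (chrom, strand), grp in table.groupby(["chrom", "strand"]):
                clusters.extend(
                    cluster_ctss(
                        grp["pos"].to_numpy(),
                        grp["count"].to_numpy().astype(float),
                        chrom,
                        strand,
                    )
                )
            for c in clusters:
                interquantile_boundaries(c)
            replicate_clusters.append(clusters)
        consensus = aggregate_clusters(replicate_clusters)
        narrow = select_narrow_promoters(consensus)
        frac = len(narrow) / len(truths)
        if narrow_expected:
            assert frac >= 0.95
        else:
            assert frac <= 0.05


class TestSimulatePausingTimecourse:
    def test_noiseless_decay_closed_form(self, clean_config, clean_promoters):
        _, truths = clean_promoters
        sub = truths[:3]
        for t in sub:
            t.half_life_min = 10.0
        courses = simulate_pausing_timecourse(sub, [0, 10, 20], clean_config)
        s = {tp: cov.total_signal for tp, cov in courses.items()}
        assert s[10.0] == pytest.approx(s[0.0] / 2)
        assert s[20.0] == pytest.approx(s[0.0] / 4)

    def test_fit_round_trip_noiseless(self, clean_config, clean_promoters):
        _, truths = clean_promoters
        sub = [dataclasses.replace(t) for t in truths[:4]]
        for i, t in enumerate(sub):
            t.half_life_min = [3.0, 12.0, 30.0, 55.0][i]
        courses = simulate_pausing_timecourse(sub, [0, 5, 10, 20, 40], clean_config)
        recs = truth_tss_records(sub, clean_config)
        for i, t in enumerate(sub):
            tc = []
            for tp, cov in sorted(courses.items()):
                m = extract_profile_matrix(cov, [recs[i]], w=100)
                tc.append((tp, float(m.combined().sum())))
            est = fit_half_life(tc)
            assert est.half_life_min == pytest.approx(t.half_life_min, rel=1e-6)

    def test_long_half_life_floored(self, clean_config, clean_promoters):
        _, truths = clean_promoters
        sub = [dataclasses.replace(truths[0], half_life_min=80.0)]
        courses = simulate_pausing_timecourse(sub, [0, 10, 20, 40], clean_config)
        tc = [(tp, cov.total_signal) for tp, cov in sorted(courses.items())]
        est = fit_half_life(tc)
        assert est.floored and est.half_life_min == 60.0

    def test_missing_zero_timepoint_raises(self, clean_config, clean_promoters):
        _, truths = clean_promoters
        with pytest.raises(ValueError):
            simulate_pausing_timecourse(truths[:1], [5, 10], clean_config)

    def test_nonpositive_half_life_raises(self, clean_config, clean_promoters):
        _, truths = clean_promoters
        bad = [dataclasses.replace(truths[0], half_life_min=-1.0)]
        with pytest.raises(ValueError):
            simulate_pausing_timecourse(bad, [0, 10], clean_config)
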