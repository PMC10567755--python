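"""Determinism and truth-recovery properties of the synthetic generators."""

import numpy as np
import pytest

from splicemotifs.errors import AnnotationError, SpliceMotifsError
from splicemotifs.events import filter_das
from splicemotifs.motifs import count_occurrences, iupac_match
from splicemotifs.simulate import (
    PLANTED_MOTIF_ID,
    build_enrichment_dataset,
    define_cassette_events,
    demo_catalog,
    generate_genome_annotation,
    make_splice_site_annotation,
    plant_motifs,
    simulate_junction_counts,
    simulate_splice_site_reads,
)


class TestGenomeGeneration:
    def test_internal_exon_arithmetic(self):
        _, ann = generate_genome_annotation(10, 3, seed=0)
        assert len(ann.internal_exons()) == 10

    def test_seed_determinism_byte_identical(self, tmp_path):
        from splicemotifs.genome import write_fasta, write_gtf

        for tag in ("a", "b"):
            g, ann = generate_genome_annotation(5, 4, seed=7)
            write_fasta(g, tmp_path / f"{tag}.fa")
            write_gtf(ann, tmp_path / f"{tag}.gtf")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()
        assert (tmp_path / "a.gtf").read_bytes() == (tmp_path / "b.gtf").read_bytes()

    def test_gc_concentration(self):
        g, _ = generate_genome_annotation(
            125, 4, exon_len=500, intron_len=2000, gc=0.5, seed=1
        )
        seq = g.sequence("chr1")
        assert len(seq) >= 1_000_000
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) <= 0.01

    def test_cassette_events_need_internal_exons(self):
        _, ann = generate_genome_annotation(5, 2, seed=0)
        with pytest.raises(AnnotationError):
            define_cassette_events(ann, 1, seed=0)


class TestDemoCatalog:
    def test_twenty_motifs_unique_ids(self):
        cat = demo_catalog()
        assert len(cat) == 20
        assert len({m.motif_id for m in cat}) == 20

    def test_non_planted_motifs_never_match_the_planted_hexamer(self):
        # planting one motif must leave the other 19 combinations null
        cat = demo_catalog()
        planted = cat.get(PLANTED_MOTIF_ID).consensus
        for m in cat:
            if m.motif_id == PLANTED_MOTIF_ID:
                continue
            for i in range(len(planted) - m.length + 1):
                assert not iupac_match(m.consensus, planted[i : i + m.length])

    def test_no_long_end_overlap_with_planted_consensus(self):
        # a motif whose end matches >=3 nt of the planted hexamer's end
        # would be systematically inflated by windows spanning a planted
        # instance and its random flank
        cat = demo_catalog()
        planted = cat.get(PLANTED_MOTIF_ID).consensus
        for m in cat:
            if m.motif_id == PLANTED_MOTIF_ID:
                continue
            for j in range(3, min(m.length, len(planted))):
                assert not iupac_match(m.consensus[-j:], planted[:j]), (m.motif_id, j)
                assert not iupac_match(m.consensus[:j], planted[-j:]), (m.motif_id, j)


class TestPlanting:
    def _dataset(self, multiplier, label, seed):
        return build_enrichment_dataset(
            n_events=80,
            n_background=400,
            rate_multiplier=multiplier,
            target_label=label,
            seed=seed,
        )

    def test_null_multiplier_keeps_rates_equal(self):
        ds = self._dataset(1.0, "3ss1", seed=2)
        counts = ds.truth.realized_counts
        reg = counts["3ss1"] / 80
        bg = counts["3ss"] / ds.truth.background_pool_size
        assert reg == pytest.approx(bg, rel=0.5)  # Poisson noise at ~0.4/region

    def test_excess_rate_realized_in_target(self):
        ds = self._dataset(5.0, "3ss1", seed=3)
        counts = ds.truth.realized_counts
        per_reg = counts["3ss1"] / 80
        per_bg = counts["3ss"] / ds.truth.background_pool_size
        assert per_reg / per_bg == pytest.approx(5.0, rel=0.35)

    def test_deficit_rate_realized_below_background(self):
        ds = self._dataset(0.2, "5ss2", seed=4)
        counts = ds.truth.realized_counts
        assert counts["5ss2"] / 80 < counts["5ss"] / ds.truth.background_pool_size

    def test_planted_occurrences_recoverable_from_sequence(self):
        ds = self._dataset(5.0, "3ss1", seed=5)
        motif = ds.catalog.get(ds.truth.planted_motif_id).consensus
        observed = sum(
            count_occurrences(r.sequence, motif)
            for r in ds.regulated_regions
            if r.label == "3ss1"
        )
        # at least every planted instance is present (natural hits add more)
        assert observed >= ds.truth.realized_counts["3ss1"]

    def test_infeasible_rate_rejected(self):
        g, ann = generate_genome_annotation(3, 3, seed=0)
        events = define_cassette_events(ann, 2, seed=0)
        from splicemotifs.regions import extract_event_regions

        regions = [r for ev in events for r in extract_event_regions(ev, g, 50, 50)]
        cat = demo_catalog()
        with pytest.raises(SpliceMotifsError, match="non-overlapping"):
            plant_motifs(g, regions, cat.get("M01"), "3ss1", 50.0, 50.0, seed=1)


class TestJunctionCounts:
    def _events(self, n, seed=0):
        _, ann = generate_genome_annotation(n, 3, seed=seed)
        return define_cassette_events(ann, n, seed=seed)

    def test_null_dataset_retains_almost_nothing(self):
        events = self._events(200, seed=1)
        simulate_junction_counts(events, 0.5, 0.5, seed=1)
        # BH at 0.05 plus the |dPSI| gate: a few percent survivors at most
        assert len(filter_das(events)) <= 0.05 * len(events)

    def test_strong_effect_passes_filter(self):
        events = self._events(200, seed=2)
        simulate_junction_counts(events, 0.35, 0.65, seed=2)
        assert len(filter_das(events)) >= 0.9 * len(events)

    def test_overdispersion_inflates_psi_variance(self):
        n = 400
        events_bin = self._events(n, seed=3)
        simulate_junction_counts(events_bin, 0.5, 0.5, overdispersion=0.0, seed=3)
        events_bb = self._events(n, seed=3)
        simulate_junction_counts(events_bb, 0.5, 0.5, overdispersion=0.1, seed=4)
        var_bin = np.var([p for ev in events_bin for p in ev.psi_samples(1)])
        var_bb = np.var([p for ev in events_bb for p in ev.psi_samples(1)])
        assert var_bb > 1.5 * var_bin

    def test_truth_covers_every_event(self):
        events = self._events(20, seed=5)
        truth = simulate_junction_counts(events, 0.3, 0.6, seed=5)
        assert set(truth) == {ev.event_id for ev in events}

    def test_invalid_psi_rejected(self):
        events = self._events(5, seed=6)
        with pytest.raises(SpliceMotifsError):
            simulate_junction_counts(events, -0.1, 0.5, seed=0)


class TestSpliceSiteReads:
    def test_extreme_efficiencies(self, tmp_path):
        from splicemotifs.efficiency import (
            compute_efficiencies,
            count_splice_site_reads,
        )

        ann, sites, cl = make_splice_site_annotation(n_sites=10)
        for theta in (0.0, 1.0):
            sam, truth = simulate_splice_site_reads(sites, theta, cl, depth=50, seed=1)
            p = tmp_path / f"t{theta}.sam"
            p.write_text(sam)
            res = {
                r.site_id: r
                for r in compute_efficiencies(count_splice_site_reads(p, ann, k=6))
            }
            for sid in truth:
                assert res[sid].theta == pytest.approx(theta)

    def test_short_read_rejected(self):
        ann, sites, cl = make_splice_site_annotation(n_sites=2)
        with pytest.raises(SpliceMotifsError, match="read_len"):
            simulate_splice_site_reads(sites, 0.5, cl, read_len=10, k=6, seed=0)

    def test_sam_deterministic_per_seed(self):
        ann, sites, cl = make_splice_site_annotation(n_sites=5)
        a, _ = simulate_splice_site_reads(sites, 0.7, cl, depth=30, seed=9)
        b, _ = simulate_splice_site_reads(sites, 0.7, cl, depth=30, seed=9)
        assert a == b


class TestDatasetTruth:
    def test_truth_round_trip(self, tmp_path, small_dataset):
        p = tmp_path / "truth.txt"
        small_dataset.truth.write(p)
        from splicemotifs.simulate import SimulationTruth

        back = SimulationTruth.read(p)
        assert back == small_dataset.truth

    def test_background_distinct_from_event_exons(self, small_dataset):
        from splicemotifs.simulate import event_exon_keys

        keys = event_exon_keys(small_dataset.events)
        for ex in small_dataset.background_exons:
            assert ex.key not in keys
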