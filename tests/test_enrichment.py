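"""Fisher tests, BH adjustment, enrichment calls and RNA-map profiles."""

import math
from fractions import Fraction

import numpy as np
import pytest

from splicemotifs.enrichment import (
    ContingencyTable,
    bh_adjust,
    enrichment_table,
    fisher_one_sided,
    positional_profile,
    run_enrichment,
)
from splicemotifs.errors import SpliceMotifsError
from splicemotifs.motifs import MotifCatalog, MotifRecord
from splicemotifs.regions import SpliceSiteRegion


def oracle_fisher(a, b, c, d, side):
    """Exact hypergeometric tail by enumeration with rational arithmetic."""
    from math import comb

    N, K, n = a + b + c + d, a + c, a + b
    denom = comb(N, n)
    lo, hi = max(0, n + K - N), min(n, K)
    if side == "enriched":
        support = range(a, hi + 1)
    else:
        support = range(lo, a + 1)
    num = sum(comb(K, x) * comb(N - K, n - x) for x in support)
    return Fraction(num, denom)


class TestFisherOneSided:
    def test_hand_enumerated_table(self):
        # [[2,0],[0,2]] right tail: only the observed table, 1/C(4,2)
        t = ContingencyTable(2, 0, 0, 2)
        assert fisher_one_sided(t, "enriched") == pytest.approx(1 / 6, abs=1e-12)

    def test_empty_occurrence_cells(self):
        t = ContingencyTable(0, 10, 0, 10)
        assert fisher_one_sided(t, "enriched") == pytest.approx(1.0)
        assert fisher_one_sided(t, "depleted") == pytest.approx(1.0)

    def test_tail_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 15, size=4)
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            pe = fisher_one_sided(t, "enriched")
            pd_ = fisher_one_sided(t, "depleted")
            # P(X>=a) + P(X<=a) - P(X=a) = 1
            from math import comb

            N, K, n = int(a + b + c + d), int(a + c), int(a + b)
            point = comb(K, int(a)) * comb(N - K, n - int(a)) / comb(N, n)
            assert pe + pd_ - point == pytest.approx(1.0, abs=1e-9)

    def test_negative_cell_rejected(self):
        with pytest.raises(SpliceMotifsError):
            ContingencyTable(-1, 2, 3, 4)

    def test_evidence_monotonicity(self):
        # doubling all cells preserves the odds ratio and sharpens the tail
        t1 = ContingencyTable(20, 180, 10, 190)
        t2 = ContingencyTable(40, 360, 20, 380)
        assert t1.odds_ratio == pytest.approx(t2.odds_ratio)
        assert fisher_one_sided(t2, "enriched") <= fisher_one_sided(t1, "enriched")

    def test_matches_enumeration_oracle_sample(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 11, size=4))
            t = ContingencyTable(a, b, c, d)
            for side in ("enriched", "depleted"):
                assert fisher_one_sided(t, side) == pytest.approx(
                    float(oracle_fisher(a, b, c, d, side)), abs=1e-12
                )


def oracle_bh(pvals):
    """Reference step-up adjustment, written independently."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top, i in enumerate(reversed(order)):
        rank = m - rank_from_top
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBhAdjust:
    def test_hand_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_value(self):
        assert bh_adjust([1.0]) == pytest.approx([1.0])

    def test_adjusted_geq_raw_and_monotone(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(1e-6, 1, size=40)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_reapplication_never_lowers_adjusted_values(self):
        # the step-up map is inflationary: feeding adjusted values back in
        # can only keep or raise them (it is not an idempotent map)
        rng = np.random.default_rng(2)
        p = rng.uniform(1e-6, 1, size=30)
        once = bh_adjust(p)
        twice = bh_adjust(once)
        assert np.all(twice >= once - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(SpliceMotifsError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(SpliceMotifsError):
            bh_adjust([0.5, 1.5])

    def test_matches_reference_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            p = rng.uniform(1e-8, 1, size=int(rng.integers(1, 60)))
            assert bh_adjust(p) == pytest.approx(oracle_bh(p), abs=1e-12)


def _regions_from(seqs, label, boundary=4):
    return [
        SpliceSiteRegion(
            parent_id=f"r{i}",
            label=label,
            contig="c1",
            start=0,
            end=len(s),
            strand="+",
            sequence=s,
            exon_ext=boundary,
            intron_ext=len(s) - boundary,
            boundary_offset=boundary,
        )
        for i, s in enumerate(seqs)
    ]


class TestRunEnrichment:
    def _catalog(self):
        return MotifCatalog(
            [
                MotifRecord("RBP1", "m1", "TGCATG"),
                MotifRecord("RBP2", "m2", "CCCCCC"),
            ]
        )

    def test_identical_sets_all_ns(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(40)]
        reg = _regions_from(seqs, "3ss1")
        bg = _regions_from(seqs, "3ss")
        results = run_enrichment(reg, bg, self._catalog())
        assert results
        for r in results:
            assert r.call == "ns"
            if not math.isnan(r.odds_ratio):
                assert r.odds_ratio == pytest.approx(1.0)

    def test_planted_excess_called_enriched_in_target_only(self, small_dataset):
        ds = small_dataset
        results = run_enrichment(
            ds.regulated_regions, ds.background_regions, ds.catalog
        )
        by_key = {(r.motif_id, r.region): r for r in results}
        planted = ds.truth.planted_motif_id
        assert by_key[(planted, ds.truth.target_label)].call == "enriched"
        for region in ("5ss1", "5ss2", "3ss2"):
            assert by_key[(planted, region)].call == "ns"

    def test_planted_deficit_called_depleted(self):
        from splicemotifs.simulate import build_enrichment_dataset

        ds = build_enrichment_dataset(
            n_events=60,
            n_background=400,
            target_label="5ss2",
            rate_multiplier=0.0,
            background_rate=1.0,
            seed=13,
        )
        results = run_enrichment(
            ds.regulated_regions, ds.background_regions, ds.catalog
        )
        by_key = {(r.motif_id, r.region): r for r in results}
        assert by_key[(ds.truth.planted_motif_id, "5ss2")].call == "depleted"

    def test_presence_model_counts_regions(self):
        seqs_reg = ["TGCATG" + "A" * 20] * 10
        seqs_bg = ["C" * 26] * 10
        reg = _regions_from(seqs_reg, "3ss1")
        bg = _regions_from(seqs_bg, "3ss")
        (r1, _r2) = run_enrichment(reg, bg, self._catalog(), table_model="presence")
        assert (r1.a, r1.b, r1.c, r1.d) == (10, 0, 0, 10)

    def test_oversized_motif_omitted_with_warning(self):
        cat = MotifCatalog([MotifRecord("X", "mX", "A" * 30)])
        reg = _regions_from(["ACGTACGT"] * 3, "3ss1")
        bg = _regions_from(["ACGTACGT"] * 3, "3ss")
        with pytest.warns(UserWarning, match="omitted"):
            assert run_enrichment(reg, bg, cat) == []

    def test_table_written_per_motif_and_region(self, small_dataset):
        ds = small_dataset
        results = run_enrichment(
            ds.regulated_regions, ds.background_regions, ds.catalog
        )
        df = enrichment_table(results)
        assert len(df) == 4 * len(ds.catalog)
        assert set(df["region"]) == {"5ss1", "3ss1", "5ss2", "3ss2"}


class TestPositionalProfile:
    def test_poly_a_saturates(self):
        motif = MotifRecord("X", "m", "AAAA")
        regions = _regions_from(["A" * 20] * 5, "3ss1")
        prof = positional_profile(motif, regions)
        assert np.all(prof.frequency == 1.0)
        assert prof.offsets[0] == -4

    def test_absent_motif_gives_zero_profile(self):
        motif = MotifRecord("X", "m", "GGGG")
        regions = _regions_from(["A" * 20] * 5, "3ss1")
        prof = positional_profile(motif, regions)
        assert np.all(prof.frequency == 0.0)

    def test_single_match_spike_at_offset(self):
        # one match starting 10 nt before the splice site (offset -10)
        seq = "A" * 20
        seq = seq[:2] + "TGCATG" + seq[8:]
        regions = _regions_from([seq], "3ss1", boundary=12)
        prof = positional_profile(MotifRecord("X", "m", "TGCATG"), regions)
        hits = prof.offsets[prof.frequency > 0]
        assert list(hits) == [-10]

    def test_empty_and_mixed_labels_rejected(self):
        motif = MotifRecord("X", "m", "AAAA")
        with pytest.raises(SpliceMotifsError):
            positional_profile(motif, [])
        mixed = _regions_from(["A" * 20], "3ss1") + _regions_from(["A" * 20], "5ss2")
        with pytest.raises(SpliceMotifsError, match="mixed"):
            positional_profile(motif, mixed)
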