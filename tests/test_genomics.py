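"""Interval model, BED-family round trips, consensus peaks and annotation."""

import gzip

import numpy as np
import pytest

from epigerm.genomics import (
    FeatureAnnotation,
    GeneModel,
    GenomicInterval,
    PeakRecord,
    PROMOTER_DOWNSTREAM,
    PROMOTER_UPSTREAM,
    TTS_DOWNSTREAM,
    TTS_UPSTREAM,
    annotate_interval,
    consensus_peaks,
    feature_distribution,
    read_intervals,
    sample_matched_random_regions,
    write_intervals,
)


class TestIntervalModel:
    def test_half_open_bed_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t20\tx\t0\t+\n")
        (iv,) = read_intervals(p, "bed6")
        assert (iv.chrom, iv.start, iv.end, iv.strand, iv.name) == ("chr1", 10, 20, "+", "x")

    @pytest.mark.parametrize("start,end", [(20, 10), (5, 5), (-1, 3)])
    def test_invalid_coordinates_rejected(self, start, end):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", start, end)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t1\t5\nchr1\t20\t10\n")
        with pytest.raises(ValueError, match=":2"):
            read_intervals(p, "bed3")

    def test_tss_is_strand_aware(self, toy_genes):
        by_id = {g.gene_id: g for g in toy_genes}
        assert by_id["g_plus"].tss == 10_000
        assert by_id["g_minus"].tss == 50_000 - 1

    def test_introns_are_exon_complement(self, toy_genes):
        g = next(g for g in toy_genes if g.gene_id == "g_plus")
        assert len(g.introns) == 2
        assert g.introns[0].start == 10_500
        assert all(i.overlap_length(e) == 0 for i in g.introns for e in g.exons)


class TestRoundTrips:
    @pytest.mark.parametrize("dialect,records", [
        ("bed3", [GenomicInterval("chr1", 5, 99), GenomicInterval("chr2", 0, 7)]),
        ("bed6", [GenomicInterval("chr1", 5, 99, "+", "a"),
                  GenomicInterval("chr1", 200, 300, "-", "b")]),
        ("narrowPeak", [PeakRecord(GenomicInterval("chr1", 10, 110, ".", "p1"), 12.5, 40),
                        PeakRecord(GenomicInterval("chr1", 500, 700, ".", "p2"), 3.0)]),
        ("cpg_counts", [("chr1", 10, 12, 3, 1), ("chr1", 40, 42, 0, 10)]),
    ])
    def test_write_read_preserves_records(self, tmp_path, dialect, records):
        p = tmp_path / f"x.{dialect}"
        write_intervals(records, p, dialect)
        assert read_intervals(p, dialect) == records

    def test_bed12_gene_round_trip(self, tmp_path, toy_genes):
        p = tmp_path / "genes.bed12"
        write_intervals(sorted(toy_genes, key=lambda g: g.interval.start), p, "bed12")
        back = read_intervals(p, "bed12")
        for orig, new in zip(sorted(toy_genes, key=lambda g: g.interval.start), back):
            assert new.interval == orig.interval
            assert [(e.start, e.end) for e in new.exons] == \
                   [(e.start, e.end) for e in orig.exons]

    def test_gzip_transparent(self, tmp_path):
        p = tmp_path / "a.bed.gz"
        with gzip.open(p, "wt") as fh:
            fh.write("chr1\t1\t5\n")
        assert read_intervals(p, "bed3") == [GenomicInterval("chr1", 1, 5)]

    def test_narrowpeak_q_from_column_nine(self, tmp_path):
        p = tmp_path / "p.narrowPeak"
        p.write_text("chr1\t10\t110\tp\t0\t.\t5.0\t-1\t12.5\t50\n")
        (pk,) = read_intervals(p, "narrowPeak")
        assert pk.minus_log10_q == 12.5


def _peak(start, end, q):
    return PeakRecord(GenomicInterval("chr1", start, end), q)


class TestConsensusPeaks:
    def test_overlap_and_threshold(self):
        rep_a = [_peak(100, 200, 12), _peak(500, 600, 12)]
        rep_b = [_peak(150, 250, 12)]
        out = consensus_peaks(rep_a, rep_b, 10)
        assert [(p.interval.start, p.interval.end) for p in out] == [(100, 200)]

    def test_threshold_is_strict(self):
        out = consensus_peaks([_peak(100, 200, 10.0)], [_peak(100, 200, 12)], 10)
        assert out == []

    def test_idempotent_on_identical_replicates(self):
        reps = [_peak(100, 200, 12), _peak(500, 600, 11)]
        assert consensus_peaks(reps, reps, 10) == sorted(
            reps, key=lambda p: p.interval.start)

    def test_consensus_subset_of_filtered_first_replicate(self, small_truth):
        from epigerm.synthetic import simulate_peaks
        reps = simulate_peaks(small_truth, replicates=2)
        cons = consensus_peaks(reps["rep1"], reps["rep2"], 10)
        passing_a = {p.interval for p in reps["rep1"] if p.minus_log10_q > 10}
        assert all(p.interval in passing_a for p in cons)
        assert len(cons) <= len(passing_a)


def _brute_annotation(query, genes):
    """Independent pure-Python oracle for nearest gene and category."""
    mid = (query.start + query.end) // 2
    same = [g for g in genes if g.interval.chrom == query.chrom]
    if not same:
        return None, "intergenic"
    best = None
    for g in same:
        d = abs(mid - g.tss)
        if best is None or (d, g.gene_id) < best[:2]:
            best = (d, g.gene_id)
    in_any = lambda windows: any(lo <= mid < hi for lo, hi in windows)
    prom, exon, tts, body = [], [], [], []
    for g in same:
        if g.strand == "+":
            prom.append((g.tss - PROMOTER_UPSTREAM, g.tss + PROMOTER_DOWNSTREAM + 1))
            tts.append((g.tts - TTS_UPSTREAM, g.tts + TTS_DOWNSTREAM + 1))
        else:
            prom.append((g.tss - PROMOTER_DOWNSTREAM, g.tss + PROMOTER_UPSTREAM + 1))
            tts.append((g.tts - TTS_DOWNSTREAM, g.tts + TTS_UPSTREAM + 1))
        exon.extend((e.start, e.end) for e in g.exons)
        body.append((g.interval.start, g.interval.end))
    if in_any(prom):
        cat = "promoter-TSS"
    elif in_any(exon):
        cat = "exon"
    elif in_any(tts):
        cat = "TTS"
    elif in_any(body):
        cat = "intron"
    else:
        cat = "intergenic"
    return best[1], cat


class TestAnnotation:
    def test_midpoint_in_intron(self, toy_genes):
        ann = annotate_interval(GenomicInterval("chr1", 11_000, 11_100), toy_genes)
        assert ann.category == "intron"
        assert ann.nearest_gene_id == "g_plus"

    def test_upstream_of_plus_tss_is_promoter(self, toy_genes):
        ann = annotate_interval(GenomicInterval("chr1", 9_450, 9_550), toy_genes)
        assert ann.category == "promoter-TSS"
        assert ann.signed_distance == -500

    def test_equidistant_tie_broken_lexicographically(self):
        # both TSSs ("+" start) are 3000 bp from the query midpoint at 5000
        genes = [
            GeneModel("gB", "gB", GenomicInterval("chr1", 2_000, 4_000, "+"), "+"),
            GeneModel("gA", "gA", GenomicInterval("chr1", 8_000, 9_000, "+"), "+"),
        ]
        ann = annotate_interval(GenomicInterval("chr1", 4_999, 5_001), genes)
        assert ann.nearest_gene_id == "gA"

    def test_missing_chromosome_flagged_intergenic(self, toy_genes):
        ann = annotate_interval(GenomicInterval("chrX", 100, 200), toy_genes)
        assert ann.category == "intergenic" and ann.flagged
        assert ann.nearest_gene_id is None

    def test_agrees_with_brute_force_on_random_queries(self, small_truth):
        rng = np.random.default_rng(11)
        genes = small_truth.genes
        L = small_truth.chrom_sizes["chr1"]
        for _ in range(1000):
            s = int(rng.integers(0, L - 200))
            q = GenomicInterval("chr1", s, s + int(rng.integers(50, 200)))
            ann = annotate_interval(q, genes)
            gid, cat = _brute_annotation(q, genes)
            assert ann.nearest_gene_id == gid
            assert ann.category == cat


class TestFeatureDistribution:
    def test_percentages(self, toy_genes):
        peaks = [
            _peak(11_000, 11_100, 12),  # intron of g_plus
            _peak(12_200, 12_300, 12),  # intron
            _peak(30_000, 30_100, 12),  # intergenic
            _peak(9_500, 9_600, 12),    # promoter of g_plus
        ]
        dist = feature_distribution(peaks, toy_genes)
        assert dist == {"intron": 50.0, "intergenic": 25.0, "promoter-TSS": 25.0}

    def test_sums_to_100_and_order_invariant(self, small_truth):
        from epigerm.synthetic import simulate_peaks
        peaks = simulate_peaks(small_truth, replicates=1)["rep1"]
        d1 = feature_distribution(peaks, small_truth.genes)
        d2 = feature_distribution(list(reversed(peaks)), small_truth.genes)
        assert d1 == d2
        assert abs(sum(d1.values()) - 100.0) < 0.01

    def test_empty_peaks_is_error(self, toy_genes):
        with pytest.raises(ValueError, match="empty"):
            feature_distribution([], toy_genes)


class TestRandomRegions:
    def test_deterministic_under_seed(self):
        sizes = {"chr1": 100_000}
        template = [GenomicInterval("chr1", 0, 369)]
        a = sample_matched_random_regions(sizes, template, 10, seed=1)
        b = sample_matched_random_regions(sizes, template, 10, seed=1)
        assert a == b

    def test_lengths_matched_to_template(self):
        sizes = {"chr1": 100_000, "chr2": 50_000}
        template = [GenomicInterval("chr1", 0, 369)] * 3
        out = sample_matched_random_regions(sizes, template, 25, seed=2)
        assert all(iv.length == 369 for iv in out)

    def test_unsatisfiable_constraint_errors(self):
        sizes = {"chr1": 10_000}
        template = [GenomicInterval("chr1", 0, 100)]
        with pytest.raises(RuntimeError, match="attempts"):
            sample_matched_random_regions(
                sizes, template, 2, seed=3,
                constraint=lambda iv: False, max_attempts_per_region=50)
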