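"""The simulated world: determinism, planted features, and count models."""

import dataclasses
import hashlib

import numpy as np
import pandas as pd
import pytest

from epigerm.genomics import consensus_peaks, read_intervals
from epigerm.synthetic import (
    DMRT1_MOTIF,
    SimConfig,
    make_genome,
    render_if_images,
    simulate_expression,
    simulate_methylome,
    simulate_peaks,
)


def _genome_md5(truth):
    h = hashlib.md5()
    for chrom in sorted(truth.sequences):
        h.update(truth.sequences[chrom].encode())
    return h.hexdigest()


class TestMakeGenome:
    def test_deterministic_per_seed(self, small_config, small_truth):
        again = make_genome(small_config)
        assert _genome_md5(again) == _genome_md5(small_truth)
        other = make_genome(dataclasses.replace(small_config, seed=8))
        assert _genome_md5(other) != _genome_md5(small_truth)

    def test_motif_embedded_verbatim_at_recorded_coordinates(self, small_truth):
        assert len(small_truth.motif_instances) >= small_truth.config.n_tf_sites
        for m in small_truth.motif_instances:
            seq = small_truth.sequences[m.chrom][m.start:m.end]
            assert seq.upper() == DMRT1_MOTIF

    def test_cpg_count_near_binomial_expectation(self, small_truth):
        cfg = small_truth.config
        n = sum(len(p) for p in small_truth.cpg_positions.values())
        # background draws: Bernoulli(density*2) over L/2 dinucleotide slots,
        # plus a bounded number of forced bound-site CpGs
        expect = cfg.cpg_density * cfg.chrom_length * cfg.n_chrom
        sigma = np.sqrt(expect * (1 - 2 * cfg.cpg_density))
        slack = cfg.n_tf_sites * cfg.site_cpgs
        assert expect - 3 * sigma <= n <= expect + 3 * sigma + slack

    def test_sequence_cpgs_match_registry(self, small_truth):
        seq = small_truth.sequences["chr1"].upper()
        found = set()
        i = seq.find("CG")
        while i != -1:
            found.add(i)
            i = seq.find("CG", i + 1)
        assert found == set(int(p) for p in small_truth.cpg_positions["chr1"])

    def test_planted_dmrs_span_at_least_three_cpgs(self, small_truth):
        pos = small_truth.cpg_positions["chr1"]
        for d in small_truth.planted_dmrs:
            iv = d["interval"]
            n = int(((pos >= iv.start) & (pos < iv.end)).sum())
            assert n >= 3

    def test_emitted_files_parse_with_core_readers(self, small_config, tmp_path):
        truth = make_genome(small_config, outdir=tmp_path)
        genes = read_intervals(tmp_path / "genes.bed12", "bed12")
        assert len(genes) == small_config.n_genes
        reps = read_intervals(tmp_path / "repeats.bed6", "bed6")
        assert len(reps) == 3 * small_config.n_repeat_instances
        sites = read_intervals(tmp_path / "tf_sites.bed6", "bed6")
        assert len(sites) == small_config.n_tf_sites
        from pyfaidx import Fasta
        fa = Fasta(str(tmp_path / "genome.fa"))
        assert len(fa["chr1"]) == small_config.chrom_length

    def test_too_small_genome_errors(self):
        with pytest.raises(ValueError, match="too small"):
            make_genome(SimConfig(n_chrom=1, chrom_length=50_000, n_genes=40))


class TestSimulateMethylome:
    def test_law_of_large_numbers_at_high_coverage(self, small_config, small_truth):
        cfg = dataclasses.replace(small_config, coverage=2000.0)
        counts, _ = simulate_methylome(small_truth, "ES", "5mC", 1, cfg)
        rate = counts["n_mod"] / (counts["n_mod"] + counts["n_unmod"])
        p = small_truth.true_p[("ES", "5mC")]["chr1"]
        assert np.abs(rate.to_numpy() - p).mean() < 0.02

    def test_planted_gain_shifts_region_mean_by_delta(self, small_truth):
        cfg = dataclasses.replace(small_truth.config, coverage=200.0)
        counts, _ = simulate_methylome(small_truth, "committed", "5hmC", 1, cfg)
        rate = counts["n_mod"] / (counts["n_mod"] + counts["n_unmod"])
        pos = counts["pos"].to_numpy()
        in_site = np.zeros(len(pos), dtype=bool)
        for s in small_truth.tf_sites:
            in_site |= (pos >= s.start) & (pos < s.end)
        gain = rate[in_site].mean() - rate[~in_site].mean()
        assert abs(gain - small_truth.config.delta_5hmc) < 0.05

    def test_unknown_stage_errors(self, small_truth):
        with pytest.raises(ValueError, match="stage"):
            simulate_methylome(small_truth, "blastocyst", "5mC", 1)

    def test_deterministic_per_replicate_stream(self, small_truth):
        a, _ = simulate_methylome(small_truth, "ES", "5hmC", 1)
        b, _ = simulate_methylome(small_truth, "ES", "5hmC", 1)
        c, _ = simulate_methylome(small_truth, "ES", "5hmC", 2)
        pd.testing.assert_frame_equal(a, b)
        assert not a["n_mod"].equals(c["n_mod"])


class TestSimulatePeaks:
    def test_zero_false_peaks_gives_exact_consensus_recovery(self, small_truth):
        cfg = dataclasses.replace(small_truth.config, n_false_peaks=0)
        reps = simulate_peaks(small_truth, replicates=2, config=cfg)
        cons = consensus_peaks(reps["rep1"], reps["rep2"], 10)
        assert len(cons) == small_truth.config.n_tf_sites

    def test_replicate_private_false_peaks_excluded(self, small_truth):
        import dataclasses as dc
        cfg_clean = dc.replace(small_truth.config, n_false_peaks=0)
        rep_a = simulate_peaks(small_truth, replicates=1)["rep1"]  # with false peaks
        rep_b = simulate_peaks(small_truth, replicates=1, config=cfg_clean)["rep1"]
        cons = consensus_peaks(rep_a, rep_b, 10)
        names = {p.interval.name for p in cons}
        assert not any(n.startswith("false") for n in names)

    def test_jitter_bounded(self, small_truth):
        reps = simulate_peaks(small_truth, replicates=2)
        sites = {s.name: s for s in small_truth.tf_sites}
        for p in reps["rep1"] + reps["rep2"]:
            if p.interval.name in sites:
                assert abs(p.interval.start - sites[p.interval.name].start) <= \
                    small_truth.config.peak_jitter


class TestSimulateExpression:
    def test_null_config_group_means_close(self, small_config):
        cfg = dataclasses.replace(small_config, n_de_up=0, n_de_down=0,
                                  repeat_log2fc={})
        truth = make_genome(cfg)
        counts = simulate_expression(truth, cfg)
        es = counts[[c for c in counts if c.startswith("ES")]].mean(axis=1)
        com = counts[[c for c in counts if c.startswith("committed")]].mean(axis=1)
        ratio = (com.sum() + 1) / (es.sum() + 1)
        assert 0.9 < ratio < 1.1

    def test_planted_fold_change_recovered_naively(self, small_truth):
        counts = simulate_expression(small_truth)
        up = small_truth.de_log2fc[small_truth.de_log2fc > 0].index
        es = counts.loc[up, [c for c in counts if c.startswith("ES")]].mean(axis=1)
        com = counts.loc[up, [c for c in counts if c.startswith("committed")]].mean(axis=1)
        log2fc = np.log2((com + 1) / (es + 1))
        assert 2.0 <= log2fc.median() <= 4.5  # planted log2FC 3 at 3 reps

    def test_same_seed_identical_matrix(self, small_truth):
        a = simulate_expression(small_truth)
        b = simulate_expression(small_truth)
        pd.testing.assert_frame_equal(a, b)


class TestRenderImages:
    def test_nucleus_count_and_determinism(self, small_truth):
        cfg = dataclasses.replace(small_truth.config, n_nuclei=5,
                                  pixel_noise_sd=0.0)
        stack, table = render_if_images(small_truth, "control", cfg)
        assert stack.shape == (3, cfg.image_size, cfg.image_size)
        assert len(table) == 5
        from scipy import ndimage
        lab, n = ndimage.label(stack[0] > 0)
        assert n == 5
        stack2, table2 = render_if_images(small_truth, "control", cfg)
        assert np.array_equal(stack, stack2)
        pd.testing.assert_frame_equal(table, table2)

    def test_condition_intensity_ratio_in_truth_table(self, small_truth):
        cfg = dataclasses.replace(small_truth.config, nucleus_intensity_cv=0.0)
        _, ctrl = render_if_images(small_truth, "control", cfg)
        _, ind = render_if_images(small_truth, "induced", cfg)
        ratio = ind["true_5hmC"].mean() / ctrl["true_5hmC"].mean()
        assert ratio == pytest.approx(
            cfg.channel_means["induced"]["5hmC"] / cfg.channel_means["control"]["5hmC"])

    def test_impossible_packing_errors(self, small_truth):
        cfg = dataclasses.replace(small_truth.config, image_size=64, n_nuclei=200)
        with pytest.raises(RuntimeError, match="non-overlapping"):
            render_if_images(small_truth, "control", cfg)
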