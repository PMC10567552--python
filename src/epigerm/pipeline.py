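"""End-to-end orchestration: simulate, call, integrate, score.

``run_all`` executes the whole synthetic-world analysis — methylome calling,
tiling, DMR detection, peak consensus and annotation, motif enrichment,
differential expression with gene-set stratification, repeat activation and
per-nucleus image quantification — and returns an :class:`IntegrationReport`
of figure-level summary tables.  ``score_against_truth`` compares the report
with the planted truth.  Runs are fully reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genomics import (
    GenomicInterval,
    annotate_interval,
    consensus_peaks,
    feature_distribution,
    sample_matched_random_regions,
    write_intervals,
)
from .dmr import DMR, DMRConfig, call_dmrs, compare_dmr_sets, peak_dmr_overlap
from .expression import (
    call_degs,
    marker_set_proportions,
    nearest_gene_activation,
    normalize_counts,
    stratified_expression,
)
from .imaging import default_sigmas, quantify_nuclei, scale_normalize, segment_nuclei
from .methylome import call_site_levels, estimate_conversion, region_methylation, tile_methylome
from .motif import Motif, enrich_motifs, scan_motif
from .synthetic import (
    REPEAT_SUBFAMILIES,
    SimConfig,
    SyntheticTruth,
    _rng,
    make_genome,
    render_if_images,
    simulate_expression,
    simulate_methylome,
    simulate_peaks,
)

__all__ = ["IntegrationReport", "run_all", "score_against_truth", "KNOWN_MOTIFS"]

# Known-motif panel for the enrichment tables: the DMRT1 consensus plus two
# standard TF consensus strings as comparators.
KNOWN_MOTIFS = (
    Motif("DMRT1", iupac="TTGAAACACTCTTTT"),
    Motif("SOX17", iupac="AACAATG"),
    Motif("AP1", iupac="TGASTCA"),
)


@dataclass
class IntegrationReport:
    """Figure-level summary tables keyed by name, plus the run manifest."""

    tables: Dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: Dict = field(default_factory=dict)

    def write(self, outdir: Path) -> None:
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t", float_format="%.6g")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True, default=str)


def _config_hash(config: SimConfig) -> str:
    blob = yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:10]


def _log(msg: str) -> None:
    print(f"[epigerm] {msg}", file=sys.stderr)


def _marker_sets(truth: SyntheticTruth) -> Dict[str, set]:
    """Stage marker gene sets for the synthetic world.

    Mitotic-arrest markers are enriched for bound genes (mirroring the
    committed-stage coupling); migratory and mitotic sets are disjoint draws
    from the remainder.
    """
    rng = _rng(truth.config.seed, "markers")
    all_ids = [g.gene_id for g in truth.genes]
    bound = list(truth.intronic_bound_gene_ids)
    n = len(all_ids)
    arrest = set(bound)
    pool = [g for g in all_ids if g not in arrest]
    extra = min(len(pool), max(0, n // 3 - len(arrest)))
    arrest |= set(rng.choice(pool, size=extra, replace=False))
    pool = [g for g in all_ids if g not in arrest]
    n_mig = min(len(pool) // 2, n // 5)
    migratory = set(rng.choice(pool, size=n_mig, replace=False))
    pool = [g for g in pool if g not in migratory]
    mitotic = set(rng.choice(pool, size=min(len(pool), n // 5), replace=False))
    return {"migratory": migratory, "mitotic": mitotic, "mitotic_arrest": arrest}


def run_all(
    config: Optional[SimConfig] = None,
    seed: Optional[int] = None,
    outdir: Optional[Path] = None,
    write_files: bool = True,
) -> Tuple[IntegrationReport, SyntheticTruth]:
    """Run the full synthetic-world analysis and return (report, truth)."""
    config = config or SimConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    run_id = _config_hash(config)
    if outdir is not None:
        outdir = Path(outdir) / f"run-{run_id}"
        outdir.mkdir(parents=True, exist_ok=True)
    report = IntegrationReport()
    report.manifest = {
        "package": "epigerm",
        "version": __version__,
        "seed": config.seed,
        "run_id": run_id,
        "config": dataclasses.asdict(config),
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }

    stage = "synthetic genome"
    try:
        truth = make_genome(config, outdir / "genome" if outdir else None)
        _log(f"genome: {config.n_chrom} chromosomes x {config.chrom_length} bp, "
             f"{sum(len(p) for p in truth.cpg_positions.values())} CpGs, "
             f"{len(truth.tf_sites)} TF-bound sites")

        stage = "methylome"
        tracks: Dict[tuple, object] = {}
        conv_rows = []
        for st in config.stages:
            for modality in ("5mC", "5hmC"):
                for rep in range(1, config.replicates + 1):
                    counts, spike = simulate_methylome(truth, st, modality, rep, config)
                    sample = f"{st}_{modality}_rep{rep}"
                    if outdir is not None:
                        write_intervals(
                            list(counts.itertuples(index=False, name=None)),
                            outdir / f"methylome_{sample}.cpg_counts.tsv", "cpg_counts",
                        )
                    track = call_site_levels(counts, sample_id=sample, stage=st,
                                             modality=modality, replicate=rep)
                    mod_spike = spike[spike["chrom"] == "spike_mod"]
                    unmod_spike = spike[spike["chrom"] == "spike_unmod"]
                    track.conversion_rate = estimate_conversion(mod_spike)
                    conv_rows.append({
                        "sample": sample,
                        "conversion_rate": track.conversion_rate,
                        "false_conversion": estimate_conversion(unmod_spike),
                    })
                    tracks[(st, modality, rep)] = track
        report.tables["conversion_qc"] = pd.DataFrame(conv_rows).set_index("sample")

        stage = "tiling"
        tile_rows = []
        for (st, modality, rep), track in tracks.items():
            _, gmean, _ = tile_methylome(track)
            tile_rows.append({"stage": st, "modality": modality, "replicate": rep,
                              "global_tile_mean": gmean})
        report.tables["global_levels"] = pd.DataFrame(tile_rows)
        _log("global tile means:\n" + report.tables["global_levels"].to_string(index=False))

        stage = "DMR calling"
        dmr_cfg = DMRConfig()
        dmrs: Dict[str, List[DMR]] = {}
        for exp_stage in ("committed", "nascent"):
            for modality in ("5hmC", "5mC"):
                ctrl = [tracks[("ES", modality, r)] for r in range(1, config.replicates + 1)]
                exp = [tracks[(exp_stage, modality, r)] for r in range(1, config.replicates + 1)]
                dmrs[f"{exp_stage}_{modality}"] = call_dmrs(ctrl, exp, dmr_cfg)
        hyper5hmc = [d for d in dmrs["committed_5hmC"] if d.direction == "hyper"]
        hypo5mc = [d for d in dmrs["committed_5mC"] if d.direction == "hypo"]
        _log(f"DMRs committed/ES: {len(hyper5hmc)} hyper-5hmC, {len(hypo5mc)} hypo-5mC")
        venn_rows = []
        for modality in ("5hmC", "5mC"):
            v = compare_dmr_sets(dmrs[f"committed_{modality}"], dmrs[f"nascent_{modality}"])
            venn_rows.append({"modality": modality, **v})
        report.tables["dmr_venn"] = pd.DataFrame(venn_rows).set_index("modality")
        dmr_rows = [
            {"chrom": d.interval.chrom, "start": d.interval.start, "end": d.interval.end,
             "contrast": key, "modality": d.modality, "direction": d.direction,
             "n_cpg": d.n_cpg, "mean_diff": d.mean_diff}
            for key, ds in dmrs.items() for d in ds
        ]
        report.tables["dmrs"] = pd.DataFrame(
            dmr_rows, columns=["chrom", "start", "end", "contrast", "modality",
                               "direction", "n_cpg", "mean_diff"])

        stage = "peak consensus"
        reps = simulate_peaks(truth, replicates=2, config=config)
        consensus = consensus_peaks(reps["rep1"], reps["rep2"], q_threshold=10.0)
        _log(f"consensus peaks: {len(consensus)} (rep1 {len(reps['rep1'])}, "
             f"rep2 {len(reps['rep2'])})")
        if outdir is not None:
            for name, ps in reps.items():
                write_intervals(ps, outdir / f"peaks_{name}.narrowPeak", "narrowPeak")
            write_intervals(consensus, outdir / "peaks_consensus.narrowPeak", "narrowPeak")

        stage = "peak annotation"
        anns = [annotate_interval(p.interval, truth.genes, truth.repeats) for p in consensus]
        fdist = feature_distribution(consensus, truth.genes, truth.repeats) if consensus else {}
        report.tables["feature_distribution"] = pd.DataFrame(
            sorted(fdist.items()), columns=["category", "percent"]).set_index("category")
        target_genes = sorted({a.nearest_gene_id for a in anns if a.nearest_gene_id})

        stage = "peak methylation"
        committed_tracks = [tracks[("committed", "5hmC", r)]
                            for r in range(1, config.replicates + 1)]
        all_5hmc = [tracks[(s, "5hmC", r)] for s in config.stages
                    for r in range(1, config.replicates + 1)]
        peak_ivs = [p.interval for p in consensus]
        if peak_ivs:
            peak_meth = region_methylation(committed_tracks[0], peak_ivs, min_cpg=3,
                                           all_tracks=all_5hmc)
            filtered_peaks = [iv for iv, v in zip(peak_ivs, peak_meth) if not np.isnan(v)]
            rand_regions = sample_matched_random_regions(
                truth.chrom_sizes, peak_ivs, n=len(peak_ivs), seed=config.seed + 1)
            rand_meth = region_methylation(committed_tracks[0], rand_regions, min_cpg=3)
            report.tables["peak_vs_random_5hmc"] = pd.DataFrame({
                "set": ["peaks"] * len(peak_meth) + ["random"] * len(rand_meth),
                "region": list(peak_meth.index) + list(rand_meth.index),
                "mean_5hmc": list(peak_meth) + list(rand_meth),
            })
        else:
            filtered_peaks = []
            report.tables["peak_vs_random_5hmc"] = pd.DataFrame(
                columns=["set", "region", "mean_5hmc"])
        overlap = peak_dmr_overlap(filtered_peaks, hyper5hmc, hypo5mc) if filtered_peaks \
            else {}
        report.tables["peak_dmr_overlap"] = pd.DataFrame(
            sorted(overlap.items()), columns=["class", "percent"]).set_index("class")

        stage = "motif enrichment"
        genome = truth.sequences
        peak_enrich = []
        if peak_ivs:
            bg = sample_matched_random_regions(
                truth.chrom_sizes, peak_ivs, n=2 * len(peak_ivs), seed=config.seed + 2)
            peak_enrich = enrich_motifs(peak_ivs, bg, KNOWN_MOTIFS, genome)
        dmr_targets = [d.interval for d in hyper5hmc]
        dmr_enrich = []
        if dmr_targets:
            dmr_bg = sample_matched_random_regions(
                truth.chrom_sizes, dmr_targets, n=2 * len(dmr_targets),
                seed=config.seed + 3)
            dmr_enrich = enrich_motifs(dmr_targets, dmr_bg, KNOWN_MOTIFS, genome)
        rows = [{"target_set": name, "motif": r.motif_id,
                 "n_target_with": r.n_target_with, "n_target": r.n_target,
                 "n_bg_with": r.n_bg_with, "n_bg": r.n_bg,
                 "fold": r.fold, "p": r.p_value, "fdr": r.fdr}
                for name, rs in (("peaks", peak_enrich), ("hyper5hmC_DMRs", dmr_enrich))
                for r in rs]
        report.tables["motif_enrichment"] = pd.DataFrame(
            rows, columns=["target_set", "motif", "n_target_with", "n_target",
                           "n_bg_with", "n_bg", "fold", "p", "fdr"])

        stage = "expression"
        counts = simulate_expression(truth, config)
        gene_ids = [g.gene_id for g in truth.genes]
        ctrl_cols = [f"ES_rep{r}" for r in range(1, config.expr_replicates + 1)]
        exp_cols = [f"committed_rep{r}" for r in range(1, config.expr_replicates + 1)]
        degs = call_degs(counts.loc[gene_ids], ctrl_cols, exp_cols)
        report.tables["degs"] = degs
        norm_repeats = normalize_counts(counts, "per1e8").loc[list(REPEAT_SUBFAMILIES)]
        report.tables["repeat_expression"] = norm_repeats
        repeat_degs = call_degs(counts, ctrl_cols, exp_cols).loc[list(REPEAT_SUBFAMILIES)]
        _log(f"DE genes: {int((degs['status'] != 'NS').sum())} of {len(degs)}; "
             f"repeat subfamily status: "
             + ", ".join(f"{i}={s}" for i, s in repeat_degs["status"].items()))

        stage = "gene-set integration"
        markers = _marker_sets(truth)
        report.tables["marker_proportions"] = marker_set_proportions(
            set(target_genes), markers)
        # mitotic-arrest targets stratified by intronic hyper-5hmC DMR
        gene_by_id = {g.gene_id: g for g in truth.genes}
        with_dmr, without_dmr = [], []
        for gid in sorted(set(target_genes) & markers["mitotic_arrest"]):
            introns = gene_by_id[gid].introns
            hit = any(d.interval.overlaps(iv) for d in hyper5hmc for iv in introns)
            (with_dmr if hit else without_dmr).append(gid)
        report.tables["stratified_expression"] = stratified_expression(
            {"with_intronic_hyper5hmC": with_dmr, "without": without_dmr},
            degs["log2fc"])

        stage = "repeat activation"
        rep_rows = []
        for subfam in ("LTR12C", "SVA_D"):
            inst = [r.interval for r in truth.repeats if r.subfamily == subfam]
            gene_set, fcs = nearest_gene_activation(inst, truth.genes, degs["log2fc"])
            rep_rows.append({"subfamily": subfam, "n_genes": len(gene_set),
                             "mean_log2fc": float(fcs.mean()) if len(fcs) else np.nan,
                             "median_log2fc": float(fcs.median()) if len(fcs) else np.nan})
        report.tables["repeat_activation"] = pd.DataFrame(rep_rows).set_index("subfamily")

        stage = "target-gene table"
        tg_rows = []
        arrest = markers["mitotic_arrest"]
        for a in anns:
            gid = a.nearest_gene_id
            tg_rows.append({
                "peak": f"{a.query.chrom}:{a.query.start}-{a.query.end}",
                "nearest_gene": gid,
                "tss_distance": a.signed_distance,
                "category": a.category,
                "marker_set": next((k for k, v in markers.items() if gid in v), "none"),
                "de_status": degs.loc[gid, "status"] if gid in degs.index else "NA",
                "overlapping_repeat": a.overlapping_repeat or "none",
            })
        report.tables["target_genes"] = pd.DataFrame(tg_rows)

        stage = "imaging"
        sig_s, sig_l = default_sigmas(sum(config.radius_range))
        nuc_frames = []
        for condition in sorted(config.channel_means):
            stack, img_truth = render_if_images(truth, condition, config)
            labels = segment_nuclei(stack[0], sig_s, sig_l)
            rec = quantify_nuclei(labels, {"5mC": stack[1], "5hmC": stack[2]},
                                  image_id=f"img_{condition}", condition=condition)
            rec["batch"] = "b1"
            nuc_frames.append(rec)
            if outdir is not None:
                import tifffile
                tifffile.imwrite(outdir / f"image_{condition}.tif", stack,
                                 photometric="minisblack")
        nuclei = pd.concat(nuc_frames, ignore_index=True)
        nuclei = scale_normalize(nuclei, ["5mC", "5hmC"], control_condition="control")
        report.tables["nuclei"] = nuclei
        _log(f"nuclei quantified: {len(nuclei)} across {nuclei['condition'].nunique()} "
             "conditions")
    except Exception as exc:
        if outdir is not None:
            report.write(outdir / "partial")
        raise RuntimeError(f"pipeline failed at stage: {stage}: {exc}") from exc

    if outdir is not None and write_files:
        report.write(outdir / "report")
        _log(f"report written to {outdir / 'report'}")
    return report, truth


# ---------------------------------------------------------------------------
# Scoring against planted truth
# ---------------------------------------------------------------------------

def _interval_recovery(called: Sequence[GenomicInterval],
                       planted: Sequence[GenomicInterval]) -> Tuple[float, float]:
    def hit(iv, others):
        return any(iv.overlaps(o) for o in others)
    sens = (sum(hit(p, called) for p in planted) / len(planted)) if planted else np.nan
    prec = (sum(hit(c, planted) for c in called) / len(called)) if called else np.nan
    return sens, prec


def score_against_truth(report: IntegrationReport, truth: SyntheticTruth) -> pd.DataFrame:
    """Recovery metrics for DMRs, DE genes, consensus peaks, nuclei and levels."""
    if report.manifest.get("seed") != truth.config.seed:
        raise ValueError("report and truth come from different runs (seed mismatch)")
    rows = []
    cfg = truth.config

    dmr_df = report.tables["dmrs"]
    for modality, direction in (("5hmC", "hyper"), ("5mC", "hypo")):
        sub = dmr_df[(dmr_df["contrast"] == f"committed_{modality}")
                     & (dmr_df["direction"] == direction)]
        called = [GenomicInterval(r.chrom, int(r.start), int(r.end))
                  for r in sub.itertuples()]
        planted = [d["interval"] for d in truth.planted_dmrs
                   if d["modality"] == modality and d["direction"] == direction]
        sens, prec = _interval_recovery(called, planted)
        rows.append({"metric": f"dmr_{direction}_{modality}_sensitivity", "value": sens})
        rows.append({"metric": f"dmr_{direction}_{modality}_precision", "value": prec})

    degs = report.tables["degs"]
    true_up = set(truth.de_log2fc.index[truth.de_log2fc > 0])
    called_up = set(degs.index[degs["status"] == "up"])
    rows.append({"metric": "de_up_sensitivity",
                 "value": len(true_up & called_up) / len(true_up) if true_up else np.nan})
    rows.append({"metric": "de_up_precision",
                 "value": len(true_up & called_up) / len(called_up) if called_up else np.nan})

    tg = report.tables["target_genes"]
    called_peaks = []
    for s in tg["peak"]:
        chrom, span = s.split(":")
        a, b = span.split("-")
        called_peaks.append(GenomicInterval(chrom, int(a), int(b)))
    sens, prec = _interval_recovery(called_peaks, truth.tf_sites)
    rows.append({"metric": "peak_sensitivity", "value": sens})
    rows.append({"metric": "peak_precision", "value": prec})

    gl = report.tables["global_levels"]
    errs = []
    for r in gl.itertuples():
        target = (cfg.global_5hmc if r.modality == "5hmC" else cfg.global_5mc)[r.stage]
        errs.append(abs(r.global_tile_mean - target))
    rows.append({"metric": "global_level_mae", "value": float(np.mean(errs))})

    nuclei = report.tables["nuclei"]
    n_expected = cfg.n_nuclei * len(cfg.channel_means)
    rows.append({"metric": "nuclei_detected_fraction",
                 "value": len(nuclei) / n_expected})
    means = cfg.channel_means
    true_ratio = means["induced"]["5hmC"] / means["control"]["5hmC"]
    obs = nuclei.groupby("condition")["mean_5hmC"].mean()
    obs_ratio = obs["induced"] / obs["control"]
    rows.append({"metric": "intensity_ratio_error",
                 "value": abs(obs_ratio - true_ratio) / true_ratio})
    return pd.DataFrame(rows).set_index("metric")
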