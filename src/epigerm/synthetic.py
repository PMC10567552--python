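"""Seeded multi-omic toy world with planted ground truth.

Generates a small random genome with registered CpG dinucleotides, gene
models, repeat instances and TF-bound sites carrying an exact binding-motif
instance; then simulates stage-structured beta-binomial 5mC/5hmC methylomes
(with 5hmC gain and 5mC loss planted at bound sites in the committed stage),
replicate peak sets, negative-binomial expression coupled to binding/DMR
status, spike-in conversion controls, and nuclear immunofluorescence images.

Default stage levels are the study-scale ones: global 5hmC 5.5% (ES),
4.2% (nascent), 10.1% (committed); global 5mC ~76-79% across stages.
Everything is deterministic in ``SimConfig.seed``: sub-streams are derived
from the seed plus stable string tags.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .genomics import (
    GeneModel,
    GenomicInterval,
    PeakRecord,
    RepeatElement,
    write_chrom_sizes,
    write_intervals,
)

__all__ = ["SimConfig", "SyntheticTruth", "make_genome", "simulate_methylome",
           "simulate_peaks", "simulate_expression", "render_if_images",
           "DMRT1_MOTIF"]

DMRT1_MOTIF = "TTGAAACACTCTTTT"  # printed DMRT1 consensus within ALR/Alpha

STAGES = ("ES", "nascent", "committed")
REPEAT_SUBFAMILIES = {
    "LTR12C": ("ERV1", "LTR"),
    "SVA_D": ("SVA", "Retroposon"),
    "ALR/Alpha": ("centr", "Satellite"),
}


@dataclass
class SimConfig:
    seed: int = 0
    # genome
    n_chrom: int = 2
    chrom_length: int = 1_000_000
    cpg_density: float = 0.01            # expected CpGs per bp
    n_genes: int = 300
    n_repeat_instances: int = 30         # per subfamily
    n_tf_sites: int = 40
    tf_site_width: int = 300
    site_cpgs: int = 5               # CpGs forced into each bound site
    motif: str = DMRT1_MOTIF
    # methylome
    stages: Tuple[str, ...] = STAGES
    replicates: int = 2
    coverage: float = 30.0
    global_5hmc: Mapping[str, float] = field(
        default_factory=lambda: {"ES": 0.055, "nascent": 0.042, "committed": 0.101}
    )
    global_5mc: Mapping[str, float] = field(
        default_factory=lambda: {"ES": 0.79, "nascent": 0.78, "committed": 0.76}
    )
    beta_concentration: float = 30.0
    delta_5hmc: float = 0.4              # planted gain at bound sites (committed)
    delta_5mc: float = -0.3              # planted loss at bound sites (committed)
    conversion_rate: float = 1.0
    false_conversion: float = 0.005
    n_spikein: int = 200
    # peaks
    peak_jitter: int = 50
    n_false_peaks: int = 10
    q_exp_mean: float = 8.0              # q = 10 + Exponential(mean)
    # expression
    expr_replicates: int = 3
    nb_mean_log: float = float(np.log(200.0))
    nb_mean_sigma: float = 1.0
    nb_dispersion: float = 0.05
    n_de_up: int = 30
    n_de_down: int = 15
    de_log2fc: float = 3.0
    de_coupling: float = 0.8             # fraction of up genes drawn from bound genes
    repeat_log2fc: Mapping[str, float] = field(
        default_factory=lambda: {"LTR12C": 3.0, "SVA_D": 3.0, "ALR/Alpha": 0.0}
    )
    # imaging
    image_size: int = 512
    n_nuclei: int = 25
    radius_range: Tuple[int, int] = (8, 14)
    dapi_intensity: float = 30000.0
    channel_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "control": {"5mC": 8000.0, "5hmC": 2000.0},
            "induced": {"5mC": 4000.0, "5hmC": 4000.0},
        }
    )
    nucleus_intensity_cv: float = 0.05   # between-nucleus variation
    pixel_noise_sd: float = 200.0

    def __post_init__(self) -> None:
        for m in (self.global_5hmc, self.global_5mc):
            if any(not (0 <= v <= 1) for v in m.values()):
                raise ValueError("stage levels must be probabilities")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates")
        if not (0 <= self.conversion_rate <= 1):
            raise ValueError("conversion_rate must be in [0,1]")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "radius_range" in raw:
            raw["radius_range"] = tuple(raw["radius_range"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _rng(seed: int, *tags) -> np.random.Generator:
    """Deterministic sub-stream: seed plus CRC32 of the joined string tags."""
    key = zlib.crc32("/".join(str(t) for t in tags).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


@dataclass
class SyntheticTruth:
    """The planted ground truth; the oracle for every recovery test."""

    config: SimConfig
    chrom_sizes: Dict[str, int]
    sequences: Dict[str, str]
    cpg_positions: Dict[str, np.ndarray]
    genes: List[GeneModel]
    repeats: List[RepeatElement]
    tf_sites: List[GenomicInterval]
    motif_instances: List[GenomicInterval]
    planted_dmrs: List[dict]             # interval, modality, direction, delta
    bound_gene_ids: List[str]
    intronic_bound_gene_ids: List[str]
    de_log2fc: pd.Series                 # per gene, committed vs ES/nascent
    true_p: Dict[Tuple[str, str], Dict[str, np.ndarray]]  # (stage,modality)->chrom->p
    paths: Dict[str, str] = field(default_factory=dict)

    def cpg_index(self) -> Dict[str, Dict[int, int]]:
        return {c: {int(p): i for i, p in enumerate(pos)}
                for c, pos in self.cpg_positions.items()}


def _scrub_cpg(seq: np.ndarray) -> None:
    cg = (seq[:-1] == b"C") & (seq[1:] == b"G")
    seq[1:][cg] = b"A"


def make_genome(config: SimConfig, outdir: Optional[Path] = None) -> SyntheticTruth:
    """Build the genome, annotations and planted truth (optionally on disk).

    The genome carries exact CG dinucleotides only at registered CpG
    positions; each TF-bound site embeds one exact motif instance and at
    least five registered CpGs, so every planted DMR spans >= 3 CpGs.
    """
    L = config.chrom_length
    motif = config.motif.upper()
    if "CG" in motif:
        raise ValueError("motif must not contain CG (would collide with CpG registry)")
    genes_per_chrom = config.n_genes // config.n_chrom
    min_len = genes_per_chrom * 6000 + 10_000
    if L < min_len:
        raise ValueError(f"chrom_length {L} too small for {genes_per_chrom} genes per chrom")

    chrom_sizes = {f"chr{i+1}": L for i in range(config.n_chrom)}
    sequences: Dict[str, np.ndarray] = {}
    cpgs: Dict[str, np.ndarray] = {}
    rng_seq = _rng(config.seed, "genome")
    for chrom in chrom_sizes:
        seq = rng_seq.choice(np.frombuffer(b"ACGT", dtype="S1"), size=L)
        _scrub_cpg(seq)
        even = np.arange(0, L - 2, 2)
        keep = rng_seq.random(len(even)) < config.cpg_density * 2
        cpgs[chrom] = even[keep]
        sequences[chrom] = seq

    # genes: non-overlapping slots, 3 exons each
    rng_gene = _rng(config.seed, "genes")
    genes: List[GeneModel] = []
    gi = 0
    for chrom in chrom_sizes:
        slot = L // genes_per_chrom
        for k in range(genes_per_chrom):
            body_len = int(rng_gene.integers(4000, min(20000, slot - 1000)))
            start = k * slot + int(rng_gene.integers(0, slot - body_len))
            strand = "+" if rng_gene.random() < 0.5 else "-"
            exon_len = 500
            e1 = GenomicInterval(chrom, start, start + exon_len, strand)
            mid = start + body_len // 2
            e2 = GenomicInterval(chrom, mid, mid + exon_len, strand)
            e3 = GenomicInterval(chrom, start + body_len - exon_len, start + body_len, strand)
            gid = f"G{gi:04d}"
            genes.append(
                GeneModel(gid, gid, GenomicInterval(chrom, start, start + body_len, strand),
                          strand, exons=(e1, e2, e3))
            )
            gi += 1

    # repeats: random placements per subfamily
    rng_rep = _rng(config.seed, "repeats")
    repeats: List[RepeatElement] = []
    chrom_list = list(chrom_sizes)
    for subfam, (family, rclass) in REPEAT_SUBFAMILIES.items():
        for _ in range(config.n_repeat_instances):
            chrom = chrom_list[int(rng_rep.integers(len(chrom_list)))]
            length = int(rng_rep.integers(300, 1000))
            start = int(rng_rep.integers(0, L - length))
            repeats.append(
                RepeatElement(GenomicInterval(chrom, start, start + length, ".", subfam),
                              subfam, family, rclass)
            )
    repeats.sort(key=lambda r: (r.interval.chrom, r.interval.start))

    # TF-bound sites: ~70% in introns, rest intergenic; embed the motif and
    # force >= 5 registered CpGs per site outside the motif span
    rng_tf = _rng(config.seed, "tf_sites")
    w = config.tf_site_width
    tf_sites: List[GenomicInterval] = []
    motif_instances: List[GenomicInterval] = []
    bound_gene_ids: List[str] = []
    intronic_bound: List[str] = []
    used: List[Tuple[str, int, int]] = []
    genes_with_introns = [g for g in genes
                          if any(iv.length >= w + 40 for iv in g.introns)]
    n_intronic = int(round(config.n_tf_sites * 0.7))
    attempts = 0
    while len(tf_sites) < config.n_tf_sites and attempts < config.n_tf_sites * 200:
        attempts += 1
        intronic = len(tf_sites) < n_intronic
        if intronic:
            g = genes_with_introns[int(rng_tf.integers(len(genes_with_introns)))]
            intr = [iv for iv in g.introns if iv.length >= w + 40]
            iv0 = intr[int(rng_tf.integers(len(intr)))]
            start = iv0.start + int(rng_tf.integers(0, iv0.length - w))
            chrom = iv0.chrom
        else:
            chrom = chrom_list[int(rng_tf.integers(len(chrom_list)))]
            start = int(rng_tf.integers(0, L - w))
        if any(c == chrom and start < e + 600 and s - 600 < start + w for c, s, e in used):
            continue
        site = GenomicInterval(chrom, start, start + w, ".", f"site{len(tf_sites):03d}")
        used.append((chrom, start, start + w))
        tf_sites.append(site)
        if intronic:
            bound_gene_ids.append(g.gene_id)
            intronic_bound.append(g.gene_id)
    if len(tf_sites) < config.n_tf_sites:
        raise RuntimeError("could not place requested TF sites; enlarge the genome")

    # embed motifs, then rebuild the CpG registry around them
    for site in tf_sites:
        pos = site.start + (w - len(motif)) // 2
        arr = sequences[site.chrom]
        arr[pos:pos + len(motif)] = np.frombuffer(motif.encode(), dtype="S1")
        motif_instances.append(
            GenomicInterval(site.chrom, pos, pos + len(motif), "+", site.name)
        )

    for chrom in chrom_sizes:
        spans = [(m.start - 1, m.end) for m in motif_instances if m.chrom == chrom]
        pos = cpgs[chrom]
        for lo, hi in spans:
            pos = pos[(pos < lo) | (pos >= hi)]
        forced = []
        for site in tf_sites:
            if site.chrom != chrom:
                continue
            mstart = site.start + (w - len(motif)) // 2
            first = site.start + 2 + (site.start % 2)  # keep registry even-spaced
            cand = [p for p in range(first, site.end - 2, 2)
                    if p + 2 <= mstart - 1 or p >= mstart + len(motif)]
            k = config.site_cpgs
            step = max(1, len(cand) // k)
            forced.extend(cand[::step][:k])
        pos = np.unique(np.concatenate([pos, np.array(forced, dtype=pos.dtype)]))
        cpgs[chrom] = pos
        arr = sequences[chrom]
        arr_cg = arr.copy()
        arr_cg[pos] = b"C"
        arr_cg[pos + 1] = b"G"
        sequences[chrom] = arr_cg

    planted_dmrs = []
    if config.delta_5hmc != 0:
        planted_dmrs += [
            {"interval": s, "modality": "5hmC",
             "direction": "hyper" if config.delta_5hmc > 0 else "hypo",
             "delta": config.delta_5hmc}
            for s in tf_sites
        ]
    if config.delta_5mc != 0:
        planted_dmrs += [
            {"interval": s, "modality": "5mC",
             "direction": "hypo" if config.delta_5mc < 0 else "hyper",
             "delta": config.delta_5mc}
            for s in tf_sites
        ]

    # Per-CpG true methylation probabilities per (stage, modality).  Each CpG
    # keeps its rank across stages (a shared Beta quantile models the
    # CpG-intrinsic propensity), so stage contrasts at background CpGs reflect
    # only the global stage shift; planted deltas apply at bound-site CpGs in
    # the committed stage.  The committed background mean is reduced by the
    # planted mass so the genome-wide mean equals the configured global level.
    from scipy.stats import beta as beta_dist

    rng_p = _rng(config.seed, "true_p")
    conc = config.beta_concentration
    true_p: Dict[Tuple[str, str], Dict[str, np.ndarray]] = {}
    site_masks = {
        chrom: _site_mask(cpgs[chrom], [s for s in tf_sites if s.chrom == chrom])
        for chrom in chrom_sizes
    }
    n_total = sum(len(cpgs[c]) for c in chrom_sizes)
    n_planted = sum(int(site_masks[c].sum()) for c in chrom_sizes)
    planted_frac = n_planted / n_total
    for modality, levels, delta in (
        ("5hmC", config.global_5hmc, config.delta_5hmc),
        ("5mC", config.global_5mc, config.delta_5mc),
    ):
        quantiles = {c: rng_p.random(len(cpgs[c])) for c in chrom_sizes}

        def build(mean_bg: float, planted: bool) -> Dict[str, np.ndarray]:
            per_chrom = {}
            for chrom in chrom_sizes:
                p = beta_dist.ppf(quantiles[chrom], mean_bg * conc, (1 - mean_bg) * conc)
                if planted:
                    p = np.where(site_masks[chrom], np.clip(p + delta, 0.0, 1.0), p)
                per_chrom[chrom] = p
            return per_chrom

        for stage in config.stages:
            target = levels[stage]
            if stage != "committed":
                true_p[(stage, modality)] = build(target, planted=False)
                continue
            # calibrate the background so the expected 1-kb tile mean equals
            # the configured genome-wide level despite the planted mass
            mean_bg = target - planted_frac * delta
            per_chrom = build(mean_bg, planted=True)
            for _ in range(2):
                mean_bg -= _expected_tile_mean(cpgs, per_chrom) - target
                mean_bg = float(np.clip(mean_bg, 1e-4, 1 - 1e-4))
                per_chrom = build(mean_bg, planted=True)
            true_p[(stage, modality)] = per_chrom

    # planted differential expression, coupled to binding/DMR status
    rng_de = _rng(config.seed, "de")
    all_ids = [g.gene_id for g in genes]
    bound_unique = sorted(set(intronic_bound))
    n_coupled = min(len(bound_unique), int(round(config.n_de_up * config.de_coupling)))
    up = list(rng_de.choice(bound_unique, size=n_coupled, replace=False))
    pool = [g for g in all_ids if g not in set(up)]
    up += list(rng_de.choice(pool, size=config.n_de_up - n_coupled, replace=False))
    pool = [g for g in all_ids if g not in set(up)]
    down = list(rng_de.choice(pool, size=config.n_de_down, replace=False))
    lfc = pd.Series(0.0, index=all_ids, name="log2fc")
    lfc.loc[up] = config.de_log2fc
    lfc.loc[down] = -config.de_log2fc

    truth = SyntheticTruth(
        config=config,
        chrom_sizes=chrom_sizes,
        sequences={c: s.tobytes().decode() for c, s in sequences.items()},
        cpg_positions=cpgs,
        genes=genes,
        repeats=repeats,
        tf_sites=tf_sites,
        motif_instances=motif_instances,
        planted_dmrs=planted_dmrs,
        bound_gene_ids=sorted(set(bound_gene_ids)),
        intronic_bound_gene_ids=bound_unique,
        de_log2fc=lfc,
        true_p=true_p,
    )
    if outdir is not None:
        _write_genome_files(truth, Path(outdir))
    return truth


def _expected_tile_mean(
    cpg_positions: Mapping[str, np.ndarray],
    p_per_chrom: Mapping[str, np.ndarray],
    tile_size: int = 1000,
    min_cpg: int = 3,
) -> float:
    """Expected global 1-kb tile mean of a true-probability field."""
    tile_means = []
    for chrom, pos in cpg_positions.items():
        tiles = pos // tile_size
        uniq, inverse, counts = np.unique(tiles, return_inverse=True, return_counts=True)
        sums = np.bincount(inverse, weights=p_per_chrom[chrom])
        keep = counts >= min_cpg
        tile_means.append(sums[keep] / counts[keep])
    all_means = np.concatenate(tile_means)
    return float(all_means.mean())


def _site_mask(positions: np.ndarray, sites: Sequence[GenomicInterval]) -> np.ndarray:
    mask = np.zeros(len(positions), dtype=bool)
    for s in sites:
        mask |= (positions >= s.start) & (positions < s.end)
    return mask


def _write_genome_files(truth: SyntheticTruth, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        for chrom, seq in truth.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    write_chrom_sizes(truth.chrom_sizes, outdir / "genome.chrom.sizes")
    write_intervals(truth.genes, outdir / "genes.bed12", "bed12")
    write_intervals([r.interval for r in truth.repeats], outdir / "repeats.bed6", "bed6")
    write_intervals(truth.tf_sites, outdir / "tf_sites.bed6", "bed6")
    write_intervals([m for m in truth.motif_instances], outdir / "motif_instances.bed6", "bed6")
    truth.paths.update(
        fasta=str(fasta),
        chrom_sizes=str(outdir / "genome.chrom.sizes"),
        genes=str(outdir / "genes.bed12"),
        repeats=str(outdir / "repeats.bed6"),
        tf_sites=str(outdir / "tf_sites.bed6"),
    )


def simulate_methylome(
    truth: SyntheticTruth,
    stage: str,
    modality: str,
    replicate: int,
    config: Optional[SimConfig] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Converted-base count table for one sample, plus its spike-in table.

    Per CpG: coverage ~ Poisson(config.coverage) and modified calls ~
    Binomial(coverage, p_true * conversion_rate).  The spike-in table holds
    fully modified controls (read at the conversion rate) and unmodified
    controls (read at the false-conversion rate) on synthetic contigs.
    """
    config = config or truth.config
    if stage not in config.stages:
        raise ValueError(f"unknown stage {stage!r}")
    if (stage, modality) not in truth.true_p:
        raise ValueError(f"unknown modality {modality!r}")
    rng = _rng(config.seed, "methylome", stage, modality, replicate)
    rows = []
    for chrom, pos in truth.cpg_positions.items():
        p = truth.true_p[(stage, modality)][chrom] * config.conversion_rate
        cov = rng.poisson(config.coverage, size=len(pos))
        n_mod = rng.binomial(cov, p)
        rows.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "end": pos + 2,
            "n_mod": n_mod, "n_unmod": cov - n_mod,
        }))
    counts = pd.concat(rows, ignore_index=True)[["chrom", "pos", "end", "n_mod", "n_unmod"]]

    spike_rows = []
    for contig, p_true in (("spike_mod", config.conversion_rate),
                           ("spike_unmod", config.false_conversion)):
        n = config.n_spikein
        cov = rng.poisson(config.coverage, size=n)
        n_mod = rng.binomial(cov, p_true)
        spike_rows.append(pd.DataFrame({
            "chrom": contig, "pos": np.arange(n) * 2, "end": np.arange(n) * 2 + 2,
            "n_mod": n_mod, "n_unmod": cov - n_mod,
        }))
    spike = pd.concat(spike_rows, ignore_index=True)
    return counts, spike


def simulate_peaks(
    truth: SyntheticTruth,
    replicates: int = 2,
    config: Optional[SimConfig] = None,
) -> Dict[str, List[PeakRecord]]:
    """Replicate peak sets: every TF site jittered <= peak_jitter bp with a
    threshold-clearing q, plus replicate-private false peaks."""
    config = config or truth.config
    out: Dict[str, List[PeakRecord]] = {}
    L = config.chrom_length
    chroms = list(truth.chrom_sizes)
    for rep in range(1, replicates + 1):
        rng = _rng(config.seed, "peaks", rep)
        peaks = []
        for site in truth.tf_sites:
            shift = int(rng.integers(-config.peak_jitter, config.peak_jitter + 1))
            start = max(0, site.start + shift)
            q = 10.0 + float(rng.exponential(config.q_exp_mean))
            peaks.append(PeakRecord(
                GenomicInterval(site.chrom, start, start + site.length, ".", site.name),
                minus_log10_q=q, summit_offset=site.length // 2,
                sample_id=f"rep{rep}",
            ))
        for j in range(config.n_false_peaks):
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, L - config.tf_site_width))
            q = 10.0 + float(rng.exponential(config.q_exp_mean))
            peaks.append(PeakRecord(
                GenomicInterval(chrom, start, start + config.tf_site_width, ".",
                                f"false_r{rep}_{j}"),
                minus_log10_q=q, sample_id=f"rep{rep}",
            ))
        out[f"rep{rep}"] = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start))
    return out


def simulate_expression(
    truth: SyntheticTruth,
    config: Optional[SimConfig] = None,
) -> pd.DataFrame:
    """Counts matrix (genes + repeat subfamilies) x (stage x replicate).

    Counts ~ NB(mean, dispersion); the planted log2FC applies in the
    committed stage.  Columns are named ``<stage>_rep<k>``.
    """
    config = config or truth.config
    rng = _rng(config.seed, "expression")
    gene_ids = list(truth.de_log2fc.index)
    base_mean = np.exp(rng.normal(config.nb_mean_log, config.nb_mean_sigma,
                                  size=len(gene_ids)))
    rep_ids = list(REPEAT_SUBFAMILIES)
    rep_lfc = np.array([config.repeat_log2fc.get(r, 0.0) for r in rep_ids])
    rep_mean = np.full(len(rep_ids), np.exp(config.nb_mean_log))
    means = np.concatenate([base_mean, rep_mean])
    lfc = np.concatenate([truth.de_log2fc.to_numpy(), rep_lfc])
    index = gene_ids + rep_ids

    r = 1.0 / config.nb_dispersion
    cols = {}
    for stage in config.stages:
        mu = means * (2.0 ** lfc if stage == "committed" else 1.0)
        for rep in range(1, config.expr_replicates + 1):
            cols[f"{stage}_rep{rep}"] = rng.negative_binomial(r, r / (r + mu))
    return pd.DataFrame(cols, index=index)


def render_if_images(
    truth: SyntheticTruth,
    condition: str,
    config: Optional[SimConfig] = None,
) -> Tuple[np.ndarray, pd.DataFrame]:
    """Render a 3-channel (DAPI, 5mC, 5hmC) uint16 image and a nucleus table.

    Nuclei are non-overlapping softened disks; per-nucleus 5mC/5hmC levels
    are drawn around the condition means with the configured between-nucleus
    CV, and Gaussian pixel noise is added everywhere.
    """
    config = config or truth.config
    if config.n_nuclei < 1:
        raise ValueError("n_nuclei must be >= 1")
    if condition not in config.channel_means:
        raise ValueError(f"unknown condition {condition!r}")
    rng = _rng(config.seed, "images", condition)
    size = config.image_size
    rmin, rmax = config.radius_range
    centers, radii = [], []
    margin = rmax + 2
    attempts = 0
    while len(centers) < config.n_nuclei:
        attempts += 1
        if attempts > config.n_nuclei * 2000:
            raise RuntimeError("cannot place non-overlapping nuclei; reduce n_nuclei")
        r = int(rng.integers(rmin, rmax + 1))
        cy = int(rng.integers(margin, size - margin))
        cx = int(rng.integers(margin, size - margin))
        if all((cy - y) ** 2 + (cx - x) ** 2 > (r + rr + 4) ** 2
               for (y, x), rr in zip(centers, radii)):
            centers.append((cy, cx))
            radii.append(r)

    yy, xx = np.mgrid[0:size, 0:size]
    chans = {"DAPI": np.zeros((size, size)), "5mC": np.zeros((size, size)),
             "5hmC": np.zeros((size, size))}
    means = config.channel_means[condition]
    records = []
    for i, ((cy, cx), r) in enumerate(zip(centers, radii)):
        dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        soft = np.clip(r + 0.5 - dist, 0.0, 1.0)  # anti-aliased edge
        chans["DAPI"] += config.dapi_intensity * soft
        row = {"nucleus": i, "row": cy, "col": cx, "radius": r, "condition": condition}
        for ch in ("5mC", "5hmC"):
            level = float(means[ch] * (1 + config.nucleus_intensity_cv * rng.standard_normal()))
            chans[ch] += level * soft
            row[f"true_{ch}"] = level
        records.append(row)

    stack = []
    for name in ("DAPI", "5mC", "5hmC"):
        img = chans[name] + rng.normal(0.0, config.pixel_noise_sd, size=(size, size))
        stack.append(np.clip(img, 0, 65535).astype(np.uint16))
    return np.stack(stack), pd.DataFrame(records)
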