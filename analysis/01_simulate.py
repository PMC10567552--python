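"""Build the synthetic multi-omic world and record the planted ground truth.

Generates a two-chromosome toy genome with registered CpG sites, gene models,
repeat instances (LTR12C / SVA_D / ALR-Alpha) and 40 DMRT1-bound sites, each
carrying an exact binding-motif instance and a planted committed-stage
5hmC gain / 5mC loss.  Writes the genome files and a truth summary.

Run from the repository root: python analysis/01_simulate.py [seed]
"""

import sys
from pathlib import Path

import pandas as pd

from epigerm.synthetic import SimConfig, make_genome

OUT = Path("results")


def main(seed: int = 0) -> None:
    OUT.mkdir(exist_ok=True)
    cfg = SimConfig(seed=seed)
    truth = make_genome(cfg, outdir=OUT / "genome")
    n_cpg = sum(len(p) for p in truth.cpg_positions.values())
    print(f"genome: {cfg.n_chrom} x {cfg.chrom_length/1e6:.1f} Mb, {n_cpg} CpGs")
    print(f"genes: {len(truth.genes)}; repeats: {len(truth.repeats)}; "
          f"TF-bound sites: {len(truth.tf_sites)} "
          f"({len(truth.intronic_bound_gene_ids)} genes bound in introns)")
    print(f"planted DMRs: {len(truth.planted_dmrs)} "
          f"(5hmC +{cfg.delta_5hmc}, 5mC {cfg.delta_5mc} at bound sites)")
    de = truth.de_log2fc[truth.de_log2fc != 0]
    print(f"planted DE genes: {len(de)} ({int((de > 0).sum())} up, "
          f"{int((de < 0).sum())} down, |log2FC| = {cfg.de_log2fc})")
    pd.DataFrame({
        "gene": de.index, "log2fc": de.to_numpy(),
        "bound": [g in set(truth.intronic_bound_gene_ids) for g in de.index],
    }).to_csv(OUT / "01_planted_de_genes.tsv", sep="\t", index=False)
    rows = [{"chrom": d["interval"].chrom, "start": d["interval"].start,
             "end": d["interval"].end, "modality": d["modality"],
             "direction": d["direction"], "delta": d["delta"]}
            for d in truth.planted_dmrs]
    pd.DataFrame(rows).to_csv(OUT / "01_planted_dmrs.tsv", sep="\t", index=False)
    print(f"genome files and truth tables under {OUT}/")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
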