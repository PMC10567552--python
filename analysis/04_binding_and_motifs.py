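"""TF-binding peaks: replicate consensus, annotation, methylation and motifs.

Filters replicate peak sets at -log10(q) > 10, keeps replicate-common peaks,
annotates them to nearest genes and genomic features, compares peak 5hmC to
length-matched random regions, and runs binomial known-motif enrichment
against a matched random background.  The DMRT1 consensus should dominate
the enrichment table at the peaks and at the hyper-5hmC DMRs.

Run: python analysis/04_binding_and_motifs.py [seed]
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from epigerm.pipeline import run_all

OUT = Path("results")


def main(seed: int = 0) -> None:
    OUT.mkdir(exist_ok=True)
    report, truth = run_all(seed=seed)
    fd = report.tables["feature_distribution"]
    fd.to_csv(OUT / "04_feature_distribution.tsv", sep="\t", float_format="%.6g")
    print("consensus-peak genomic feature distribution (%):")
    print(fd.to_string())

    pv = report.tables["peak_vs_random_5hmc"]
    pv.to_csv(OUT / "04_peak_vs_random_5hmc.tsv", sep="\t", index=False,
              float_format="%.6g")
    means = pv.groupby("set")["mean_5hmc"].mean()
    print(f"\ncommitted 5hmC at peaks {means.get('peaks', float('nan')):.3f} vs "
          f"random regions {means.get('random', float('nan')):.3f}")

    po = report.tables["peak_dmr_overlap"]
    po.to_csv(OUT / "04_peak_dmr_overlap.tsv", sep="\t", float_format="%.6g")
    print("\npeak-DMR overlap classes (%):")
    print(po.to_string())

    me = report.tables["motif_enrichment"]
    me.to_csv(OUT / "04_motif_enrichment.tsv", sep="\t", index=False,
              float_format="%.6g")
    top = me.sort_values("p").groupby("target_set").head(1)
    print("\ntop enriched motif per target set:")
    print(top[["target_set", "motif", "fold", "p"]].to_string(index=False))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
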