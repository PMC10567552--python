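"""Detect differentially methylated regions for committed vs ES cells.

Per-CpG pooled t tests (alpha 0.05), <300-bp gap merging, >= 3 CpGs and
modality-specific mean-difference cutoffs (5mC 0.2, 5hmC 0.05).  Reports the
hyper-5hmC / hypo-5mC DMR counts, their overlap with the planted bound-site
DMRs, and the Venn against the nascent-stage contrast.

Run: python analysis/03_dmr_calling.py [seed]
"""

import sys
from pathlib import Path

import pandas as pd

from epigerm.dmr import DMRConfig, call_dmrs, compare_dmr_sets
from epigerm.methylome import call_site_levels
from epigerm.synthetic import SimConfig, make_genome, simulate_methylome

OUT = Path("results")


def main(seed: int = 0) -> None:
    OUT.mkdir(exist_ok=True)
    cfg = SimConfig(seed=seed)
    truth = make_genome(cfg)

    def tracks(stage, modality):
        out = []
        for rep in range(1, cfg.replicates + 1):
            counts, _ = simulate_methylome(truth, stage, modality, rep, cfg)
            out.append(call_site_levels(counts, stage=stage, modality=modality,
                                        replicate=rep))
        return out

    all_rows = []
    sets = {}
    for contrast in ("committed", "nascent"):
        for modality in ("5hmC", "5mC"):
            dmrs = call_dmrs(tracks("ES", modality), tracks(contrast, modality),
                             DMRConfig())
            sets[(contrast, modality)] = dmrs
            for d in dmrs:
                all_rows.append({"contrast": f"{contrast}_vs_ES",
                                 "chrom": d.interval.chrom,
                                 "start": d.interval.start, "end": d.interval.end,
                                 "modality": modality, "direction": d.direction,
                                 "n_cpg": d.n_cpg, "mean_diff": d.mean_diff})
    df = pd.DataFrame(all_rows)
    df.to_csv(OUT / "03_dmrs.tsv", sep="\t", index=False, float_format="%.6g")

    hyper = [d for d in sets[("committed", "5hmC")] if d.direction == "hyper"]
    hypo = [d for d in sets[("committed", "5mC")] if d.direction == "hypo"]
    print(f"committed vs ES: {len(hyper)} hyper-5hmC, {len(hypo)} hypo-5mC DMRs")
    planted = [d["interval"] for d in truth.planted_dmrs if d["modality"] == "5hmC"]
    rec = sum(any(p.overlaps(d.interval) for d in hyper) for p in planted)
    print(f"planted bound-site 5hmC gains recovered: {rec}/{len(planted)}")
    for modality in ("5hmC", "5mC"):
        v = compare_dmr_sets(sets[("committed", modality)], sets[("nascent", modality)])
        print(f"{modality} Venn committed-contrast vs nascent-contrast: {v}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
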