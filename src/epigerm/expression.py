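"""Count normalization, differential expression and gene-set integration.

The differential test is a documented stand-in for a negative-binomial GLM:
a two-sided Welch t on log2(CPM + 1) across replicates, BH-corrected.  The
calling thresholds follow the study conventions: a feature is differential
when its fold change strictly exceeds 2 and its FDR is strictly below 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomics import GeneModel, GenomicInterval, annotate_interval

__all__ = [
    "normalize_counts",
    "call_degs",
    "classify_de",
    "derive_pgc_genes",
    "marker_set_proportions",
    "stratified_expression",
    "nearest_gene_activation",
    "luciferase_normalize",
    "zscore_rows",
]


def normalize_counts(
    matrix: pd.DataFrame,
    mode: str = "per1e8",
    total_constant: float = 1e8,
    lengths: Optional[pd.Series] = None,
    library_sizes: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Normalize a features x samples count matrix.

    modes: ``per1e8`` scales every sample to a fixed total (default 1e8, the
    repeat-count convention); ``cpm`` is per1e8 with total 1e6; ``rpkm`` is
    count * 1e9 / (length_bp * library_size) and requires ``lengths``.
    Library sizes default to column sums.
    """
    lib = library_sizes if library_sizes is not None else matrix.sum(axis=0)
    lib = lib.astype(float)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    if mode == "per1e8":
        return matrix * (total_constant / lib)
    if mode == "cpm":
        return matrix * (1e6 / lib)
    if mode == "rpkm":
        if lengths is None:
            raise ValueError("rpkm requires feature lengths")
        L = lengths.reindex(matrix.index).astype(float)
        if (L <= 0).any():
            raise ValueError("lengths must be > 0")
        return matrix.mul(1e9, axis=0).div(L, axis=0).div(lib, axis=1)
    raise ValueError(f"unknown mode {mode!r}")


def classify_de(log2fc: float, fdr: float, fc_threshold: float = 2.0,
                fdr_threshold: float = 0.05) -> str:
    """Status by the strict printed rule: FC > 2 and FDR < 0.05 (FC = 2 is NS)."""
    lfc_thr = np.log2(fc_threshold)
    if fdr < fdr_threshold and log2fc > lfc_thr:
        return "up"
    if fdr < fdr_threshold and log2fc < -lfc_thr:
        return "down"
    return "NS"


def call_degs(
    matrix: pd.DataFrame,
    ctrl_samples: Sequence[str],
    exp_samples: Sequence[str],
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
    library_sizes: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Differential expression (experimental vs control) with strict thresholds.

    Returns a DataFrame indexed by feature with columns (log2fc, p, fdr,
    status).  log2fc = log2((mean CPM_exp + 1) / (mean CPM_ctrl + 1)); the p
    value is a two-sided Welch t on log2(CPM + 1) across replicates.
    """
    if len(ctrl_samples) < 2 or len(exp_samples) < 2:
        raise ValueError("need >= 2 replicates per group")
    cpm = normalize_counts(matrix, "cpm", library_sizes=library_sizes)
    ctrl = cpm[list(ctrl_samples)]
    exp = cpm[list(exp_samples)]
    log2fc = np.log2((exp.mean(axis=1) + 1.0) / (ctrl.mean(axis=1) + 1.0))
    la = np.log2(ctrl + 1.0)
    lb = np.log2(exp + 1.0)
    t, p = stats.ttest_ind(lb, la, axis=1, equal_var=False)
    p = pd.Series(p, index=matrix.index).fillna(1.0)
    fdr = pd.Series(multipletests(p, method="fdr_bh")[1], index=matrix.index)
    status = [
        classify_de(l, f, fc_threshold, fdr_threshold)
        for l, f in zip(log2fc, fdr)
    ]
    return pd.DataFrame({"log2fc": log2fc, "p": p, "fdr": fdr, "status": status})


def _passing(de: pd.DataFrame, logfc_min: float, fdr_max: float) -> Set[str]:
    return set(de.index[(de["log2fc"] > logfc_min) & (de["fdr"] < fdr_max)])


def derive_pgc_genes(
    wk7_vs_soma: pd.DataFrame,
    wk7_vs_es: pd.DataFrame,
    wk9_vs_soma: pd.DataFrame,
    wk9_vs_es: pd.DataFrame,
    logfc_min: float = 1.0,
    fdr_max: float = 0.05,
    mode: str = "union",
) -> Dict[str, Set[str]]:
    """Derive the "PGC genes" set from week-7 and week-9 enrichment.

    A gene is enriched in a week when it passes (logFC > 1, FDR < 0.05) in
    the comparison against gonadal somatic cells or against conventional ES
    cells (``mode='union'``; ``mode='intersection'`` requires both).  The
    shared set is genes enriched in both weeks; week-specific sets are also
    returned.
    """
    op = set.union if mode == "union" else set.intersection
    wk7 = op(_passing(wk7_vs_soma, logfc_min, fdr_max),
             _passing(wk7_vs_es, logfc_min, fdr_max))
    wk9 = op(_passing(wk9_vs_soma, logfc_min, fdr_max),
             _passing(wk9_vs_es, logfc_min, fdr_max))
    return {"shared": wk7 & wk9, "wk7_only": wk7 - wk9, "wk9_only": wk9 - wk7}


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def marker_set_proportions(flagged: Set[str], markers: Mapping[str, Set[str]]) -> pd.DataFrame:
    """Fraction of each marker set carried by a flagged gene set.

    Returns per marker set (n_flagged, n_total, fraction, percent) where
    percent is rounded half-away-from-zero to an integer.
    """
    rows = []
    for name, members in markers.items():
        if not members:
            raise ValueError(f"empty marker set {name!r}")
        k = len(flagged & set(members))
        frac = 100.0 * k / len(members)
        rows.append({"set": name, "n_flagged": k, "n_total": len(members),
                     "fraction": frac, "percent": _round_half_away(frac)})
    return pd.DataFrame(rows).set_index("set")


def stratified_expression(
    strata: Mapping[str, Sequence[str]],
    fold_changes: pd.Series,
) -> pd.DataFrame:
    """Summarise a fold-change vector over disjoint gene strata.

    Returns per stratum (n, mean, median); empty strata are reported with
    NaN summaries rather than dropped.  Strata must be disjoint.
    """
    seen: Set[str] = set()
    for name, members in strata.items():
        m = set(members)
        if m & seen:
            raise ValueError(f"strata overlap at {sorted(m & seen)[:3]}")
        seen |= m
    missing = seen - set(fold_changes.index)
    if missing:
        raise ValueError(f"fold changes missing for {sorted(missing)[:3]}")
    rows = []
    for name, members in strata.items():
        vals = fold_changes.loc[list(members)]
        rows.append({
            "stratum": name,
            "n": len(members),
            "mean": float(vals.mean()) if len(members) else np.nan,
            "median": float(vals.median()) if len(members) else np.nan,
        })
    return pd.DataFrame(rows).set_index("stratum")


def nearest_gene_activation(
    instances: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    fold_changes: pd.Series,
) -> Tuple[Set[str], pd.Series]:
    """Genes nearest to repeat instances and their fold-change distribution.

    Each instance is assigned its nearest gene by TSS distance (midpoint
    rule); the gene set is deduplicated.  Instances on chromosomes without
    genes are excluded.  Returns (gene set, fold changes over the set).
    """
    gene_set: Set[str] = set()
    for iv in instances:
        ann = annotate_interval(iv, genes)
        if ann.nearest_gene_id is not None:
            gene_set.add(ann.nearest_gene_id)
    present = sorted(g for g in gene_set if g in fold_changes.index)
    return gene_set, fold_changes.loc[present]


def luciferase_normalize(
    firefly: pd.Series,
    gfp: pd.Series,
    neg_well_ids: Sequence[str],
) -> pd.Series:
    """Firefly/GFP ratios expressed relative to the negative-control mean.

    ratio = firefly / gfp per well; relative = ratio / mean(ratio over the
    negative wells), so the negative control averages 1 by construction.
    """
    gfp = gfp.reindex(firefly.index)
    if (gfp <= 0).any():
        raise ValueError("GFP signal must be > 0 in every well")
    ratio = firefly / gfp
    neg = ratio.loc[list(neg_well_ids)]
    return ratio / neg.mean()


def zscore_rows(matrix: pd.DataFrame) -> Tuple[pd.DataFrame, List[str]]:
    """Row-standardize (population sd); constant rows become zeros and are flagged."""
    mu = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=0)
    flagged = list(matrix.index[sd == 0])
    safe_sd = sd.replace(0, 1.0)
    z = matrix.sub(mu, axis=0).div(safe_sd, axis=0)
    z.loc[flagged] = 0.0
    return z, flagged
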