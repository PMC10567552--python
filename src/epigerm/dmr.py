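"""Differentially methylated region (DMR) detection.

A DMR is a run of individually significant, same-signed CpGs: each CpG is
tested with a pooled-variance two-sample t across replicate rates, CpGs whose
|t| exceeds the two-sided critical value at alpha are candidates, consecutive
candidates closer than ``max_gap`` bases sharing a sign are merged, and a run
is reported when it holds at least ``min_cpg`` CpGs and its mean rate
difference (experimental - control) clears the modality-specific cutoff
(5mC 0.2, 5hmC 0.05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .genomics import GenomicInterval
from .methylome import MIN_COVERAGE, MethylomeTrack

__all__ = ["DMRConfig", "DMR", "cpg_test", "call_dmrs", "compare_dmr_sets", "peak_dmr_overlap"]

MEAN_DIFF_CUTOFFS = {"5mC": 0.2, "5hmC": 0.05}


@dataclass(frozen=True)
class DMRConfig:
    alpha: float = 0.05
    max_gap: int = 300            # strict: merge only when gap < max_gap
    mean_diff_cutoff: Optional[float] = None  # None -> modality default
    min_cpg: int = 3
    pct_min_ctrl: float = 0.0     # retained for fidelity; inert at 0
    pct_min_exp: float = 0.0
    min_coverage: int = MIN_COVERAGE

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0,1)")
        if self.max_gap <= 0:
            raise ValueError("max_gap must be > 0")
        if self.mean_diff_cutoff is not None and not (0 < self.mean_diff_cutoff < 1):
            raise ValueError("mean_diff_cutoff must be in (0,1)")

    def cutoff_for(self, modality: str) -> float:
        if self.mean_diff_cutoff is not None:
            return self.mean_diff_cutoff
        try:
            return MEAN_DIFF_CUTOFFS[modality]
        except KeyError:
            raise ValueError(f"no default mean-diff cutoff for modality {modality!r}")


@dataclass(frozen=True)
class DMR:
    interval: GenomicInterval
    modality: str
    direction: str  # hyper/hypo w.r.t. the experimental group
    n_cpg: int
    mean_diff: float
    cpg_t_stats: Tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.direction not in {"hyper", "hypo"}:
            raise ValueError("direction must be hyper or hypo")
        if (self.mean_diff > 0) != (self.direction == "hyper"):
            raise ValueError("mean_diff sign inconsistent with direction")


def cpg_test(ctrl_rates: Sequence[float], exp_rates: Sequence[float]) -> Tuple[float, int]:
    """Pooled-variance two-sample t on per-replicate rates at one CpG.

    Returns (t, df) with df = n_ctrl + n_exp - 2.  A zero pooled variance
    yields t = 0 for equal means and signed infinity otherwise.
    """
    a = np.asarray(ctrl_rates, dtype=float)
    b = np.asarray(exp_rates, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per group")
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    diff = b.mean() - a.mean()
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    denom = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    if denom == 0:
        t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
    else:
        t = diff / denom
    return t, df


def _per_cpg_table(tracks: Sequence[MethylomeTrack], min_coverage: int) -> pd.DataFrame:
    """Wide table of passing per-replicate rates indexed by (chrom, pos)."""
    cols = []
    for i, tr in enumerate(tracks):
        r = tr.records
        ok = r[r["coverage"] >= min_coverage]
        s = pd.Series(
            (ok["n_mod"] / ok["coverage"]).to_numpy(),
            index=pd.MultiIndex.from_arrays([ok["chrom"], ok["pos"]]),
            name=f"rep{i}",
        )
        cols.append(s)
    return pd.concat(cols, axis=1)


def call_dmrs(
    ctrl_tracks: Sequence[MethylomeTrack],
    exp_tracks: Sequence[MethylomeTrack],
    config: DMRConfig = DMRConfig(),
) -> List[DMR]:
    """Call DMRs (experimental vs control) from called replicate tracks."""
    modalities = {t.modality for t in list(ctrl_tracks) + list(exp_tracks)}
    if len(modalities) > 1:
        raise ValueError(f"modality mismatch between tracks: {sorted(modalities)}")
    modality = modalities.pop() if modalities else ""
    cutoff = config.cutoff_for(modality) if modality else (config.mean_diff_cutoff or 0.0)

    ctrl = _per_cpg_table(ctrl_tracks, config.min_coverage)
    exp = _per_cpg_table(exp_tracks, config.min_coverage)
    idx = ctrl.dropna(thresh=2).index.intersection(exp.dropna(thresh=2).index)
    if len(idx) == 0:
        return []
    ctrl = ctrl.loc[idx]
    exp = exp.loc[idx]

    a = ctrl.to_numpy()
    b = exp.to_numpy()
    n1 = np.sum(~np.isnan(a), axis=1)
    n2 = np.sum(~np.isnan(b), axis=1)
    usable = (n1 >= 2) & (n2 >= 2)
    ma = np.nanmean(a, axis=1)
    mb = np.nanmean(b, axis=1)
    va = np.nanvar(a, axis=1, ddof=1)
    vb = np.nanvar(b, axis=1, ddof=1)
    df = n1 + n2 - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        sp2 = ((n1 - 1) * va + (n2 - 1) * vb) / df
        denom = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        t = (mb - ma) / denom
    diff = mb - ma
    with np.errstate(invalid="ignore"):
        t = np.where(denom == 0, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
    crit = stats.t.ppf(1 - config.alpha / 2, df)
    candidate = usable & (np.abs(t) > crit) & (diff != 0)

    table = pd.DataFrame(
        {
            "chrom": idx.get_level_values(0),
            "pos": idx.get_level_values(1),
            "t": t,
            "diff": diff,
        }
    )[candidate].sort_values(["chrom", "pos"], kind="mergesort")

    dmrs: List[DMR] = []
    run: List[tuple] = []

    def flush(run: List[tuple]) -> None:
        if len(run) < config.min_cpg:
            return
        mean_diff = float(np.mean([r[3] for r in run]))
        if abs(mean_diff) < cutoff:
            return
        chrom = run[0][0]
        start, end = run[0][1], run[-1][1] + 2  # include both bases of last CpG
        dmrs.append(
            DMR(
                interval=GenomicInterval(chrom, int(start), int(end)),
                modality=modality,
                direction="hyper" if mean_diff > 0 else "hypo",
                n_cpg=len(run),
                mean_diff=mean_diff,
                cpg_t_stats=tuple(float(r[2]) for r in run),
            )
        )

    for row in table.itertuples(index=False):
        chrom, pos, tval, dval = row.chrom, row.pos, row.t, row.diff
        sign = 1 if dval > 0 else -1
        if run and (
            chrom != run[-1][0]
            or pos - run[-1][1] >= config.max_gap
            or sign != run[-1][4]
        ):
            flush(run)
            run = []
        run.append((chrom, pos, tval, dval, sign))
    flush(run)
    return dmrs


def compare_dmr_sets(set_a: Sequence[DMR], set_b: Sequence[DMR]) -> dict:
    """Venn-style overlap counts between two DMR sets (>= 1 bp overlap)."""
    b_by_chrom: dict = {}
    for d in set_b:
        b_by_chrom.setdefault(d.interval.chrom, []).append(d.interval)
    a_by_chrom: dict = {}
    for d in set_a:
        a_by_chrom.setdefault(d.interval.chrom, []).append(d.interval)

    def n_overlapping(queries, targets_by_chrom):
        return sum(
            1
            for d in queries
            if any(d.interval.overlaps(iv) for iv in targets_by_chrom.get(d.interval.chrom, ()))
        )

    shared_a = n_overlapping(set_a, b_by_chrom)
    shared_b = n_overlapping(set_b, a_by_chrom)
    return {
        "a_only": len(set_a) - shared_a,
        "b_only": len(set_b) - shared_b,
        "shared_a": shared_a,
        "shared_b": shared_b,
    }


def peak_dmr_overlap(
    peaks: Sequence[GenomicInterval],
    hyper_5hmc: Sequence[DMR],
    hypo_5mc: Sequence[DMR],
) -> dict:
    """Classify filtered peak regions by DMR overlap.

    Each peak falls in exactly one of {"5hmC_only", "5mC_only", "both",
    "neither"} by >= 1 bp overlap with hyper-5hmC / hypo-5mC DMRs;
    percentages sum to 100.
    """
    if not peaks:
        raise ValueError("empty peak set")
    h_by = {}
    for d in hyper_5hmc:
        h_by.setdefault(d.interval.chrom, []).append(d.interval)
    m_by = {}
    for d in hypo_5mc:
        m_by.setdefault(d.interval.chrom, []).append(d.interval)
    counts = {"5hmC_only": 0, "5mC_only": 0, "both": 0, "neither": 0}
    for p in peaks:
        has_h = any(p.overlaps(iv) for iv in h_by.get(p.chrom, ()))
        has_m = any(p.overlaps(iv) for iv in m_by.get(p.chrom, ()))
        key = (
            "both" if has_h and has_m else "5hmC_only" if has_h else "5mC_only" if has_m else "neither"
        )
        counts[key] += 1
    n = len(peaks)
    return {k: 100.0 * v / n for k, v in counts.items()}
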