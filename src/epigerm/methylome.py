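"""Base-resolution 5mC/5hmC level calling from converted-base counts.

In pyridine-borane sequencing chemistries the modified cytosine of interest is
read as T, so the per-CpG modification rate is T / (C + T), i.e.
``n_mod / (n_mod + n_unmod)``.  TAPSb (beta-glucosyltransferase-blocked TAPS)
reads 5mC only; CAPS+ reads 5hmC only, so no subtraction between chemistries
is needed.  Sites are used only when covered more than 5 times (coverage >= 6).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .genomics import GenomicInterval

__all__ = [
    "MethylomeTrack",
    "call_site_levels",
    "estimate_conversion",
    "tile_methylome",
    "region_methylation",
    "MIN_COVERAGE",
]

MIN_COVERAGE = 6  # "covered >5 times" read strictly


@dataclass
class MethylomeTrack:
    """Per-sample, per-modality called CpG levels.

    ``records`` is a DataFrame with columns (chrom, pos, n_mod, n_unmod,
    coverage, rate, covered), sorted by (chrom, pos) and unique on them.
    ``rate`` is NaN where the coverage filter fails.
    """

    sample_id: str
    stage: str
    modality: str  # "5mC" (TAPSb) or "5hmC" (CAPS+)
    replicate: int
    records: pd.DataFrame
    conversion_rate: Optional[float] = None

    def __post_init__(self) -> None:
        r = self.records
        if r.duplicated(["chrom", "pos"]).any():
            raise ValueError("duplicate CpG positions in track")
        self.records = r.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    @property
    def covered(self) -> pd.DataFrame:
        return self.records[self.records["covered"]]


def call_site_levels(
    counts,
    min_coverage: int = MIN_COVERAGE,
    sample_id: str = "",
    stage: str = "",
    modality: str = "",
    replicate: int = 1,
) -> MethylomeTrack:
    """Call per-CpG modification rates from converted-base counts.

    ``counts`` is an iterable of (chrom, start, end, n_mod, n_unmod) rows (as
    produced by :func:`epigerm.genomics.read_intervals` with the ``cpg_counts``
    dialect) or an equivalent DataFrame.  The rate is n_mod/(n_mod+n_unmod);
    CpGs with coverage below ``min_coverage`` are retained but flagged
    uncovered (rate NaN).
    """
    if isinstance(counts, pd.DataFrame):
        df = counts.rename(columns={"start": "pos"}).copy()
    else:
        rows = list(counts)
        df = pd.DataFrame(rows, columns=["chrom", "pos", "end", "n_mod", "n_unmod"])
    if (df["n_mod"] < 0).any() or (df["n_unmod"] < 0).any():
        raise ValueError("negative counts")
    df = df[["chrom", "pos", "n_mod", "n_unmod"]].copy()
    df["coverage"] = df["n_mod"] + df["n_unmod"]
    df["covered"] = df["coverage"] >= min_coverage
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = df["n_mod"] / df["coverage"]
    df["rate"] = rate.where(df["covered"])
    return MethylomeTrack(sample_id, stage, modality, replicate, df)


def estimate_conversion(spike) -> float:
    """Aggregate conversion rate over fully modified spike-in control CpGs.

    conversion = sum(n_mod) / sum(n_mod + n_unmod).  Applied to unmodified
    controls the same ratio estimates the false-conversion rate.
    """
    if isinstance(spike, pd.DataFrame):
        n_mod = int(spike["n_mod"].sum())
        n_unmod = int(spike["n_unmod"].sum())
    else:
        rows = list(spike)
        n_mod = sum(r[3] for r in rows)
        n_unmod = sum(r[4] for r in rows)
    total = n_mod + n_unmod
    if total == 0:
        raise ValueError("zero aggregate spike-in coverage")
    return n_mod / total


def tile_methylome(
    track: MethylomeTrack,
    tile_size: int = 1000,
    min_cpg: int = 3,
    min_coverage: int = MIN_COVERAGE,
    kde_bandwidth: float = 0.05,
    kde_grid_points: int = 201,
):
    """Fixed-grid tiling of a called track with the standard genome-wide view.

    Tiles are non-overlapping windows of ``tile_size`` bp anchored at
    coordinate 0 on each chromosome.  A tile is retained when it holds at
    least ``min_cpg`` CpGs passing the coverage filter; its mean is the
    unweighted mean of passing CpG rates.  Returns ``(tiles, global_mean,
    density)`` where ``tiles`` is a DataFrame (chrom, start, end, n_cpg,
    mean_rate), ``global_mean`` the unweighted mean over retained tiles, and
    ``density`` a (grid, value) DataFrame from a Gaussian KDE with absolute
    bandwidth ``kde_bandwidth`` on the [0, 1] rate scale (None when fewer
    than 2 distinct tile means exist).
    """
    rec = track.records
    ok = rec[(rec["n_mod"] + rec["n_unmod"]) >= min_coverage].copy()
    if ok.empty:
        tiles = pd.DataFrame(columns=["chrom", "start", "end", "n_cpg", "mean_rate"])
        return tiles, float("nan"), None
    rate = ok["n_mod"] / (ok["n_mod"] + ok["n_unmod"])
    ok = ok.assign(rate=rate, tile=ok["pos"] // tile_size)
    grouped = ok.groupby(["chrom", "tile"], sort=True)["rate"].agg(["size", "mean"])
    grouped = grouped[grouped["size"] >= min_cpg].reset_index()
    tiles = pd.DataFrame(
        {
            "chrom": grouped["chrom"],
            "start": grouped["tile"] * tile_size,
            "end": (grouped["tile"] + 1) * tile_size,
            "n_cpg": grouped["size"].astype(int),
            "mean_rate": grouped["mean"],
        }
    )
    if tiles.empty:
        return tiles, float("nan"), None
    global_mean = float(tiles["mean_rate"].mean())
    density = None
    vals = tiles["mean_rate"].to_numpy()
    sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
    if sd > 0:
        kde = gaussian_kde(vals, bw_method=kde_bandwidth / sd)
        grid = np.linspace(0.0, 1.0, kde_grid_points)
        density = pd.DataFrame({"rate": grid, "density": kde(grid)})
    return tiles, global_mean, density


def region_methylation(
    track: MethylomeTrack,
    regions: Sequence[GenomicInterval],
    min_coverage: int = MIN_COVERAGE,
    min_cpg: Optional[int] = None,
    all_tracks: Optional[Sequence[MethylomeTrack]] = None,
) -> pd.Series:
    """Unweighted mean CpG rate per region, with the standard filters.

    A CpG contributes when its coverage passes ``min_coverage`` in ``track``;
    when ``all_tracks`` is supplied (the "covered >5 times in all samples"
    rule) the CpG must additionally pass the filter in every listed track.
    Regions with fewer than ``min_cpg`` passing CpGs (when set) or on
    chromosomes absent from the track yield NaN.  Output is indexed by region
    order and invariant to region reordering.
    """
    rec = track.records
    passing = rec["coverage"] >= min_coverage
    if all_tracks is not None:
        key = rec.set_index(["chrom", "pos"]).index
        for other in all_tracks:
            o = other.records
            ok_idx = o.loc[o["coverage"] >= min_coverage].set_index(["chrom", "pos"]).index
            passing &= key.isin(ok_idx)
    ok = rec[passing]
    rate = ok["n_mod"] / ok["coverage"]
    by_chrom = {
        chrom: (grp["pos"].to_numpy(), (grp["n_mod"] / grp["coverage"]).to_numpy())
        for chrom, grp in ok.groupby("chrom")
    }
    values = []
    for iv in regions:
        if iv.chrom not in by_chrom:
            values.append(np.nan)
            continue
        pos, rates = by_chrom[iv.chrom]
        lo = np.searchsorted(pos, iv.start, side="left")
        hi = np.searchsorted(pos, iv.end, side="left")
        n = hi - lo
        if n == 0 or (min_cpg is not None and n < min_cpg):
            values.append(np.nan)
        else:
            values.append(float(rates[lo:hi].mean()))
    names = [iv.name or f"{iv.chrom}:{iv.start}-{iv.end}" for iv in regions]
    return pd.Series(values, index=names, name="mean_rate")
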