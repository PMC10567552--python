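"""Genomic interval model, BED-family I/O, peak consensus and feature annotation.

All coordinates are 0-based half-open (BED convention) everywhere in this
package.  Coordinates printed 1-based inclusive in external sources must be
converted on ingestion (``start = printed_start - 1``).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "PeakRecord",
    "RepeatElement",
    "FeatureAnnotation",
    "read_intervals",
    "write_intervals",
    "read_chrom_sizes",
    "consensus_peaks",
    "annotate_interval",
    "feature_distribution",
    "sample_matched_random_regions",
    "PROMOTER_UPSTREAM",
    "PROMOTER_DOWNSTREAM",
    "TTS_UPSTREAM",
    "TTS_DOWNSTREAM",
]

# Promoter-TSS / TTS windows follow HOMER annotatePeaks.pl defaults
# (upstream 1 kb, downstream 100 bp around the relevant end, strand-aware).
PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 100
TTS_UPSTREAM = 100
TTS_DOWNSTREAM = 1000


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneModel:
    """A gene body with exon structure; TSS/TTS are strand-aware."""

    gene_id: str
    gene_name: str
    interval: GenomicInterval
    strand: str
    exons: tuple = ()
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        prev_end = None
        for ex in self.exons:
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"{self.gene_id}: exon outside gene body")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = ex.end

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tts(self) -> int:
        """Transcription end site (3' end), strand-aware."""
        return self.interval.end - 1 if self.strand == "+" else self.interval.start

    @property
    def introns(self) -> tuple:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end < b.start:
                out.append(GenomicInterval(self.interval.chrom, a.end, b.start, self.strand))
        return tuple(out)


@dataclass(frozen=True)
class PeakRecord:
    """A called TF-binding peak with a MACS2-style -log10(q) score."""

    interval: GenomicInterval
    minus_log10_q: float
    summit_offset: Optional[int] = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.minus_log10_q < 0:
            raise ValueError("minus_log10_q must be >= 0")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.interval.length
        ):
            raise ValueError("summit_offset outside interval")


@dataclass(frozen=True)
class RepeatElement:
    interval: GenomicInterval
    subfamily: str
    family: str = ""
    repeat_class: str = ""

    def __post_init__(self) -> None:
        if not self.subfamily:
            raise ValueError("subfamily must be non-empty")


@dataclass(frozen=True)
class FeatureAnnotation:
    query: GenomicInterval
    nearest_gene_id: Optional[str]
    signed_distance: Optional[int]
    category: str
    overlapping_repeat: Optional[str] = None
    flagged: bool = False


CATEGORIES = ("promoter-TSS", "exon", "TTS", "intron", "intergenic")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _parse_bed_fields(fields, lineno: int, path, n_min: int):
    if len(fields) < n_min:
        raise ValueError(f"{path}:{lineno}: expected >= {n_min} columns, got {len(fields)}")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
    if start >= end or start < 0:
        raise ValueError(f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}")
    return chrom, start, end


def read_intervals(path, dialect: str):
    """Read a BED-family file into typed records.

    Supported dialects: ``bed3``, ``bed6``, ``bed12`` (returns :class:`GeneModel`),
    ``narrowPeak`` (returns :class:`PeakRecord`), ``cpg_counts`` (returns a list
    of ``(chrom, start, end, n_mod, n_unmod)`` tuples).  Files may be gzipped.
    Records are returned sorted by (chrom, start).
    """
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if dialect == "bed3":
                chrom, start, end = _parse_bed_fields(fields, lineno, path, 3)
                out.append(GenomicInterval(chrom, start, end))
            elif dialect == "bed6":
                chrom, start, end = _parse_bed_fields(fields, lineno, path, 6)
                out.append(
                    GenomicInterval(chrom, start, end, strand=fields[5], name=fields[3])
                )
            elif dialect == "bed12":
                chrom, start, end = _parse_bed_fields(fields, lineno, path, 12)
                strand = fields[5]
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
                if len(sizes) != n_blocks or len(offsets) != n_blocks:
                    raise ValueError(f"{path}:{lineno}: block count mismatch")
                exons = tuple(
                    GenomicInterval(chrom, start + off, start + off + size, strand)
                    for off, size in zip(offsets, sizes)
                )
                out.append(
                    GeneModel(
                        gene_id=fields[3],
                        gene_name=fields[3],
                        interval=GenomicInterval(chrom, start, end, strand),
                        strand=strand,
                        exons=exons,
                    )
                )
            elif dialect == "narrowPeak":
                chrom, start, end = _parse_bed_fields(fields, lineno, path, 10)
                summit = int(fields[9])
                out.append(
                    PeakRecord(
                        interval=GenomicInterval(
                            chrom, start, end, strand=fields[5] if fields[5] in "+-" else ".",
                            name=fields[3],
                        ),
                        minus_log10_q=float(fields[8]),
                        summit_offset=summit if summit >= 0 else None,
                    )
                )
            elif dialect == "cpg_counts":
                chrom, start, end = _parse_bed_fields(fields, lineno, path, 5)
                n_mod, n_unmod = int(fields[3]), int(fields[4])
                if n_mod < 0 or n_unmod < 0:
                    raise ValueError(f"{path}:{lineno}: negative count")
                out.append((chrom, start, end, n_mod, n_unmod))
            else:
                raise ValueError(f"unknown dialect {dialect!r}")
    return sorted(out, key=_sort_key)


def _sort_key(rec):
    iv = _interval_of(rec)
    return (iv.chrom, iv.start, iv.end)


def _interval_of(rec) -> GenomicInterval:
    if isinstance(rec, GenomicInterval):
        return rec
    if isinstance(rec, (PeakRecord, RepeatElement)):
        return rec.interval
    if isinstance(rec, GeneModel):
        return rec.interval
    if isinstance(rec, tuple):  # cpg_counts row
        return GenomicInterval(rec[0], rec[1], rec[2])
    raise TypeError(type(rec))


def write_intervals(records, path, dialect: str) -> None:
    """Inverse of :func:`read_intervals` for every supported dialect."""
    with _open_text(path, "wt") as fh:
        for rec in records:
            if dialect == "bed3":
                iv = _interval_of(rec)
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            elif dialect == "bed6":
                iv = _interval_of(rec)
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n")
            elif dialect == "bed12":
                g: GeneModel = rec
                iv = g.interval
                sizes = ",".join(str(e.length) for e in g.exons) + ","
                offs = ",".join(str(e.start - iv.start) for e in g.exons) + ","
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{g.strand}\t"
                    f"{iv.start}\t{iv.end}\t0\t{len(g.exons)}\t{sizes}\t{offs}\n"
                )
            elif dialect == "narrowPeak":
                p: PeakRecord = rec
                iv = p.interval
                summit = p.summit_offset if p.summit_offset is not None else -1
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\t"
                    f"0\t-1\t{p.minus_log10_q:g}\t{summit}\n"
                )
            elif dialect == "cpg_counts":
                chrom, start, end, n_mod, n_unmod = rec
                fh.write(f"{chrom}\t{start}\t{end}\t{n_mod}\t{n_unmod}\n")
            else:
                raise ValueError(f"unknown dialect {dialect!r}")


def read_chrom_sizes(path) -> dict:
    sizes = {}
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split("\t")[:2]
            sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with _open_text(path, "wt") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


# ---------------------------------------------------------------------------
# Peak consensus
# ---------------------------------------------------------------------------

def consensus_peaks(
    rep_a: Sequence[PeakRecord],
    rep_b: Sequence[PeakRecord],
    q_threshold: float,
) -> list:
    """Replicate-common peaks at a strict -log10(q) threshold.

    Keeps each peak of ``rep_a`` with ``minus_log10_q > q_threshold`` (strict,
    as printed ">10") that overlaps by >= 1 bp at least one ``rep_b`` peak
    passing the same threshold.  Replicate-1 coordinates are retained.
    """
    if q_threshold < 0:
        raise ValueError("q_threshold must be >= 0")
    a_pass = [p for p in rep_a if p.minus_log10_q > q_threshold]
    b_pass = [p for p in rep_b if p.minus_log10_q > q_threshold]
    b_by_chrom: dict = {}
    for p in b_pass:
        b_by_chrom.setdefault(p.interval.chrom, []).append(p.interval)
    out = []
    seen = set()
    for p in a_pass:
        key = (p.interval.chrom, p.interval.start, p.interval.end)
        if key in seen:
            continue
        if any(p.interval.overlaps(iv) for iv in b_by_chrom.get(p.interval.chrom, ())):
            out.append(p)
            seen.add(key)
    return sorted(out, key=_sort_key)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def _promoter_window(gene: GeneModel):
    if gene.strand == "+":
        return gene.tss - PROMOTER_UPSTREAM, gene.tss + PROMOTER_DOWNSTREAM + 1
    return gene.tss - PROMOTER_DOWNSTREAM, gene.tss + PROMOTER_UPSTREAM + 1


def _tts_window(gene: GeneModel):
    if gene.strand == "+":
        return gene.tts - TTS_UPSTREAM, gene.tts + TTS_DOWNSTREAM + 1
    return gene.tts - TTS_DOWNSTREAM, gene.tts + TTS_UPSTREAM + 1


def annotate_interval(
    query: GenomicInterval,
    genes: Sequence[GeneModel],
    repeats: Sequence[RepeatElement] = (),
) -> FeatureAnnotation:
    """Annotate a region with its nearest gene and genomic-feature category.

    The query is anchored at its midpoint.  Nearest gene minimises
    ``|midpoint - TSS|`` (ties broken lexicographically by gene_id); the
    category is assigned by precedence promoter-TSS > exon > TTS > intron >
    intergenic, testing the midpoint against every gene on the query's
    chromosome.  The signed distance is strand-aware: negative means the
    midpoint is upstream of the nearest TSS.
    """
    if not genes:
        raise ValueError("gene set must be non-empty")
    mid = query.midpoint
    same_chrom = [g for g in genes if g.interval.chrom == query.chrom]

    overlapping_repeat = None
    best_ov = 0
    for r in repeats:
        ov = query.overlap_length(r.interval)
        if ov > best_ov or (ov == best_ov and ov > 0 and (
            overlapping_repeat is None or r.subfamily < overlapping_repeat
        )):
            best_ov = ov
            overlapping_repeat = r.subfamily

    if not same_chrom:
        return FeatureAnnotation(
            query, None, None, "intergenic", overlapping_repeat, flagged=True
        )

    nearest = min(same_chrom, key=lambda g: (abs(mid - g.tss), g.gene_id))
    signed = mid - nearest.tss if nearest.strand == "+" else nearest.tss - mid

    category = "intergenic"
    in_promoter = any(lo <= mid < hi for lo, hi in map(_promoter_window, same_chrom))
    if in_promoter:
        category = "promoter-TSS"
    elif any(e.start <= mid < e.end for g in same_chrom for e in g.exons):
        category = "exon"
    elif any(lo <= mid < hi for lo, hi in map(_tts_window, same_chrom)):
        category = "TTS"
    elif any(g.interval.start <= mid < g.interval.end for g in same_chrom):
        category = "intron"
    return FeatureAnnotation(query, nearest.gene_id, signed, category, overlapping_repeat)


def feature_distribution(
    peaks: Sequence[PeakRecord],
    genes: Sequence[GeneModel],
    repeats: Sequence[RepeatElement] = (),
) -> dict:
    """Percentage of peaks per genomic-feature category (midpoint-anchored)."""
    if not peaks:
        raise ValueError("empty peak set")
    counts = {c: 0 for c in CATEGORIES}
    for p in peaks:
        ann = annotate_interval(p.interval, genes, repeats)
        counts[ann.category] += 1
    n = len(peaks)
    return {c: 100.0 * k / n for c, k in counts.items() if k > 0}


# ---------------------------------------------------------------------------
# Matched random regions
# ---------------------------------------------------------------------------

def sample_matched_random_regions(
    genome_sizes: Mapping[str, int],
    template: Sequence[GenomicInterval],
    n: int,
    seed: int,
    constraint: Optional[Callable[[GenomicInterval], bool]] = None,
    max_attempts_per_region: int = 1000,
) -> list:
    """Sample ``n`` random regions length-matched to a template set.

    Lengths are drawn with replacement (seeded) from the template lengths and
    regions are placed uniformly on the genome (chromosome chosen with
    probability proportional to its length); each region is resampled until
    the optional constraint holds.  Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not template:
        raise ValueError("template must be non-empty")
    rng = np.random.default_rng(seed)
    lengths = np.array([iv.length for iv in template])
    chroms = list(genome_sizes)
    sizes = np.array([genome_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    out = []
    for _ in range(n):
        length = int(rng.choice(lengths))
        for attempt in range(max_attempts_per_region):
            ci = int(rng.choice(len(chroms), p=probs))
            chrom = chroms[ci]
            hi = genome_sizes[chrom] - length
            if hi < 0:
                continue
            start = int(rng.integers(0, hi + 1))
            iv = GenomicInterval(chrom, start, start + length)
            if constraint is None or constraint(iv):
                out.append(iv)
                break
        else:
            raise RuntimeError(
                f"constraint unsatisfiable after {max_attempts_per_region} attempts"
            )
    return out
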