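"""Motif scanning and binomial motif enrichment.

Motifs are exact IUPAC strings (e.g. the DMRT1 consensus) or position count
matrices scored as log-odds against a uniform background.  Enrichment follows
the classic known-motif binomial model: a region counts as "with motif" when
it holds at least one hit, and the target count is tested against the
background hit fraction with an upper-tail binomial p-value, BH-adjusted
across motifs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .genomics import GenomicInterval

__all__ = ["Motif", "MotifHit", "EnrichmentResult", "scan_motif", "enrich_motifs",
           "binomial_tail_p", "reverse_complement", "read_homer_motifs"]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Motif:
    motif_id: str
    iupac: Optional[str] = None
    pcm: Optional[np.ndarray] = None  # shape (length, 4), A C G T column order
    score_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.iupac is None) == (self.pcm is None):
            raise ValueError("exactly one of iupac or pcm must be given")
        if self.iupac is not None:
            s = self.iupac.upper()
            bad = set(s) - set(IUPAC)
            if not s or bad:
                raise ValueError(f"invalid IUPAC motif {self.iupac!r}: {sorted(bad)}")
        else:
            pcm = np.asarray(self.pcm, dtype=float)
            if pcm.ndim != 2 or pcm.shape[1] != 4 or (pcm.sum(axis=1) <= 0).any():
                raise ValueError("PCM must be (length, 4) with positive column sums")
            if self.score_threshold is None:
                raise ValueError("PCM mode requires a score_threshold")

    @property
    def length(self) -> int:
        return len(self.iupac) if self.iupac is not None else self.pcm.shape[0]


@dataclass(frozen=True)
class MotifHit:
    interval: GenomicInterval
    strand: str
    matched: str
    score: float


def _iupac_regex(iupac: str) -> re.Pattern:
    return re.compile("".join(f"[{IUPAC[c]}]" if len(IUPAC[c]) > 1 else IUPAC[c]
                              for c in iupac.upper()))


def _scan_seq_exact(seq: str, motif: Motif, chrom: str, offset: int) -> List[MotifHit]:
    seq = seq.upper()
    hits = []
    for strand, pat_src in (("+", motif.iupac), ("-", reverse_complement(motif.iupac))):
        pat = _iupac_regex(pat_src)
        for m in re.finditer(f"(?=({pat.pattern}))", seq):
            start = m.start()
            matched = m.group(1)
            hits.append(
                MotifHit(
                    GenomicInterval(chrom, offset + start, offset + start + motif.length,
                                    strand, motif.motif_id),
                    strand,
                    matched if strand == "+" else reverse_complement(matched),
                    float(motif.length),
                )
            )
    return hits


def _scan_seq_pcm(seq: str, motif: Motif, chrom: str, offset: int) -> List[MotifHit]:
    seq = seq.upper()
    pwm = np.asarray(motif.pcm, dtype=float)
    probs = (pwm + 0.25) / (pwm.sum(axis=1, keepdims=True) + 1.0)  # pseudocount
    logodds = np.log2(probs / 0.25)
    L = motif.length
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    hits = []
    enc = np.array([code.get(c, -1) for c in seq])
    for strand in ("+", "-"):
        mat = logodds if strand == "+" else logodds[::-1, ::-1]
        for i in range(len(seq) - L + 1):
            window = enc[i:i + L]
            if (window < 0).any():
                continue
            score = float(mat[np.arange(L), window].sum())
            if score >= motif.score_threshold:
                matched = seq[i:i + L]
                hits.append(
                    MotifHit(
                        GenomicInterval(chrom, offset + i, offset + i + L, strand,
                                        motif.motif_id),
                        strand,
                        matched if strand == "+" else reverse_complement(matched),
                        score,
                    )
                )
    return hits


def scan_motif(
    sequences: Union[str, Mapping[str, str]],
    motif: Motif,
    regions: Optional[Sequence[GenomicInterval]] = None,
) -> List[MotifHit]:
    """Scan sequence(s) for a motif on both strands.

    ``sequences`` is either a single sequence string (reported on chromosome
    "seq") or a mapping chrom -> sequence (e.g. a ``pyfaidx.Fasta``); when
    ``regions`` is given, only those sub-sequences are scanned and hit
    coordinates are genomic.  Reverse-complement matches are reported on the
    "-" strand with ``matched`` giving the motif-strand sequence.  Hits are
    sorted by position.
    """
    scanner = _scan_seq_exact if motif.iupac is not None else _scan_seq_pcm
    hits: List[MotifHit] = []
    if isinstance(sequences, str):
        if regions is not None:
            raise ValueError("regions require a named sequence mapping")
        hits = scanner(sequences, motif, "seq", 0)
    elif regions is not None:
        for iv in regions:
            sub = str(sequences[iv.chrom][iv.start:iv.end])
            hits.extend(scanner(sub, motif, iv.chrom, iv.start))
    else:
        for chrom in sequences.keys() if hasattr(sequences, "keys") else sequences:
            hits.extend(scanner(str(sequences[chrom][:]), motif, chrom, 0))
    return sorted(hits, key=lambda h: (h.interval.chrom, h.interval.start, h.strand))


@dataclass(frozen=True)
class EnrichmentResult:
    motif_id: str
    n_target_with: int
    n_target: int
    n_bg_with: int
    n_bg: int
    fold: float
    p_value: float
    fdr: float = float("nan")
    flagged: bool = False


def _regions_with_motif(regions, motif, genome) -> int:
    n = 0
    for iv in regions:
        sub = str(genome[iv.chrom][iv.start:iv.end])
        if motif.iupac is not None:
            found = bool(
                _iupac_regex(motif.iupac.upper()).search(sub.upper())
                or _iupac_regex(reverse_complement(motif.iupac).upper()).search(sub.upper())
            )
        else:
            found = bool(_scan_seq_pcm(sub, motif, iv.chrom, iv.start))
        n += found
    return n


def binomial_tail_p(k: int, n: int, rate: float) -> float:
    """Upper-tail binomial p-value P(X >= k), X ~ Binomial(n, rate)."""
    if rate <= 0:
        return 1.0 if k <= 0 else 0.0
    return float(binom.sf(k - 1, n, min(rate, 1.0)))


def enrich_motifs(
    targets: Sequence[GenomicInterval],
    background: Sequence[GenomicInterval],
    motifs: Sequence[Motif],
    genome: Mapping[str, str],
) -> List[EnrichmentResult]:
    """Binomial known-motif enrichment of targets against a background set.

    Per motif: p = P(X >= n_target_with) with X ~ Binomial(n_target,
    n_bg_with/n_bg); a zero background rate with target hits is floored at
    1/(n_bg+1) and flagged.  Results are BH-adjusted across motifs and ranked
    by p.
    """
    if not targets:
        raise ValueError("empty target set")
    if len(background) < len(targets):
        raise ValueError("background must be at least as large as targets")
    results = []
    for motif in motifs:
        k = _regions_with_motif(targets, motif, genome)
        kb = _regions_with_motif(background, motif, genome)
        n, nb = len(targets), len(background)
        flagged = False
        bg_rate = kb / nb
        if kb == 0 and k > 0:
            bg_rate = 1.0 / (nb + 1)
            flagged = True
        p = binomial_tail_p(k, n, bg_rate)
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        target_rate = k / n
        fold = (target_rate / bg_rate) if bg_rate > 0 else float("inf")
        results.append(EnrichmentResult(motif.motif_id, k, n, kb, nb, fold, p,
                                        flagged=flagged))
    if results:
        fdrs = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        results = [
            EnrichmentResult(r.motif_id, r.n_target_with, r.n_target, r.n_bg_with,
                             r.n_bg, r.fold, r.p_value, float(f), r.flagged)
            for r, f in zip(results, fdrs)
        ]
    return sorted(results, key=lambda r: r.p_value)


def read_homer_motifs(path) -> List[Motif]:
    """Read HOMER-style .motif text: '>consensus name threshold' + A C G T rows."""
    motifs: List[Motif] = []
    name, thresh, rows = None, None, []
    def flush():
        if name is not None and rows:
            motifs.append(Motif(name, pcm=np.array(rows), score_threshold=thresh))
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split()
                name = parts[1] if len(parts) > 1 else parts[0]
                thresh = float(parts[2]) if len(parts) > 2 else 0.0
                rows = []
            else:
                rows.append([float(x) for x in line.split()])
    flush()
    return motifs
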