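"""PWM motif scanning, enrichment testing, and paired-motif spacing.

Scoring is standard log-odds: score(window) = sum_i log2(p_i(b_i) / q(b_i))
over motif positions i, with background q (uniform by default, or genome
composition).  Both strands are scanned; a window is reported when its score
reaches ``threshold_fraction`` of the maximum achievable score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .io import BASES, GenomicInterval, PWMRecord
from .peaks import Peak

__all__ = [
    "MotifOccurrence",
    "EnrichmentResult",
    "SpacingDistribution",
    "scan_pwm",
    "scan_peaks",
    "motif_enrichment",
    "motif_spacing",
    "genome_background",
    "reverse_complement",
]

_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class MotifOccurrence:
    """A scored PWM hit inside a scanned sequence or peak."""

    motif_id: str
    peak_id: str | None
    interval: GenomicInterval
    strand: str
    score: float
    score_fraction: float

    @property
    def center(self) -> int:
        return (self.interval.start + self.interval.end) // 2


@dataclass(frozen=True)
class EnrichmentResult:
    motif_id: str
    n_fg_with: int
    n_fg: int
    n_bg_with: int
    n_bg: int
    fold_enrichment: float
    p_value: float


@dataclass
class SpacingDistribution:
    """Center-to-center distances of two motifs within the same peaks."""

    pair: tuple[str, str]
    distances: list[int]
    bin_width: int
    histogram: np.ndarray = field(default=None)  # type: ignore[assignment]
    bin_edges: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.histogram is None:
            hi = (max(self.distances) // self.bin_width + 1) * self.bin_width \
                if self.distances else self.bin_width
            edges = np.arange(0, hi + self.bin_width, self.bin_width)
            self.histogram, self.bin_edges = np.histogram(self.distances,
                                                          bins=edges)

    def mode_bin(self) -> tuple[int, int] | None:
        """(lo, hi) of the most populated distance bin; None when empty."""
        if not self.distances:
            return None
        i = int(np.argmax(self.histogram))
        return int(self.bin_edges[i]), int(self.bin_edges[i + 1])


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _log_odds(pwm: PWMRecord, background: np.ndarray) -> np.ndarray:
    return np.log2(pwm.matrix / background[None, :])


def genome_background(sequences: Mapping[str, str]) -> np.ndarray:
    """Per-base (ACGT) frequencies over a sequence set, ignoring N."""
    counts = np.zeros(4)
    for seq in sequences.values():
        enc = _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]
        counts += np.bincount(enc[enc < 4], minlength=4)[:4]
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


def scan_pwm(sequence: str, pwm: PWMRecord,
             background: np.ndarray | None = None,
             threshold_fraction: float = 0.8,
             chrom: str = ".", offset: int = 0,
             peak_id: str | None = None) -> list[MotifOccurrence]:
    """Scan both strands of ``sequence`` for occurrences of ``pwm``.

    A window is reported when score >= threshold_fraction * max_score, where
    max_score is the best achievable log-odds sum.  The reverse strand
    scores the reverse complement of each window.  Windows containing N are
    skipped; when both strands pass at the same position only the
    higher-scoring strand is kept (forward on ties).  Reported coordinates
    are ``offset`` + window position, on chromosome ``chrom``.
    """
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must be in (0, 1]")
    L = len(pwm)
    n = len(sequence)
    if n < L:
        return []
    bg = np.full(4, 0.25) if background is None else np.asarray(background,
                                                                dtype=float)
    lo = _log_odds(pwm, bg)
    # reverse-strand matrix: scoring the reverse complement of a window with
    # lo equals scoring the window itself with lo flipped in both axes
    lo_rc = lo[::-1, ::-1]
    max_score = float(lo.max(axis=1).sum())
    threshold = threshold_fraction * max_score

    enc = _ENC[np.frombuffer(sequence.encode(), dtype=np.uint8)].astype(np.intp)
    n_win = n - L + 1
    has_n = np.convolve((enc == 4).astype(int), np.ones(L, dtype=int),
                        mode="valid") > 0
    # pad score lookup with a column for N so indexing stays valid
    lo_p = np.hstack([lo, np.zeros((L, 1))])
    lo_rc_p = np.hstack([lo_rc, np.zeros((L, 1))])
    fwd = np.zeros(n_win)
    rev = np.zeros(n_win)
    for i in range(L):
        col = enc[i:i + n_win]
        fwd += lo_p[i, col]
        rev += lo_rc_p[i, col]

    occs: list[MotifOccurrence] = []
    hit_f = (fwd >= threshold) & ~has_n
    hit_r = (rev >= threshold) & ~has_n
    for pos in np.nonzero(hit_f | hit_r)[0]:
        if hit_f[pos] and (not hit_r[pos] or fwd[pos] >= rev[pos]):
            strand, score = "+", float(fwd[pos])
        else:
            strand, score = "-", float(rev[pos])
        frac = score / max_score if max_score != 0 else 1.0
        occs.append(MotifOccurrence(
            pwm.motif_id, peak_id,
            GenomicInterval(chrom, offset + int(pos), offset + int(pos) + L,
                            strand),
            strand, score, frac))
    return occs


def scan_peaks(genome: Mapping[str, str], peaks: Sequence[Peak],
               pwms: Sequence[PWMRecord],
               background: np.ndarray | None = None,
               threshold_fraction: float = 0.8) -> list[MotifOccurrence]:
    """Scan every peak's sequence for every motif, in genomic coordinates."""
    occs: list[MotifOccurrence] = []
    for p in peaks:
        chrom_seq = genome.get(p.interval.chrom)
        if chrom_seq is None:
            raise KeyError(f"peak {p.peak_id}: chromosome "
                           f"{p.interval.chrom!r} not in genome")
        start = p.interval.start
        seq = chrom_seq[start:min(p.interval.end, len(chrom_seq))]
        for pwm in pwms:
            occs.extend(scan_pwm(seq, pwm, background, threshold_fraction,
                                 chrom=p.interval.chrom, offset=start,
                                 peak_id=p.peak_id))
    return occs


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def motif_enrichment(fg_peak_ids: Iterable[str], bg_peak_ids: Iterable[str],
                     occurrences: Sequence[MotifOccurrence],
                     ) -> list[EnrichmentResult]:
    """Known-motif enrichment of a foreground peak set against a background.

    A peak "has" a motif when it carries at least one occurrence.  The
    p-value is the upper-tail hypergeometric probability of drawing at least
    the observed number of motif-positive peaks when n_fg peaks are drawn
    from the pooled fg+bg universe.
    """
    fg = set(fg_peak_ids)
    bg = set(bg_peak_ids)
    if fg & bg:
        raise ValueError(f"foreground and background overlap: "
                         f"{sorted(fg & bg)[:5]}")
    with_motif: dict[str, set[str]] = {}
    for occ in occurrences:
        if occ.peak_id is not None:
            with_motif.setdefault(occ.motif_id, set()).add(occ.peak_id)

    results = []
    n_fg, n_bg = len(fg), len(bg)
    for motif_id in sorted(with_motif):
        pos = with_motif[motif_id]
        k_fg = len(pos & fg)
        k_bg = len(pos & bg)
        if n_fg == 0 or n_bg == 0:
            raise ValueError("foreground and background must be non-empty")
        fg_rate = k_fg / n_fg
        bg_rate = k_bg / n_bg
        fold = math.inf if bg_rate == 0 else fg_rate / bg_rate
        p = float(hypergeom.sf(k_fg - 1, n_fg + n_bg, k_fg + k_bg, n_fg))
        results.append(EnrichmentResult(motif_id, k_fg, n_fg, k_bg, n_bg,
                                        fold, p))
    return results


# ---------------------------------------------------------------------------
# Spacing
# ---------------------------------------------------------------------------

def motif_spacing(occ_a: Sequence[MotifOccurrence],
                  occ_b: Sequence[MotifOccurrence],
                  bin_width: int = 5,
                  best_pair: bool = False) -> SpacingDistribution:
    """Center-to-center distances between two motifs within shared peaks.

    For every peak containing at least one occurrence of each motif, all
    cross pairs contribute |centerA - centerB| (motif centers are
    floor((start + end) / 2)).  With ``best_pair`` only the highest-scoring
    occurrence of each motif per peak contributes one distance.
    """
    by_peak_a: dict[str, list[MotifOccurrence]] = {}
    for o in occ_a:
        if o.peak_id is not None:
            by_peak_a.setdefault(o.peak_id, []).append(o)
    by_peak_b: dict[str, list[MotifOccurrence]] = {}
    for o in occ_b:
        if o.peak_id is not None:
            by_peak_b.setdefault(o.peak_id, []).append(o)

    name_a = occ_a[0].motif_id if occ_a else "A"
    name_b = occ_b[0].motif_id if occ_b else "B"
    distances: list[int] = []
    for pid in sorted(set(by_peak_a) & set(by_peak_b)):
        aa, bb = by_peak_a[pid], by_peak_b[pid]
        if best_pair:
            aa = [max(aa, key=lambda o: (o.score, -o.interval.start))]
            bb = [max(bb, key=lambda o: (o.score, -o.interval.start))]
        for oa in aa:
            for ob in bb:
                distances.append(abs(oa.center - ob.center))
    return SpacingDistribution((name_a, name_b), distances, bin_width)
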