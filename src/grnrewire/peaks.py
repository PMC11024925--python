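"""Peak-level processing: unions, normalization, differential fold rules,
promoter proximity, and ranked tag-density matrices.

Two union-building conventions are supported, mirroring the two assay styles
the fold rules come from: DNase-style unions extend the peak interval ends
(default 200 bp) and call 3-fold differences; ChIP-style unions extend a
fixed window around the summit (default 100 bp) and call 2-fold differences.
Both extensions and thresholds are parameters, never hard-coded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import GenomicInterval, TSS

__all__ = [
    "Peak",
    "DifferentialCall",
    "DensityMatrix",
    "build_peak_union",
    "filter_low_summit",
    "normalize_tag_counts",
    "classify_differential",
    "annotate_promoter_proximal",
    "density_matrix",
]

logger = logging.getLogger(__name__)

LABEL_A = "specific_to_A"
LABEL_B = "specific_to_B"
LABEL_UNCHANGED = "unchanged"


@dataclass
class Peak:
    """A genomic peak: interval, summit, and per-sample tag counts."""

    peak_id: str
    interval: GenomicInterval
    summit: int
    counts: dict[str, float] = field(default_factory=dict)
    normalized: dict[str, float] | None = None
    summit_counts: dict[str, float] | None = None
    members: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"{self.peak_id}: summit {self.summit} outside "
                f"[{self.interval.start}, {self.interval.end})")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError(f"{self.peak_id}: negative tag count")
        if not self.members:
            self.members = [self.peak_id]

    @property
    def total_count(self) -> float:
        return float(sum(self.counts.values()))

    def summit_count(self) -> float:
        """Reads at the summit: max over samples (counts used as fallback)."""
        src = self.summit_counts if self.summit_counts is not None else self.counts
        return max(src.values(), default=0.0)


@dataclass(frozen=True)
class DifferentialCall:
    peak_id: str
    fold_change: float            # condition A over condition B, pseudocounted
    label: str                    # specific_to_A | specific_to_B | unchanged
    threshold_used: float
    mean_a: float = 0.0
    mean_b: float = 0.0


@dataclass
class DensityMatrix:
    """Per-peak binned tag density in a window centered on each summit,
    rows ordered by non-increasing fold change."""

    peak_ids: list[str]
    fold_changes: list[float]
    values: np.ndarray            # (n_peaks, window // bin)
    window: int
    bin_size: int


# ---------------------------------------------------------------------------
# Union construction
# ---------------------------------------------------------------------------

def _extended(peak: Peak, extension: int, mode: str) -> tuple[int, int]:
    if mode == "chip":
        start = peak.summit - extension
        end = peak.summit + extension
    else:  # dnase/atac: extend interval ends
        start = peak.interval.start - extension
        end = peak.interval.end + extension
    return max(0, start), end


def build_peak_union(peak_sets: Sequence[Sequence[Peak]], extension: int,
                     mode: str = "dnase") -> list[Peak]:
    """Merge extended peaks from all input sets into a single union.

    ``mode='chip'`` extends a fixed window either side of the summit;
    ``mode='dnase'`` (also used for ATAC) extends the interval ends.
    Overlapping or book-ended extended intervals on the same chromosome
    merge; the merged summit is the summit of the member with the highest
    raw count (leftmost on ties), per-sample counts are summed over members,
    and member peak ids are retained as provenance.
    """
    if extension < 0:
        raise ValueError("extension must be >= 0 (0 merges without "
                         "extending)")
    if mode not in ("dnase", "chip", "atac"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "atac":
        mode = "dnase"

    all_peaks = [p for ps in peak_sets for p in ps]
    if not all_peaks:
        return []
    ext = sorted(
        ((p.interval.chrom, *_extended(p, extension, mode), p)
         for p in all_peaks),
        key=lambda t: (t[0], t[1], t[2], t[3].peak_id))

    union: list[Peak] = []
    cluster: list[tuple[int, int, Peak]] = []

    def flush(chrom: str):
        if not cluster:
            return
        start = min(s for s, _, _ in cluster)
        end = max(e for _, e, _ in cluster)
        members = [p for _, _, p in cluster]
        best = max(members, key=lambda p: (p.total_count, -p.summit))
        counts: dict[str, float] = {}
        summit_counts: dict[str, float] = {}
        has_sc = False
        for p in members:
            for s, v in p.counts.items():
                counts[s] = counts.get(s, 0.0) + v
            if p.summit_counts is not None:
                has_sc = True
                for s, v in p.summit_counts.items():
                    summit_counts[s] = summit_counts.get(s, 0.0) + v
        member_ids = sorted(m for p in members for m in p.members)
        pid = members[0].peak_id if len(members) == 1 else ";".join(member_ids)
        union.append(Peak(pid, GenomicInterval(chrom, start, end),
                          best.summit, counts,
                          summit_counts=summit_counts if has_sc else None,
                          members=member_ids))

    cur_chrom = None
    cur_end = -1
    for chrom, start, end, peak in ext:
        if chrom != cur_chrom or start > cur_end:
            flush(cur_chrom)
            cluster = []
            cur_chrom, cur_end = chrom, end
        cur_end = max(cur_end, end)
        cluster.append((start, end, peak))
    flush(cur_chrom)
    return union


# ---------------------------------------------------------------------------
# Filtering and normalization
# ---------------------------------------------------------------------------

def filter_low_summit(peaks: Sequence[Peak], min_reads: float = 10) -> list[Peak]:
    """Drop peaks with fewer than ``min_reads`` reads at the summit.

    The comparison is strict ("less than"), so a peak with exactly
    ``min_reads`` is kept.
    """
    kept = [p for p in peaks if p.summit_count() >= min_reads]
    removed = len(peaks) - len(kept)
    if removed:
        logger.info("filter_low_summit: removed %d of %d peaks (< %g reads "
                    "at summit)", removed, len(peaks), min_reads)
    return kept


def normalize_tag_counts(
        peaks: Sequence[Peak],
        library_totals: Mapping[str, float] | None = None,
) -> tuple[list[Peak], dict[str, float]]:
    """Tags-per-million normalization.

    The divisor per sample is the supplied library total when given,
    otherwise the per-sample sum of raw counts over the union.  Returns the
    normalized peaks and the divisors actually used.
    """
    samples = sorted({s for p in peaks for s in p.counts})
    if library_totals is not None:
        totals = {s: float(library_totals[s]) for s in samples}
    else:
        totals = {s: float(sum(p.counts.get(s, 0.0) for p in peaks))
                  for s in samples}
    for s, tot in totals.items():
        if tot <= 0:
            raise ValueError(f"zero tag total for sample {s!r}")
    out = []
    for p in peaks:
        norm = {s: v * 1e6 / totals[s] for s, v in p.counts.items()}
        out.append(replace(p, normalized=norm))
    return out, totals


# ---------------------------------------------------------------------------
# Differential fold rule
# ---------------------------------------------------------------------------

def classify_differential(peaks: Sequence[Peak],
                          cond_a_samples: Sequence[str],
                          cond_b_samples: Sequence[str],
                          fold_threshold: float,
                          pseudocount: float = 1.0,
                          use_normalized: bool = True) -> list[DifferentialCall]:
    """Classify peaks by the simple fold rule.

    For each peak the per-condition value is the arithmetic mean over that
    condition's samples; the fold change is (A + c) / (B + c) with
    pseudocount c.  A peak is specific to A iff fold >= k, specific to B iff
    fold <= 1/k, else unchanged.  k = 3 reproduces the DNase-style rule,
    k = 2 the ChIP/ATAC-style rule.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    a_set, b_set = set(cond_a_samples), set(cond_b_samples)
    if not a_set or not b_set:
        raise ValueError("both condition sample sets must be non-empty")
    if a_set & b_set:
        raise ValueError(f"condition sample sets overlap: {sorted(a_set & b_set)}")

    calls = []
    for p in peaks:
        src = p.normalized if use_normalized else p.counts
        if src is None:
            raise ValueError(f"{p.peak_id}: normalized counts requested but "
                             "not computed")
        mean_a = float(np.mean([src.get(s, 0.0) for s in cond_a_samples]))
        mean_b = float(np.mean([src.get(s, 0.0) for s in cond_b_samples]))
        denom = mean_b + pseudocount
        if denom == 0:
            raise ValueError(
                f"{p.peak_id}: zero denominator with pseudocount 0; supply a "
                "positive pseudocount")
        fold = (mean_a + pseudocount) / denom
        if fold >= fold_threshold:
            label = LABEL_A
        elif fold <= 1.0 / fold_threshold:
            label = LABEL_B
        else:
            label = LABEL_UNCHANGED
        calls.append(DifferentialCall(p.peak_id, fold, label, fold_threshold,
                                      mean_a, mean_b))
    return calls


# ---------------------------------------------------------------------------
# Promoter proximity
# ---------------------------------------------------------------------------

def annotate_promoter_proximal(peaks: Sequence[Peak],
                               tss_catalog: Sequence[TSS],
                               max_distance: int = 1500) -> dict[str, str]:
    """Label each peak proximal/distal by summit-to-nearest-TSS distance.

    Proximal iff the minimum distance to any TSS is <= ``max_distance``
    (default 1.5 kb); strictly greater is distal.
    """
    if not tss_catalog:
        raise ValueError("tss_catalog must be non-empty")
    by_chrom: dict[str, np.ndarray] = {}
    for t in tss_catalog:
        by_chrom.setdefault(t.chrom, []).append(t.pos)  # type: ignore[arg-type]
    by_chrom = {c: np.sort(np.asarray(v)) for c, v in by_chrom.items()}

    out = {}
    for p in peaks:
        pos = by_chrom.get(p.interval.chrom)
        if pos is None or len(pos) == 0:
            out[p.peak_id] = "distal"
            continue
        i = int(np.searchsorted(pos, p.summit))
        d = min(
            abs(p.summit - pos[j]) for j in (i - 1, i) if 0 <= j < len(pos))
        out[p.peak_id] = "proximal" if d <= max_distance else "distal"
    return out


# ---------------------------------------------------------------------------
# Ranked tag-density matrices
# ---------------------------------------------------------------------------

def density_matrix(peaks: Sequence[Peak],
                   fold_by_peak: Mapping[str, float],
                   coverage: Mapping[str, np.ndarray],
                   window: int = 2000,
                   bin_size: int = 10) -> DensityMatrix:
    """Binned per-bp tag density around each summit, ranked by fold change.

    Each row sums ``coverage`` over fixed-width bins across
    [summit - window/2, summit + window/2); positions beyond either end of
    the chromosome contribute 0.  Rows are ordered by descending fold change
    (ties broken by peak id) — the convention behind ranked ChIP/ATAC
    heatmaps.
    """
    if window % bin_size != 0:
        raise ValueError("window must be divisible by bin size")
    n_bins = window // bin_size
    order = sorted(peaks,
                   key=lambda p: (-fold_by_peak.get(p.peak_id, 0.0), p.peak_id))
    mat = np.zeros((len(order), n_bins))
    half = window // 2
    for ri, p in enumerate(order):
        cov = coverage.get(p.interval.chrom)
        if cov is None:
            continue
        w0 = p.summit - half
        lo = max(0, w0)
        hi = min(len(cov), w0 + window)
        if hi <= lo:
            continue
        row = np.zeros(window)
        row[lo - w0:hi - w0] = cov[lo:hi]
        mat[ri] = row.reshape(n_bins, bin_size).sum(axis=1)
    return DensityMatrix([p.peak_id for p in order],
                         [float(fold_by_peak.get(p.peak_id, 0.0))
                          for p in order],
                         mat, window, bin_size)
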