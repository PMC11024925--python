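"""Peak-to-gene assignment: promoter-capture HiC links first, closest TSS
as the fallback, so that every peak ends up annotated to at least one gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import ChromatinLink, TSS
from .peaks import Peak

__all__ = [
    "GeneAssignment",
    "assign_genes_hic",
    "assign_closest_gene",
    "annotate_peaks",
]


@dataclass(frozen=True)
class GeneAssignment:
    peak_id: str
    genes: frozenset[str]
    method: str                   # "hic" | "closest" | "unassigned"
    distance: int | None = None   # summit-to-TSS bp, closest method only

    def __post_init__(self):
        if self.method not in ("hic", "closest", "unassigned"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method != "unassigned" and not self.genes:
            raise ValueError(f"{self.peak_id}: empty gene set")


def assign_genes_hic(peaks: Sequence[Peak],
                     links: Sequence[ChromatinLink]) -> list[GeneAssignment]:
    """Assign genes whose HiC anchors overlap the peak by >= 1 bp.

    A peak overlapping anchors of several genes receives all of them; peaks
    overlapping no anchor are absent from the result.  The whole peak
    interval (not just the summit) is tested, since HiC anchors are
    typically wide restriction fragments.
    """
    by_chrom: dict[str, list[ChromatinLink]] = {}
    for lk in links:
        by_chrom.setdefault(lk.anchor.chrom, []).append(lk)

    out = []
    for p in peaks:
        genes = {lk.gene for lk in by_chrom.get(p.interval.chrom, ())
                 if p.interval.overlaps(lk.anchor)}
        if genes:
            out.append(GeneAssignment(p.peak_id, frozenset(genes), "hic"))
    return out


def assign_closest_gene(peaks: Sequence[Peak],
                        tss_catalog: Sequence[TSS],
                        max_distance: int | None = None) -> list[GeneAssignment]:
    """Assign each peak the gene with the nearest TSS to its summit.

    Distance is |summit - TSS| minimized over all TSSs on the peak's
    chromosome; equidistant candidates resolve to the lexicographically
    smallest gene id.  With ``max_distance`` set, peaks farther than the cap
    from every TSS are labelled unassigned instead.
    """
    if not tss_catalog:
        raise ValueError("tss_catalog must be non-empty")
    by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    for chrom in {t.chrom for t in tss_catalog}:
        entries = sorted((t.pos, t.gene) for t in tss_catalog
                         if t.chrom == chrom)
        by_chrom[chrom] = (np.array([e[0] for e in entries]),
                           [e[1] for e in entries])

    out = []
    for p in peaks:
        entry = by_chrom.get(p.interval.chrom)
        if entry is None:
            out.append(GeneAssignment(p.peak_id, frozenset(), "unassigned"))
            continue
        pos, genes = entry
        dists = np.abs(pos - p.summit)
        best = int(dists.min())
        if max_distance is not None and best > max_distance:
            out.append(GeneAssignment(p.peak_id, frozenset(), "unassigned"))
            continue
        gene = min(genes[i] for i in np.nonzero(dists == best)[0])
        out.append(GeneAssignment(p.peak_id, frozenset([gene]), "closest",
                                  best))
    return out


def annotate_peaks(peaks: Sequence[Peak], links: Sequence[ChromatinLink],
                   tss_catalog: Sequence[TSS],
                   max_distance: int | None = None) -> list[GeneAssignment]:
    """HiC-first total annotation: link-supported genes where a peak overlaps
    any anchor, closest TSS for every remaining peak."""
    hic = {a.peak_id: a for a in assign_genes_hic(peaks, links)}
    remaining = [p for p in peaks if p.peak_id not in hic]
    closest = {a.peak_id: a
               for a in assign_closest_gene(remaining, tss_catalog,
                                            max_distance)}
    return [hic.get(p.peak_id) or closest[p.peak_id] for p in peaks]
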