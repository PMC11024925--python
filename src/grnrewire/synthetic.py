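"""Synthetic regulatory landscapes with a planted truth network.

The generator emulates the data shapes the pipeline consumes: a random
genome, non-overlapping accessibility peaks with condition-dependent
negative-binomial tag counts, exact consensus motif instances planted inside
peaks, promoter-capture HiC links wiring a subset of peaks to gene
promoters, a TSS catalog for closest-gene fallback, and two-condition
expression tables.  Every planted regulatory edge (TF family -> gene) is
physically realized: a peak that carries the family's motif, is annotated to
the target gene (by link or closest TSS), and is condition-specific exactly
when the edge is.  At zero noise the downstream pipeline must therefore
recover the truth networks exactly; the manifest records every planted
element for that comparison.

Two construction rules keep the truth bookkeeping exact: peaks are planted
far enough apart that union extension can never merge two planted peaks, and
accidental exact consensus matches elsewhere in the random genome are
mutated away ("scrubbed"), so a consensus-like PWM scan finds planted
instances and nothing else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as gio
from .annotation import assign_closest_gene
from .io import BASES, ChromatinLink, GenomicInterval, PWMRecord, TSS
from .motifs import MotifOccurrence, reverse_complement
from .peaks import Peak

__all__ = [
    "SimulationParams",
    "SyntheticLandscape",
    "ParameterError",
    "CapacityError",
    "generate_genome",
    "plant_regulatory_landscape",
    "simulate_tag_counts",
    "simulate_expression",
    "generate_landscape",
    "write_landscape",
    "simulate_spacing_occurrences",
    "nb_draw",
]

MOTIF_LENGTH = 10
PEAK_WIDTH = 400
MAX_EXTENSION = 200          # largest union extension the pipeline applies
CHROM_MARGIN = 1000
DECOY_SPECIFIC_FRACTION = 0.1  # per direction, of non-edge peaks


class ParameterError(ValueError):
    pass


class CapacityError(RuntimeError):
    """The requested landscape does not fit in the genome."""


@dataclass
class SimulationParams:
    """Knobs of the synthetic landscape.

    Defaults describe a two-condition accessibility experiment at desk
    scale: a 2 x 2 Mb genome, 5 TF families of 3 members, 200 genes, 1,000
    peaks at mean depth 100 tags with NB dispersion 10 (variance =
    mu + mu^2/size), 4-fold planted accessibility changes (comfortably
    above the 3-fold calling rule), and 0.25 log2 units of expression noise.
    ``nb_dispersion=inf`` is the zero-noise sentinel: counts become their
    deterministic means.
    """

    n_chromosomes: int = 2
    chromosome_length: int = 2_000_000
    gc_fraction: float = 0.41
    n_tf_families: int = 5
    members_per_family: int = 3
    n_genes: int = 200
    n_peaks: int = 1000
    edge_density: float = 0.15
    hic_link_fraction: float = 0.6
    rewired_fraction: float = 0.3
    sequencing_depth: float = 100.0
    nb_dispersion: float = 10.0
    planted_fold_change: float = 4.0
    expression_noise_sd: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_chromosomes", "n_tf_families", "members_per_family",
                     "n_genes", "n_peaks", "chromosome_length"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1, got "
                                     f"{getattr(self, name)}")
        for name in ("gc_fraction", "edge_density", "hic_link_fraction",
                     "rewired_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.planted_fold_change < 1:
            raise ParameterError("planted_fold_change must be >= 1, got "
                                 f"{self.planted_fold_change}")
        if self.sequencing_depth < 0:
            raise ParameterError("sequencing_depth must be >= 0")
        if self.expression_noise_sd < 0:
            raise ParameterError("expression_noise_sd must be >= 0")
        if not (self.nb_dispersion > 0):
            raise ParameterError("nb_dispersion must be > 0 (inf disables "
                                 "noise)")

    @property
    def n_truth_edges(self) -> int:
        return round(self.edge_density * self.n_tf_families * self.n_genes)


@dataclass(frozen=True)
class PlantedEdge:
    family: str
    gene: str
    condition: str               # A_specific | B_specific | shared
    peak_id: str


@dataclass
class SyntheticLandscape:
    params: SimulationParams
    genome: dict[str, str]
    tss_catalog: list[TSS] = field(default_factory=list)
    families: dict[str, list[str]] = field(default_factory=dict)
    representatives: dict[str, str] = field(default_factory=dict)
    consensi: dict[str, str] = field(default_factory=dict)
    pwms: list[PWMRecord] = field(default_factory=list)
    pwm_counts: dict[str, np.ndarray] = field(default_factory=dict)
    peaks: list[Peak] = field(default_factory=list)
    peak_labels: dict[str, str] = field(default_factory=dict)
    truth_edges: list[PlantedEdge] = field(default_factory=list)
    motif_placements: list[dict] = field(default_factory=list)
    hic_links: list[ChromatinLink] = field(default_factory=list)
    counts: pd.DataFrame | None = None
    expression_a: dict[str, float] = field(default_factory=dict)
    expression_b: dict[str, float] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    @property
    def truth_network_a(self) -> set[tuple[str, str]]:
        return {(e.family, e.gene) for e in self.truth_edges
                if e.condition in ("A_specific", "shared")}

    @property
    def truth_network_b(self) -> set[tuple[str, str]]:
        return {(e.family, e.gene) for e in self.truth_edges
                if e.condition in ("B_specific", "shared")}

    def motif_by_family(self) -> dict[str, str]:
        return {p.family: p.motif_id for p in self.pwms}


def _rng(params: SimulationParams, stage: int) -> np.random.Generator:
    return np.random.default_rng([params.seed, stage])


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def generate_genome(params: SimulationParams) -> dict[str, str]:
    """Random genome with the requested GC content (in expectation)."""
    params.validate()
    rng = _rng(params, 0)
    gc = params.gc_fraction
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = {}
    for c in range(params.n_chromosomes):
        draws = rng.choice(4, size=params.chromosome_length, p=probs)
        genome[f"chr{c + 1}"] = base_bytes[draws].tobytes().decode()
    return genome


# ---------------------------------------------------------------------------
# Landscape planting
# ---------------------------------------------------------------------------

def _draw_consensi(rng: np.random.Generator, n: int) -> list[str]:
    """Distinct non-palindromic consensi, pairwise Hamming >= 4 including
    against reverse complements."""
    def hamming(a: str, b: str) -> int:
        return sum(x != y for x, y in zip(a, b))

    out: list[str] = []
    for _ in range(10_000):
        if len(out) == n:
            break
        cand = "".join(BASES[i]
                       for i in rng.integers(0, 4, size=MOTIF_LENGTH))
        rc = reverse_complement(cand)
        if rc == cand:
            continue
        ok = hamming(cand, rc) >= 4
        for prev in out:
            if not ok:
                break
            ok = min(hamming(cand, prev), hamming(cand,
                     reverse_complement(prev)),
                     hamming(rc, prev)) >= 4
        if ok:
            out.append(cand)
    if len(out) < n:
        raise CapacityError(f"could not draw {n} sufficiently distinct "
                            "consensi")
    return out


def _consensus_pfm(consensus: str, counts: int = 10) -> np.ndarray:
    raw = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        raw[i, BASES.index(b)] = counts
    return raw


def _place_peaks(rng: np.random.Generator,
                 params: SimulationParams) -> list[Peak]:
    slot = PEAK_WIDTH + 2 * MAX_EXTENSION + 20
    usable = params.chromosome_length - 2 * CHROM_MARGIN
    per_chrom = max(usable // slot, 0)
    if per_chrom * params.n_chromosomes < params.n_peaks:
        raise CapacityError(
            f"cannot fit {params.n_peaks} peaks: capacity is "
            f"{per_chrom * params.n_chromosomes} "
            f"({per_chrom} per chromosome at slot {slot} bp)")
    peaks = []
    chroms = [f"chr{c + 1}" for c in range(params.n_chromosomes)]
    for i in range(params.n_peaks):
        chrom = chroms[i % len(chroms)]
        slot_idx = i // len(chroms)
        start = CHROM_MARGIN + slot_idx * slot + int(rng.integers(0, 11))
        iv = GenomicInterval(chrom, start, start + PEAK_WIDTH)
        peaks.append(Peak(f"peak_{i:05d}", iv, start + PEAK_WIDTH // 2))
    return peaks


def _place_tss(rng: np.random.Generator, params: SimulationParams,
               genes: list[str]) -> list[TSS]:
    chroms = [f"chr{c + 1}" for c in range(params.n_chromosomes)]
    used: set[tuple[str, int]] = set()
    catalog = []
    for gene in genes:
        for _ in range(1000):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            pos = int(rng.integers(CHROM_MARGIN,
                                   params.chromosome_length - CHROM_MARGIN))
            if (chrom, pos) not in used:
                used.add((chrom, pos))
                break
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        catalog.append(TSS(gene, chrom, pos, strand))
    return catalog


def _scrub_genome(genome: dict[str, bytearray],
                  patterns: list[str],
                  allowed: set[tuple[str, int, str]],
                  planted_mask: dict[str, np.ndarray]) -> int:
    """Mutate accidental exact matches of any pattern away, leaving planted
    placements untouched.  Returns the number of mutations applied."""
    n_mut = 0
    for _ in range(50):
        dirty = False
        for chrom, seq in genome.items():
            hay = bytes(seq)
            for pat in patterns:
                needle = pat.encode()
                pos = hay.find(needle)
                while pos != -1:
                    if (chrom, pos, pat) not in allowed:
                        mask = planted_mask[chrom]
                        for off in range(len(pat)):
                            if not mask[pos + off]:
                                cur = BASES.index(chr(seq[pos + off]))
                                seq[pos + off] = ord(BASES[(cur + 1) % 4])
                                n_mut += 1
                                dirty = True
                                break
                        else:
                            raise RuntimeError(
                                "cannot scrub match overlapping only "
                                "planted positions")
                        hay = bytes(seq)
                    pos = hay.find(needle, pos + 1)
        if not dirty:
            return n_mut
    raise RuntimeError("genome scrubbing did not converge")


def plant_regulatory_landscape(genome: Mapping[str, str],
                               params: SimulationParams) -> SyntheticLandscape:
    """Plant peaks, TSSs, motifs, HiC links, and the truth network.

    Each truth edge gets a dedicated supporting peak carrying an exact
    consensus instance of the source family's motif; HiC-designated peaks
    are wired by a link (to the edge target when they support an edge, to
    their closest gene otherwise) and the rest rely on closest-TSS fallback,
    so closest-mode support peaks can only realize edges to their own
    closest gene.
    """
    params.validate()
    rng = _rng(params, 1)

    n_edges = params.n_truth_edges
    if n_edges > params.n_peaks:
        raise CapacityError(f"{n_edges} truth edges need at least as many "
                            f"peaks, have {params.n_peaks}")

    genes = [f"G{i:04d}" for i in range(params.n_genes)]
    fam_ids = [f"F{i}" for i in range(params.n_tf_families)]
    families = {f: [f"TF_{f}_{k}" for k in range(params.members_per_family)]
                for f in fam_ids}
    consensi = dict(zip(fam_ids, _draw_consensi(rng, params.n_tf_families)))

    peaks = _place_peaks(rng, params)
    tss_catalog = _place_tss(rng, params, genes)
    closest = {a.peak_id: next(iter(a.genes))
               for a in assign_closest_gene(peaks, tss_catalog)}

    n_hic = round(params.hic_link_fraction * params.n_peaks)
    hic_ids = {peaks[i].peak_id
               for i in rng.choice(params.n_peaks, size=n_hic, replace=False)}

    # --- truth edges, one dedicated supporting peak each -------------------
    free: dict[str, set[str]] = {f: set(genes) for f in fam_ids}
    order = rng.permutation(params.n_peaks)
    edge_records: list[tuple[str, str, str]] = []      # family, gene, peak
    for idx in order:
        if len(edge_records) == n_edges:
            break
        peak = peaks[idx]
        if peak.peak_id in hic_ids:
            candidates = [f for f in fam_ids if free[f]]
            if not candidates:
                break
            fam = candidates[int(rng.integers(0, len(candidates)))]
            pool = sorted(free[fam])
            gene = pool[int(rng.integers(0, len(pool)))]
        else:
            gene = closest[peak.peak_id]
            candidates = [f for f in fam_ids if gene in free[f]]
            if not candidates:
                continue
            fam = candidates[int(rng.integers(0, len(candidates)))]
        free[fam].discard(gene)
        edge_records.append((fam, gene, peak.peak_id))
    if len(edge_records) < n_edges:
        raise CapacityError(
            f"could only realize {len(edge_records)} of {n_edges} edges "
            "(increase n_peaks or lower edge_density)")

    # --- condition assignment ---------------------------------------------
    n_rewired = round(params.rewired_fraction * n_edges)
    n_gained = n_rewired - n_rewired // 2
    perm = rng.permutation(n_edges)
    condition_of = {}
    for rank, ei in enumerate(perm):
        if rank < n_gained:
            condition_of[ei] = "B_specific"
        elif rank < n_rewired:
            condition_of[ei] = "A_specific"
        else:
            condition_of[ei] = "shared"
    truth_edges = [PlantedEdge(f, g, condition_of[i], pid)
                   for i, (f, g, pid) in enumerate(edge_records)]

    # --- per-peak condition labels (edge peaks + specific decoys) ----------
    peak_labels = {p.peak_id: "unchanged" for p in peaks}
    for e in truth_edges:
        peak_labels[e.peak_id] = (e.condition if e.condition != "shared"
                                  else "unchanged")
    edge_peak_ids = {e.peak_id for e in truth_edges}
    decoys = [p.peak_id for p in peaks if p.peak_id not in edge_peak_ids]
    n_spec = round(DECOY_SPECIFIC_FRACTION * len(decoys))
    decoy_perm = rng.permutation(len(decoys))
    for rank, di in enumerate(decoy_perm):
        if rank < n_spec:
            peak_labels[decoys[di]] = "A_specific"
        elif rank < 2 * n_spec:
            peak_labels[decoys[di]] = "B_specific"

    # --- plant motif instances into the genome ----------------------------
    mutable = {c: bytearray(s, "ascii") for c, s in genome.items()}
    planted_mask = {c: np.zeros(len(s), dtype=bool) for c, s in genome.items()}
    placements = []
    allowed: set[tuple[str, int, str]] = set()
    peak_by_id = {p.peak_id: p for p in peaks}
    for e in truth_edges:
        peak = peak_by_id[e.peak_id]
        cons = consensi[e.family]
        pos = peak.interval.start + int(
            rng.integers(50, PEAK_WIDTH - 50 - MOTIF_LENGTH + 1))
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        seq = cons if strand == "+" else reverse_complement(cons)
        chrom = peak.interval.chrom
        mutable[chrom][pos:pos + MOTIF_LENGTH] = seq.encode()
        planted_mask[chrom][pos:pos + MOTIF_LENGTH] = True
        allowed.add((chrom, pos, seq))
        placements.append({"motif_id": f"M_{e.family}", "family": e.family,
                           "peak_id": e.peak_id, "chrom": chrom,
                           "start": pos, "end": pos + MOTIF_LENGTH,
                           "strand": strand})

    patterns = []
    for f in fam_ids:
        patterns.append(consensi[f])
        patterns.append(reverse_complement(consensi[f]))
    n_scrubbed = _scrub_genome(mutable, patterns, allowed, planted_mask)
    clean_genome = {c: s.decode() for c, s in mutable.items()}

    # --- HiC links ---------------------------------------------------------
    tss_by_gene = {t.gene: t for t in tss_catalog}
    link_gene = {e.peak_id: e.gene for e in truth_edges}
    links = []
    for p in peaks:
        if p.peak_id not in hic_ids:
            continue
        gene = link_gene.get(p.peak_id, closest[p.peak_id])
        t = tss_by_gene[gene]
        anchor = GenomicInterval(p.interval.chrom, p.interval.start + 50,
                                 p.interval.end - 50)
        promoter = GenomicInterval(t.chrom, max(0, t.pos - 500), t.pos + 500)
        links.append(ChromatinLink(anchor, promoter, gene))

    pwms = [PWMRecord(f"M_{f}", f,
                      gio._normalize_pfm(_consensus_pfm(consensi[f]), 0.01))
            for f in fam_ids]
    pwm_counts = {f"M_{f}": _consensus_pfm(consensi[f]) for f in fam_ids}

    land = SyntheticLandscape(
        params=params, genome=clean_genome, tss_catalog=tss_catalog,
        families=families,
        representatives={f: families[f][0] for f in fam_ids},
        consensi=consensi, pwms=pwms, pwm_counts=pwm_counts, peaks=peaks,
        peak_labels=peak_labels, truth_edges=truth_edges,
        motif_placements=placements, hic_links=links)
    land.manifest = {
        "params": vars(params),
        "n_truth_edges": n_edges,
        "n_scrubbed_matches": n_scrubbed,
        "edges": [vars(e) for e in truth_edges],
        "gained_edges": sorted([e.family, e.gene] for e in truth_edges
                               if e.condition == "B_specific"),
        "lost_edges": sorted([e.family, e.gene] for e in truth_edges
                             if e.condition == "A_specific"),
        "peak_labels": peak_labels,
        "hic_peaks": sorted(hic_ids),
        "motif_placements": placements,
        "consensi": consensi,
        "representatives": land.representatives,
    }
    return land


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def nb_draw(rng: np.random.Generator, mu: float, dispersion: float,
            size: int | None = None):
    """Negative-binomial draw(s) with variance mu + mu^2/dispersion.

    ``dispersion=inf`` is the deterministic sentinel: returns round(mu).
    """
    if mu < 0:
        raise ParameterError("mean must be >= 0")
    if math.isinf(dispersion):
        val = int(round(mu))
        return val if size is None else np.full(size, val, dtype=int)
    if mu == 0:
        return 0 if size is None else np.zeros(size, dtype=int)
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_tag_counts(landscape: SyntheticLandscape,
                        params: SimulationParams) -> pd.DataFrame:
    """Draw per-peak, per-condition tag counts from the planted means.

    Condition-specific peaks have mean depth x planted_fold_change in their
    condition and depth in the other; all other peaks have equal means.
    Counts are attached to the landscape's peaks (samples ``sample_A`` and
    ``sample_B``) and returned as a long table.
    """
    params.validate()
    rng = _rng(params, 2)
    depth, fold = params.sequencing_depth, params.planted_fold_change
    rows = []
    for p in landscape.peaks:
        label = landscape.peak_labels[p.peak_id]
        mu_a = depth * fold if label == "A_specific" else depth
        mu_b = depth * fold if label == "B_specific" else depth
        c_a = float(nb_draw(rng, mu_a, params.nb_dispersion))
        c_b = float(nb_draw(rng, mu_b, params.nb_dispersion))
        p.counts = {"sample_A": c_a, "sample_B": c_b}
        p.summit_counts = dict(p.counts)
        rows.append((p.peak_id, "sample_A", "A", c_a))
        rows.append((p.peak_id, "sample_B", "B", c_b))
    df = pd.DataFrame(rows, columns=["peak_id", "sample", "condition",
                                     "count"])
    landscape.counts = df
    return df


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(landscape: SyntheticLandscape,
                        params: SimulationParams
                        ) -> tuple[dict[str, float], dict[str, float]]:
    """Two-condition expression with planted family representatives and
    planted fold changes on rewired-edge targets.

    Within each family the designated representative (first member) is
    planted strictly highest.  Targets of B-specific (gained) edges carry
    +log2(planted_fold_change) in condition B; targets of A-specific (lost)
    edges carry it in condition A.  Gaussian noise of ``expression_noise_sd``
    is added on the log2 scale, independently per gene and condition; linear
    values are returned.
    """
    params.validate()
    rng = _rng(params, 3)
    log2_a: dict[str, float] = {}
    log2_b: dict[str, float] = {}

    for t in landscape.tss_catalog:
        base = float(rng.uniform(3, 8))
        log2_a[t.gene] = base
        log2_b[t.gene] = base
    for fam, members in landscape.families.items():
        top = float(rng.uniform(6, 9))
        for j, m in enumerate(members):
            log2_a[m] = top - 0.75 * j
            log2_b[m] = top - 0.75 * j

    shift = math.log2(params.planted_fold_change)
    for e in landscape.truth_edges:
        if e.condition == "B_specific":
            log2_b[e.gene] = log2_a[e.gene] + shift
        elif e.condition == "A_specific":
            log2_a[e.gene] = log2_b[e.gene] + shift

    sd = params.expression_noise_sd
    genes = sorted(log2_a)
    noise_a = rng.normal(0, sd, size=len(genes)) if sd > 0 else \
        np.zeros(len(genes))
    noise_b = rng.normal(0, sd, size=len(genes)) if sd > 0 else \
        np.zeros(len(genes))
    expr_a = {g: float(2.0 ** (log2_a[g] + noise_a[i]))
              for i, g in enumerate(genes)}
    expr_b = {g: float(2.0 ** (log2_b[g] + noise_b[i]))
              for i, g in enumerate(genes)}
    landscape.expression_a = expr_a
    landscape.expression_b = expr_b
    landscape.manifest["planted_log2fc"] = {
        g: log2_b[g] - log2_a[g] for g in genes
        if log2_b[g] != log2_a[g]}
    return expr_a, expr_b


def generate_landscape(params: SimulationParams) -> SyntheticLandscape:
    """Genome + planted landscape + counts + expression in one call."""
    genome = generate_genome(params)
    land = plant_regulatory_landscape(genome, params)
    simulate_tag_counts(land, params)
    simulate_expression(land, params)
    return land


# ---------------------------------------------------------------------------
# File export
# ---------------------------------------------------------------------------

def write_landscape(landscape: SyntheticLandscape,
                    out_dir: str | Path) -> dict[str, Path]:
    """Write every input file the pipeline reads, plus truth and manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in {
        "genome": "genome.fa", "peaks": "peaks.bed", "counts": "counts.tsv",
        "links": "links.bedpe", "tss": "tss.bed", "pfms": "motifs.jaspar",
        "expression": "expression.tsv", "families": "families.tsv",
        "truth_a": "truth_A.tsv", "truth_b": "truth_B.tsv",
        "manifest": "landscape.json"}.items()}

    gio.write_fasta(landscape.genome, paths["genome"])
    gio.write_bed([gio.BedRecord(p.interval, p.peak_id, p.total_count,
                                 summit=p.summit)
                   for p in landscape.peaks], paths["peaks"])
    if landscape.counts is not None:
        gio.write_counts_table(landscape.counts, paths["counts"])
    gio.write_bedpe_links(landscape.hic_links, paths["links"])
    gio.write_tss(landscape.tss_catalog, paths["tss"])
    with open(paths["pfms"], "w") as fh:   # JASPAR-style count matrices
        for pwm in landscape.pwms:
            counts = landscape.pwm_counts[pwm.motif_id]
            fh.write(f">{pwm.motif_id} {pwm.family}\n")
            for bi, base in enumerate(BASES):
                vals = " ".join(gio.fmt(v) for v in counts[:, bi])
                fh.write(f"{base} [ {vals} ]\n")
    expr = pd.DataFrame({"expr_A": pd.Series(landscape.expression_a),
                         "expr_B": pd.Series(landscape.expression_b)})
    gio.write_expression_table(
        gio.ExpressionTable(expr, {"expr_A": "A", "expr_B": "B"}),
        paths["expression"])
    gio.write_family_table(landscape.families, paths["families"])
    for cond, path in (("a", paths["truth_a"]), ("b", paths["truth_b"])):
        edges = (landscape.truth_network_a if cond == "a"
                 else landscape.truth_network_b)
        with open(path, "w") as fh:
            fh.write("source\ttarget\n")
            for s, t in sorted(edges):
                fh.write(f"{s}\t{t}\n")
    gio.write_json(landscape.manifest, paths["manifest"])
    return paths


# ---------------------------------------------------------------------------
# Spacing simulation (occurrence level)
# ---------------------------------------------------------------------------

def simulate_spacing_occurrences(
        n_peaks: int = 30, spacing: int = 35, decoys_per_peak: int = 2,
        peak_width: int = 400, motif_length: int = MOTIF_LENGTH,
        seed: int = 0) -> tuple[list[MotifOccurrence], list[MotifOccurrence]]:
    """Planted fixed-spacing motif pairs plus uniformly placed decoys.

    Each synthetic peak carries one A occurrence at a random position and
    one B occurrence exactly ``spacing`` bp downstream (center to center),
    plus ``decoys_per_peak`` uniformly positioned B decoys — the null
    against which spacing-mode recovery is measured.
    """
    rng = np.random.default_rng(seed)
    occ_a: list[MotifOccurrence] = []
    occ_b: list[MotifOccurrence] = []

    def occ(motif, pid, start):
        return MotifOccurrence(
            motif, pid, GenomicInterval("chr1", start, start + motif_length,
                                        "+"), "+", 1.0, 1.0)

    for i in range(n_peaks):
        pid = f"sp_{i:04d}"
        lo = int(rng.integers(0, peak_width - spacing - motif_length))
        occ_a.append(occ("A", pid, lo))
        occ_b.append(occ("B", pid, lo + spacing))
        for _ in range(decoys_per_peak):
            occ_b.append(occ("B", pid,
                             int(rng.integers(0, peak_width - motif_length))))
    return occ_a, occ_b
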