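"""End-to-end pipeline orchestration over a single config.

The stage order mirrors the analysis it automates: peak union -> summit
filter -> tag normalization -> differential fold rule -> promoter proximity
-> peak-to-gene annotation (HiC first, closest TSS fallback) -> motif scan
-> network inference -> condition comparison -> modules, enrichment,
spacing, density matrices.  Per-assay defaults travel with the ``mode``
switch (dnase: extend 200 bp / 3-fold; chip: extend 100 bp from summit /
2-fold; atac: extend 200 bp / 2-fold) so thresholds from different assay
styles are never silently mixed.  A run writes a manifest with SHA-256
checksums of every output, and identical config + inputs + seed reproduce
identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .annotation import annotate_peaks
from .motifs import genome_background, motif_enrichment, motif_spacing, scan_peaks
from .network import (GRNetwork, compare_networks, condition_network,
                      extract_module, filter_de_genes, group_tf_families,
                      hypergeometric_overlap, infer_network)
from .peaks import (LABEL_A, LABEL_B, LABEL_UNCHANGED, Peak,
                    annotate_promoter_proximal, build_peak_union,
                    classify_differential, density_matrix, filter_low_summit,
                    normalize_tag_counts)
from .synthetic import SimulationParams, generate_landscape, write_landscape

__all__ = ["PipelineConfig", "ResultBundle", "run_pipeline", "make_fixture",
            "recover_networks", "MODE_DEFAULTS", "FIXTURE_PRESETS"]

logger = logging.getLogger(__name__)

MODE_DEFAULTS = {
    "dnase": {"extension": 200, "fold_threshold": 3.0},
    "chip": {"extension": 100, "fold_threshold": 2.0},
    "atac": {"extension": 200, "fold_threshold": 2.0},
}


@dataclass
class PipelineConfig:
    genome_fasta: str
    peaks_bed: str
    counts_tsv: str
    links_bedpe: str
    tss_bed: str
    pfm_file: str
    expression_tsv: str
    families_tsv: str
    out_dir: str
    mode: str = "dnase"
    extension: int | None = None          # None -> mode default
    fold_threshold: float | None = None   # None -> mode default
    pseudocount: float = 1.0
    min_summit_reads: float = 10.0
    use_normalized: bool = True
    promoter_distance: int = 1500
    window: int = 2000
    bin_size: int = 10
    threshold_fraction: float = 0.8
    pwm_pseudo_frequency: float = 0.01
    uniform_background: bool = True
    expression_fc_threshold: float = 2.0
    universe_size: int | None = None      # None -> genes in expression table
    make_plots: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.mode not in MODE_DEFAULTS:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of "
                             f"{sorted(MODE_DEFAULTS)}")
        if self.extension is None:
            self.extension = MODE_DEFAULTS[self.mode]["extension"]
        if self.fold_threshold is None:
            self.fold_threshold = MODE_DEFAULTS[self.mode]["fold_threshold"]

    def validate(self) -> None:
        """Fail fast: every referenced input must exist before any stage runs."""
        missing = [p for p in (self.genome_fasta, self.peaks_bed,
                               self.counts_tsv, self.links_bedpe,
                               self.tss_bed, self.pfm_file,
                               self.expression_tsv, self.families_tsv)
                   if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")
        if self.window % self.bin_size != 0:
            raise ValueError("window must be divisible by bin_size")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        base = Path(path).parent
        cfg = cls(**data)
        for name in ("genome_fasta", "peaks_bed", "counts_tsv", "links_bedpe",
                     "tss_bed", "pfm_file", "expression_tsv", "families_tsv",
                     "out_dir"):
            val = Path(getattr(cfg, name))
            if not val.is_absolute():
                setattr(cfg, name, str(base / val))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = repr(sorted(dataclasses.asdict(self).items()))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ResultBundle:
    out_dir: Path
    network_all: GRNetwork
    network_a: GRNetwork
    network_b: GRNetwork
    gained: set[tuple[str, str]]
    lost: set[tuple[str, str]]
    diff_calls: list
    modules: dict[str, set[str]]
    overlap_report: pd.DataFrame
    enrichment: pd.DataFrame
    manifest: dict
    files: dict[str, Path] = field(default_factory=dict)

    def checksums(self) -> dict[str, str]:
        return dict(self.manifest["checksums"])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Execute every stage and write a checksummed result bundle."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: "
                                           "%(message)s"))
    root = logging.getLogger("grnrewire")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    files: dict[str, Path] = {}
    try:
        logger.info("mode=%s extension=%s fold_threshold=%s pseudocount=%s "
                    "min_summit_reads=%s window=%s bin=%s "
                    "threshold_fraction=%s seed=%s",
                    config.mode, config.extension, config.fold_threshold,
                    config.pseudocount, config.min_summit_reads,
                    config.window, config.bin_size,
                    config.threshold_fraction, config.seed)

        # ---- read inputs --------------------------------------------------
        genome = gio.read_fasta(config.genome_fasta)
        bed = gio.read_bed(config.peaks_bed, expect_summit=True)
        counts = gio.read_counts_table(config.counts_tsv)
        links = gio.read_bedpe_links(config.links_bedpe)
        tss_catalog = gio.read_tss(config.tss_bed)
        pwms = gio.read_pfm(config.pfm_file, config.pwm_pseudo_frequency)
        expression = gio.read_expression_table(config.expression_tsv)
        families = gio.read_family_table(config.families_tsv)

        count_map: dict[str, dict[str, float]] = {}
        for row in counts.itertuples(index=False):
            count_map.setdefault(row.peak_id, {})[row.sample] = float(row.count)
        cond_of_sample = dict(
            counts[["sample", "condition"]].drop_duplicates().itertuples(
                index=False))
        samples_a = sorted(s for s, c in cond_of_sample.items() if c == "A")
        samples_b = sorted(s for s, c in cond_of_sample.items() if c == "B")

        raw_peaks = []
        for rec in bed:
            c = count_map.get(rec.name, {})
            raw_peaks.append(Peak(rec.name, rec.interval, rec.summit,
                                  dict(c), summit_counts=dict(c)))

        # ---- peak stages --------------------------------------------------
        union = build_peak_union([raw_peaks], config.extension,
                                 mode=config.mode)
        union = filter_low_summit(union, config.min_summit_reads)
        union, totals = normalize_tag_counts(union)
        logger.info("union: %d peaks; per-sample totals %s",
                    len(union), {k: round(v, 3) for k, v in totals.items()})
        calls = classify_differential(union, samples_a, samples_b,
                                      config.fold_threshold,
                                      config.pseudocount,
                                      config.use_normalized)
        n_a = sum(1 for c in calls if c.label == LABEL_A)
        n_b = sum(1 for c in calls if c.label == LABEL_B)
        logger.info("differential: %d specific to A, %d specific to B, %d "
                    "unchanged", n_a, n_b, len(calls) - n_a - n_b)

        files["differential"] = out / "differential_calls.tsv"
        with open(files["differential"], "w") as fh:
            fh.write("peak_id\tfold_change\tlabel\n")
            for c in sorted(calls, key=lambda c: c.peak_id):
                fh.write(f"{c.peak_id}\t{gio.fmt(c.fold_change)}\t"
                         f"{c.label}\n")

        proximity = annotate_promoter_proximal(union, tss_catalog,
                                               config.promoter_distance)
        files["proximity"] = out / "promoter_proximity.tsv"
        with open(files["proximity"], "w") as fh:
            fh.write("peak_id\tclass\n")
            for pid in sorted(proximity):
                fh.write(f"{pid}\t{proximity[pid]}\n")

        # ---- annotation ---------------------------------------------------
        assignments = annotate_peaks(union, links, tss_catalog)
        files["annotation"] = out / "peak_annotation.tsv"
        with open(files["annotation"], "w") as fh:
            fh.write("peak_id\tgene\tmethod\tdistance\n")
            for a in sorted(assignments, key=lambda a: a.peak_id):
                for g in sorted(a.genes):
                    d = a.distance if a.distance is not None else "NA"
                    fh.write(f"{a.peak_id}\t{g}\t{a.method}\t{d}\n")

        # ---- motif scan ---------------------------------------------------
        background = None if config.uniform_background else \
            genome_background(genome)
        occurrences = scan_peaks(genome, union, pwms, background,
                                 config.threshold_fraction)
        logger.info("scan: %d motif occurrences in %d peaks",
                    len(occurrences),
                    len({o.peak_id for o in occurrences}))
        files["occurrences"] = out / "motif_occurrences.bed"
        occ_rows = sorted(occurrences,
                          key=lambda o: (o.interval.chrom, o.interval.start,
                                         o.motif_id))
        with open(files["occurrences"], "w") as fh:
            for o in occ_rows:
                fh.write(f"{o.interval.chrom}\t{o.interval.start}\t"
                         f"{o.interval.end}\t{o.motif_id}\t"
                         f"{gio.fmt(o.score)}\t{o.strand}\t{o.peak_id}\n")

        # ---- expression-derived inputs -------------------------------------
        expr_samples = expression.samples
        sample_a_expr = expression.sample_values(expr_samples[0])
        sample_b_expr = expression.sample_values(expr_samples[-1])
        mean_expr = {g: (sample_a_expr[g] + sample_b_expr[g]) / 2
                     for g in sample_a_expr}
        fams = group_tf_families(families, mean_expr,
                                 motif_by_family=_motif_map(pwms))
        de_labels = filter_de_genes(sample_a_expr, sample_b_expr,
                                    fc_threshold=config.expression_fc_threshold,
                                    pseudocount=config.pseudocount)
        log2fc = {g: math.log2((sample_b_expr[g] + config.pseudocount)
                               / (sample_a_expr[g] + config.pseudocount))
                  for g in sample_a_expr}

        # ---- network inference and comparison -----------------------------
        net_all = infer_network(calls, assignments, occurrences, fams, "all")
        net_all.set_node_expression(log2fc)
        net_a = condition_network(net_all, "A")
        net_b = condition_network(net_all, "B")
        comparison = compare_networks(net_a, net_b)
        logger.info("network: %d edges total; %d gained, %d lost at B",
                    len(net_all), len(comparison.gained),
                    len(comparison.lost))
        for name, net in (("network_all", net_all), ("network_A", net_a),
                          ("network_B", net_b)):
            e, n = gio.write_network(net, out / name)
            files[f"{name}_edges"], files[f"{name}_nodes"] = e, n
        files["rewiring"] = out / "rewired_edges.tsv"
        with open(files["rewiring"], "w") as fh:
            fh.write("source_family\ttarget_gene\tdirection\n")
            for s, t in sorted(comparison.gained):
                fh.write(f"{s}\t{t}\tgained\n")
            for s, t in sorted(comparison.lost):
                fh.write(f"{s}\t{t}\tlost\n")
        files["per_family"] = out / "per_family_rewiring.tsv"
        comparison.per_family.to_csv(files["per_family"], sep="\t")

        # ---- modules and overlap statistics -------------------------------
        universe = config.universe_size or len(expression.genes)
        up_genes = {g for g, lab in de_labels.items() if lab == "up"}
        down_genes = {g for g, lab in de_labels.items() if lab == "down"}
        modules: dict[str, set[str]] = {}
        overlap_rows = []
        for fam in fams:
            module = extract_module(net_all, fam.family_id)
            modules[fam.family_id] = module
            mpath = out / f"module_{fam.family_id}.txt"
            mpath.write_text("".join(g + "\n" for g in sorted(module)))
            files[f"module_{fam.family_id}"] = mpath
            for qname, query in (("up", up_genes), ("down", down_genes)):
                ov = hypergeometric_overlap(module, query, universe)
                overlap_rows.append({
                    "family": fam.family_id, "query": qname,
                    "module_size": len(module), "query_size": len(query),
                    "universe": universe, "overlap": ov.overlap,
                    "fraction_of_query": ov.fraction_of_query,
                    "p_value": ov.p_value})
        overlap_report = pd.DataFrame(overlap_rows)
        files["overlaps"] = out / "module_overlaps.tsv"
        with open(files["overlaps"], "w") as fh:
            cols = ["family", "query", "module_size", "query_size",
                    "universe", "overlap", "fraction_of_query", "p_value"]
            fh.write("\t".join(cols) + "\n")
            for row in overlap_rows:
                fh.write("\t".join(
                    gio.fmt(row[c]) if isinstance(row[c], float)
                    else str(row[c]) for c in cols) + "\n")

        # ---- enrichment ---------------------------------------------------
        label_of = {c.peak_id: c.label for c in calls}
        unchanged = {p for p, lab in label_of.items()
                     if lab == LABEL_UNCHANGED}
        enr_rows = []
        for cond, lab in (("A", LABEL_A), ("B", LABEL_B)):
            fg = {p for p, l in label_of.items() if l == lab}
            if not fg or not unchanged:
                continue
            for r in motif_enrichment(fg, unchanged, occurrences):
                enr_rows.append({"condition": cond, "motif_id": r.motif_id,
                                 "n_fg_with": r.n_fg_with, "n_fg": r.n_fg,
                                 "n_bg_with": r.n_bg_with, "n_bg": r.n_bg,
                                 "fold_enrichment": r.fold_enrichment,
                                 "p_value": r.p_value})
        enrichment = pd.DataFrame(enr_rows)
        files["enrichment"] = out / "motif_enrichment.tsv"
        with open(files["enrichment"], "w") as fh:
            cols = ["condition", "motif_id", "n_fg_with", "n_fg",
                    "n_bg_with", "n_bg", "fold_enrichment", "p_value"]
            fh.write("\t".join(cols) + "\n")
            for row in enr_rows:
                fh.write("\t".join(
                    gio.fmt(row[c]) if isinstance(row[c], float)
                    else str(row[c]) for c in cols) + "\n")

        # ---- spacing (first two motifs by id) ------------------------------
        motif_ids = sorted({p.motif_id for p in pwms})
        if len(motif_ids) >= 2:
            occ_a = [o for o in occurrences if o.motif_id == motif_ids[0]]
            occ_b = [o for o in occurrences if o.motif_id == motif_ids[1]]
            spacing = motif_spacing(occ_a, occ_b)
            files["spacing"] = out / "motif_spacing.tsv"
            with open(files["spacing"], "w") as fh:
                fh.write("bin_lo\tbin_hi\tcount\n")
                for i, cnt in enumerate(spacing.histogram):
                    fh.write(f"{int(spacing.bin_edges[i])}\t"
                             f"{int(spacing.bin_edges[i + 1])}\t{int(cnt)}\n")

        # ---- density matrices ----------------------------------------------
        coverage = _uniform_coverage(genome, union)
        fold_by_peak = {c.peak_id: c.fold_change for c in calls}
        dm = density_matrix(union, fold_by_peak, coverage,
                            config.window, config.bin_size)
        files["density"] = out / "density_matrix.tsv"
        with open(files["density"], "w") as fh:
            fh.write("peak_id\tfold_change\t" + "\t".join(
                f"bin_{i}" for i in range(dm.values.shape[1])) + "\n")
            for i, pid in enumerate(dm.peak_ids):
                fh.write(pid + "\t" + gio.fmt(dm.fold_changes[i]) + "\t"
                         + "\t".join(gio.fmt(v) for v in dm.values[i]) + "\n")

        if config.make_plots:
            files.update(_render_plots(out, dm,
                                       spacing if len(motif_ids) >= 2
                                       else None))

        # ---- manifest -------------------------------------------------------
        manifest = {
            "config": dataclasses.asdict(config),
            "config_hash": config.config_hash(),
            "thresholds": {
                "mode": config.mode, "extension": config.extension,
                "fold_threshold": config.fold_threshold,
                "pseudocount": config.pseudocount,
                "min_summit_reads": config.min_summit_reads,
                "threshold_fraction": config.threshold_fraction,
                "promoter_distance": config.promoter_distance,
                "window": config.window, "bin": config.bin_size},
            "library_totals": totals,
            "n_union_peaks": len(union),
            "n_edges": len(net_all),
            "n_gained": len(comparison.gained),
            "n_lost": len(comparison.lost),
            "checksums": {str(p.relative_to(out)): _sha256(p)
                          for p in sorted(files.values())},
        }
        gio.write_json(manifest, out / "manifest.json")
        files["manifest"] = out / "manifest.json"
        return ResultBundle(out, net_all, net_a, net_b, comparison.gained,
                            comparison.lost, calls, modules, overlap_report,
                            enrichment, manifest, files)
    finally:
        root.removeHandler(handler)
        handler.close()


def _motif_map(pwms) -> dict[str, str]:
    return {p.family: p.motif_id for p in pwms}


def _uniform_coverage(genome, peaks) -> dict[str, np.ndarray]:
    """Per-bp density spreading each peak's normalized mean count uniformly
    over its interval (counts arrive per peak, not per bp)."""
    cov = {c: np.zeros(len(s)) for c, s in genome.items()}
    for p in peaks:
        src = p.normalized if p.normalized is not None else p.counts
        if not src:
            continue
        mean = sum(src.values()) / len(src)
        arr = cov.get(p.interval.chrom)
        if arr is None:
            continue
        lo, hi = p.interval.start, min(p.interval.end, len(arr))
        if hi > lo:
            arr[lo:hi] += mean / p.interval.width
    return cov


def _render_plots(out: Path, dm, spacing) -> dict[str, Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = {}
    fig, ax = plt.subplots(figsize=(4, 6))
    ax.imshow(np.asarray(dm.values), aspect="auto", cmap="Reds",
              interpolation="nearest")
    ax.set_xlabel(f"{dm.window} bp window ({dm.bin_size} bp bins)")
    ax.set_ylabel("peaks (ranked by fold change)")
    fig.savefig(out / "density_heatmap.png", dpi=100)
    plt.close(fig)
    written["density_heatmap"] = out / "density_heatmap.png"
    if spacing is not None and spacing.distances:
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.bar(spacing.bin_edges[:-1], spacing.histogram,
               width=spacing.bin_width, align="edge")
        ax.set_xlabel("motif center-to-center distance (bp)")
        ax.set_ylabel("pairs")
        fig.savefig(out / "spacing_histogram.png", dpi=100)
        plt.close(fig)
        written["spacing_histogram"] = out / "spacing_histogram.png"
    return written


def recover_networks(landscape, mode: str = "dnase",
                     threshold_fraction: float = 0.9,
                     pseudocount: float = 1.0,
                     min_summit_reads: float = 10.0):
    """Run the inference stages in memory on a synthetic landscape.

    Returns (network_A, network_B, comparison) — the same result chain
    ``run_pipeline`` produces, without touching disk.  Convenient for
    recovery experiments across many seeds.
    """
    defaults = MODE_DEFAULTS[mode]
    union = build_peak_union([landscape.peaks], defaults["extension"], mode)
    union = filter_low_summit(union, min_summit_reads)
    union, _ = normalize_tag_counts(union)
    samples = sorted({s for p in union for s in p.counts})
    samples_a = [s for s in samples if s.endswith("A")]
    samples_b = [s for s in samples if s.endswith("B")]
    calls = classify_differential(union, samples_a, samples_b,
                                  defaults["fold_threshold"], pseudocount)
    assignments = annotate_peaks(union, landscape.hic_links,
                                 landscape.tss_catalog)
    occurrences = scan_peaks(landscape.genome, union, landscape.pwms,
                             threshold_fraction=threshold_fraction)
    expr = {g: (landscape.expression_a.get(g, 0.0)
                + landscape.expression_b.get(g, 0.0)) / 2
            for g in set(landscape.expression_a)
            | set(landscape.expression_b)} or \
        {m: 1.0 for ms in landscape.families.values() for m in ms}
    fams = group_tf_families(landscape.families, expr,
                             motif_by_family=landscape.motif_by_family())
    net_all = infer_network(calls, assignments, occurrences, fams, "all")
    net_a = condition_network(net_all, "A")
    net_b = condition_network(net_all, "B")
    return net_a, net_b, compare_networks(net_a, net_b)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

FIXTURE_PRESETS = {
    "tiny": dict(n_chromosomes=1, chromosome_length=200_000,
                 n_tf_families=2, members_per_family=3, n_genes=20,
                 n_peaks=60, edge_density=0.5, hic_link_fraction=0.5,
                 rewired_fraction=0.4, sequencing_depth=100.0,
                 nb_dispersion=math.inf, planted_fold_change=4.0,
                 expression_noise_sd=0.0),
    "demo": dict(n_chromosomes=2, chromosome_length=2_000_000,
                 n_tf_families=5, members_per_family=3, n_genes=200,
                 n_peaks=1000, edge_density=0.15, hic_link_fraction=0.6,
                 rewired_fraction=0.3, sequencing_depth=100.0,
                 nb_dispersion=math.inf, planted_fold_change=4.0,
                 expression_noise_sd=0.0),
}


def make_fixture(out_dir: str | Path, size: str = "tiny",
                 seed: int = 0) -> dict[str, Path]:
    """Write a complete zero-noise input set plus truth and a ready config.

    ``tiny``: 1 chromosome x 200 kb, 2 families, 20 genes, 60 peaks.
    ``demo``: 2 x 2 Mb, 5 families, 200 genes, 1,000 peaks.  Both use the
    deterministic count sentinel and no expression noise, so pipeline output
    is exactly comparable to the packaged truth edge lists.
    """
    if size not in FIXTURE_PRESETS:
        raise ValueError(f"unknown fixture size {size!r}")
    params = SimulationParams(seed=seed, **FIXTURE_PRESETS[size])
    land = generate_landscape(params)
    paths = write_landscape(land, out_dir)
    out = Path(out_dir)
    cfg = PipelineConfig(
        genome_fasta="genome.fa", peaks_bed="peaks.bed",
        counts_tsv="counts.tsv", links_bedpe="links.bedpe", tss_bed="tss.bed",
        pfm_file="motifs.jaspar", expression_tsv="expression.tsv",
        families_tsv="families.tsv", out_dir="results", mode="dnase",
        threshold_fraction=0.9, seed=seed)
    cfg_dict = dataclasses.asdict(cfg)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=True)
    paths["config"] = out / "config.yaml"
    return paths
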