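"""Readers and writers for the external formats the pipeline touches.

All coordinates are 0-based half-open (BED convention) internally; any
1-based source format is converted at the boundary.  Readers validate and
reject malformed input with line numbers; writers emit deterministic,
stably sorted output with numbers formatted at six significant digits.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GenomicInterval",
    "BedRecord",
    "PWMRecord",
    "ChromatinLink",
    "TSS",
    "ExpressionTable",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_pfm",
    "write_pfm",
    "read_bedpe_links",
    "write_bedpe_links",
    "read_tss",
    "write_tss",
    "read_expression_table",
    "write_expression_table",
    "read_counts_table",
    "write_counts_table",
    "read_family_table",
    "write_family_table",
    "read_edge_list",
    "write_network",
    "fmt",
]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class FormatError(ValueError):
    """Malformed external input; carries the offending file and line."""

    def __init__(self, message: str, path: str | Path | None = None,
                 line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f", line {line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = str(path) if path is not None else None
        self.line = line


def fmt(x: float) -> str:
    """Format a number at 6 significant digits (writers' shared convention)."""
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if np.isinf(x):
        return "inf" if x > 0 else "-inf"
    return format(float(x), ".6g")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.start >= self.end:
            raise ValueError(f"start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """At least 1 bp of shared sequence (half-open semantics)."""
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


@dataclass(frozen=True)
class BedRecord:
    interval: GenomicInterval
    name: str = "."
    score: float = 0.0
    summit: int | None = None  # absolute coordinate, BED column 7


@dataclass
class PWMRecord:
    """Position weight matrix: per-position base probabilities (ACGT columns).

    ``matrix`` has shape (length, 4) and every row sums to 1.  The
    pseudo-frequency is added to the raw input entries before column
    normalization so that zero counts never yield -inf log-odds.
    """

    motif_id: str
    family: str
    matrix: np.ndarray
    pseudo_frequency: float = 0.01

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError(f"matrix must be (L, 4), got {m.shape}")
        if m.shape[0] < 4:
            raise ValueError(f"motif length {m.shape[0]} < 4")
        sums = m.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("matrix rows must each sum to 1")
        self.matrix = m

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


@dataclass(frozen=True)
class ChromatinLink:
    """A promoter-capture HiC interaction: distal anchor wired to a gene."""

    anchor: GenomicInterval
    promoter: GenomicInterval
    gene: str

    def __post_init__(self):
        if not self.gene:
            raise ValueError("gene id must be non-empty")


@dataclass(frozen=True)
class TSS:
    gene: str
    chrom: str
    pos: int
    strand: str = "+"


@dataclass
class ExpressionTable:
    """Genes x samples expression values with per-sample condition labels."""

    values: pd.DataFrame                      # index: gene, columns: samples
    conditions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()]
            raise ValueError(f"duplicate gene id {dups[0]!r}")
        if (self.values.values < 0).any():
            raise ValueError("expression values must be >= 0")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def sample_values(self, sample: str) -> dict[str, float]:
        return self.values[sample].to_dict()


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def _parse_int(tok: str, what: str, path, line_no) -> int:
    try:
        return int(tok)
    except ValueError:
        raise FormatError(f"non-numeric {what} {tok!r}", path, line_no) from None


def read_bed(path: str | Path, expect_summit: bool = False) -> list[BedRecord]:
    """Read a BED file; an optional 7th column is the absolute summit."""
    records: list[BedRecord] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            toks = line.split("\t")
            if len(toks) < 3:
                raise FormatError(f"expected >= 3 columns, got {len(toks)}",
                                  path, line_no)
            start = _parse_int(toks[1], "start", path, line_no)
            end = _parse_int(toks[2], "end", path, line_no)
            if start < 0:
                raise FormatError(f"negative coordinate {start}", path, line_no)
            if start >= end:
                raise FormatError(f"start {start} >= end {end}", path, line_no)
            name = toks[3] if len(toks) > 3 else "."
            score = float(toks[4]) if len(toks) > 4 and toks[4] != "." else 0.0
            strand = toks[5] if len(toks) > 5 else "."
            summit = None
            if len(toks) > 6:
                summit = _parse_int(toks[6], "summit", path, line_no)
                if not (start <= summit < end):
                    raise FormatError(
                        f"summit {summit} outside [{start}, {end})",
                        path, line_no)
            elif expect_summit:
                raise FormatError("summit column (7) required but missing",
                                  path, line_no)
            records.append(BedRecord(GenomicInterval(toks[0], start, end,
                                                     strand), name, score,
                                     summit))
    return records


def write_bed(records: Sequence[BedRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            iv = r.interval
            cols = [iv.chrom, str(iv.start), str(iv.end), r.name,
                    fmt(r.score), iv.strand]
            if r.summit is not None:
                cols.append(str(r.summit))
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# PFM / PWM
# ---------------------------------------------------------------------------

def _normalize_pfm(raw: np.ndarray, pseudo: float) -> np.ndarray:
    """Add the pseudo-frequency to every entry, then column-normalize."""
    m = raw + pseudo
    return m / m.sum(axis=1, keepdims=True)


def read_pfm(path: str | Path, pseudo_frequency: float = 0.01) -> list[PWMRecord]:
    """Read motif matrices from JASPAR-style or plain-matrix text.

    JASPAR-style: a ``>motif_id [family]`` header followed by four base rows
    (``A [ 10 0 ... ]``); several motifs per file are allowed.  Plain format:
    one motif per file, one row per position with 4 whitespace-separated
    columns (A C G T); the motif id is the file stem.  Entries may be counts
    or probabilities; both are converted to probabilities after adding
    ``pseudo_frequency`` to each entry.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln.rstrip("\n") for ln in text.splitlines()]
    non_empty = [ln for ln in lines if ln.strip()]
    if not non_empty:
        raise FormatError("empty motif file", path)

    records: list[PWMRecord] = []
    if non_empty[0].lstrip().startswith(">"):
        i = 0
        while i < len(lines):
            if not lines[i].strip():
                i += 1
                continue
            if not lines[i].lstrip().startswith(">"):
                raise FormatError(f"expected '>' header, got {lines[i]!r}",
                                  path, i + 1)
            header = lines[i].lstrip()[1:].split()
            motif_id = header[0] if header else ""
            family = header[1] if len(header) > 1 else motif_id
            if not motif_id:
                raise FormatError("empty motif id in header", path, i + 1)
            rows: dict[str, list[float]] = {}
            i += 1
            while i < len(lines) and lines[i].strip() and \
                    not lines[i].lstrip().startswith(">"):
                toks = lines[i].replace("[", " ").replace("]", " ").split()
                base = toks[0].upper()
                if base not in BASE_INDEX:
                    raise FormatError(f"unknown base row {toks[0]!r}",
                                      path, i + 1)
                try:
                    rows[base] = [float(t) for t in toks[1:]]
                except ValueError:
                    raise FormatError("non-numeric matrix entry",
                                      path, i + 1) from None
                i += 1
            if set(rows) != set(BASES):
                raise FormatError(
                    f"motif {motif_id!r}: need rows A,C,G,T, got "
                    f"{sorted(rows)}", path)
            lens = {len(v) for v in rows.values()}
            if len(lens) != 1:
                raise FormatError(f"motif {motif_id!r}: row-length mismatch",
                                  path)
            raw = np.array([rows[b] for b in BASES], dtype=float).T
            records.append(PWMRecord(motif_id, family,
                                     _normalize_pfm(raw, pseudo_frequency),
                                     pseudo_frequency))
    else:
        data = []
        for line_no, ln in enumerate(lines, start=1):
            if not ln.strip() or ln.startswith("#"):
                continue
            toks = ln.split()
            if len(toks) != 4:
                raise FormatError(
                    f"plain matrix rows need 4 columns (A C G T), got "
                    f"{len(toks)}", path, line_no)
            try:
                data.append([float(t) for t in toks])
            except ValueError:
                raise FormatError("non-numeric matrix entry",
                                  path, line_no) from None
        raw = np.array(data, dtype=float)
        records.append(PWMRecord(path.stem, path.stem,
                                 _normalize_pfm(raw, pseudo_frequency),
                                 pseudo_frequency))
    return records


def write_pfm(pwms: Sequence[PWMRecord], path: str | Path) -> None:
    """Write motifs as JASPAR-style probability matrices."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id} {pwm.family}\n")
            for bi, base in enumerate(BASES):
                vals = " ".join(fmt(v) for v in pwm.matrix[:, bi])
                fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# BEDPE links
# ---------------------------------------------------------------------------

def read_bedpe_links(path: str | Path) -> list[ChromatinLink]:
    """Read HiC links: anchor interval, promoter interval, gene id (col 7)."""
    links: list[ChromatinLink] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            toks = line.split("\t")
            if len(toks) < 7:
                raise FormatError(f"expected >= 7 columns, got {len(toks)}",
                                  path, line_no)
            try:
                anchor = GenomicInterval(toks[0], int(toks[1]), int(toks[2]))
                promoter = GenomicInterval(toks[3], int(toks[4]), int(toks[5]))
            except ValueError as exc:
                raise FormatError(f"malformed interval: {exc}",
                                  path, line_no) from None
            if not toks[6]:
                raise FormatError("empty gene id", path, line_no)
            links.append(ChromatinLink(anchor, promoter, toks[6]))
    return links


def write_bedpe_links(links: Sequence[ChromatinLink], path: str | Path) -> None:
    with open(path, "w") as fh:
        for lk in links:
            a, p = lk.anchor, lk.promoter
            fh.write("\t".join([a.chrom, str(a.start), str(a.end),
                                p.chrom, str(p.start), str(p.end),
                                lk.gene]) + "\n")


# ---------------------------------------------------------------------------
# TSS catalog (BED with gene name in column 4)
# ---------------------------------------------------------------------------

def read_tss(path: str | Path) -> list[TSS]:
    out = []
    for rec in read_bed(path):
        if rec.name == ".":
            raise FormatError("TSS records need a gene name (column 4)", path)
        strand = rec.interval.strand if rec.interval.strand != "." else "+"
        out.append(TSS(rec.name, rec.interval.chrom, rec.interval.start,
                       strand))
    return out


def write_tss(catalog: Sequence[TSS], path: str | Path) -> None:
    records = [BedRecord(GenomicInterval(t.chrom, t.pos, t.pos + 1, t.strand),
                         t.gene) for t in catalog]
    write_bed(records, path)


# ---------------------------------------------------------------------------
# Expression / counts / family tables
# ---------------------------------------------------------------------------

def read_expression_table(path: str | Path) -> ExpressionTable:
    """TSV: header of sample names; first column gene id; numeric cells."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate gene id {dup!r}", path)
    numeric = pd.DataFrame(index=df.index)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            gene = df.index[bad.argmax()]
            raise FormatError(
                f"non-numeric or missing value {df[col][bad].iloc[0]!r} "
                f"(gene {gene!r}, sample {col!r})", path)
        numeric[col] = vals.astype(float)
    return ExpressionTable(numeric)


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    df = table.values.sort_index()
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(df.columns) + "\n")
        for gene, row in df.iterrows():
            fh.write(gene + "\t" + "\t".join(fmt(v) for v in row) + "\n")


def read_counts_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns peak_id, sample, condition, count."""
    df = pd.read_csv(path, sep="\t", dtype={"peak_id": str, "sample": str,
                                            "condition": str})
    required = {"peak_id", "sample", "condition", "count"}
    if not required.issubset(df.columns):
        raise FormatError(f"counts table needs columns {sorted(required)}",
                          path)
    if (df["count"] < 0).any():
        raise FormatError("negative count", path)
    return df


def write_counts_table(df: pd.DataFrame, path: str | Path) -> None:
    df = df.sort_values(["peak_id", "sample"]).reset_index(drop=True)
    with open(path, "w") as fh:
        fh.write("peak_id\tsample\tcondition\tcount\n")
        for row in df.itertuples(index=False):
            fh.write(f"{row.peak_id}\t{row.sample}\t{row.condition}\t"
                     f"{fmt(row.count)}\n")


def read_family_table(path: str | Path) -> dict[str, list[str]]:
    """TSV with columns family, member (one member gene per row)."""
    families: dict[str, list[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("family\t"):
                continue
            toks = line.split("\t")
            if len(toks) < 2:
                raise FormatError("expected columns family, member",
                                  path, line_no)
            families.setdefault(toks[0], []).append(toks[1])
    return families


def write_family_table(families: Mapping[str, Sequence[str]],
                       path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("family\tmember\n")
        for fam in sorted(families):
            for member in sorted(families[fam]):
                fh.write(f"{fam}\t{member}\n")


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path) -> set[tuple[str, str]]:
    """Read (source_family, target_gene) pairs from an edge-list TSV."""
    edges = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "source\t")):
                continue
            toks = line.split("\t")
            edges.add((toks[0], toks[1]))
    return edges


def write_network(network, path_prefix: str | Path) -> tuple[Path, Path]:
    """Write edge-list and node-attribute TSVs for a GRN.

    Produces ``<prefix>.edges.tsv`` (source_family, target_gene, condition,
    supporting_peaks) and ``<prefix>.nodes.tsv`` (node, type,
    expression_log2fc), both stably sorted so identical networks yield
    byte-identical files.
    """
    prefix = Path(path_prefix)
    edge_path = prefix.with_name(prefix.name + ".edges.tsv")
    node_path = prefix.with_name(prefix.name + ".nodes.tsv")
    rows = sorted(
        (e.source, e.target, e.condition, ";".join(sorted(e.supporting_peaks)))
        for e in network.edges)
    with open(edge_path, "w") as fh:
        fh.write("source_family\ttarget_gene\tcondition\tsupporting_peaks\n")
        for r in rows:
            fh.write("\t".join(r) + "\n")
    with open(node_path, "w") as fh:
        fh.write("node\ttype\texpression_log2fc\n")
        for node in sorted(network.graph.nodes):
            data = network.graph.nodes[node]
            lfc = data.get("expression_log2fc")
            fh.write(f"{node}\t{data.get('type', 'gene')}\t"
                     f"{fmt(lfc) if lfc is not None else 'NA'}\n")
    return edge_path, node_path


def write_json(obj, path: str | Path) -> None:
    """Deterministic JSON dump (sorted keys, dataclass-aware)."""
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
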