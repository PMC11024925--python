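"""Gene-regulatory-network assembly and condition comparison.

An edge family -> gene is inferred when a differential (or in-scope) peak
annotated to that gene contains the family's binding motif.  TF genes are
grouped into families binding the same motif; the member with the highest
expression is the representative used as the family source node.  Condition
networks are compared by set difference on (source, target) keys, and module
overlaps are scored with the one-sided upper-tail hypergeometric test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from .annotation import GeneAssignment
from .motifs import MotifOccurrence
from .peaks import LABEL_A, LABEL_B, DifferentialCall

__all__ = [
    "TFFamily",
    "GRNEdge",
    "GRNetwork",
    "NetworkComparison",
    "ModuleOverlap",
    "group_tf_families",
    "infer_network",
    "condition_network",
    "compare_networks",
    "extract_module",
    "hypergeometric_overlap",
    "filter_de_genes",
    "filter_aml_specific",
]

COND_A = "A_specific"
COND_B = "B_specific"
COND_SHARED = "shared"

_LABEL_TO_COND = {LABEL_A: COND_A, LABEL_B: COND_B}


@dataclass
class TFFamily:
    family_id: str
    member_genes: list[str]
    motif_id: str
    representative: str
    representative_expression: float
    all_zero: bool = False

    def __post_init__(self):
        if self.representative not in self.member_genes:
            raise ValueError(f"family {self.family_id}: representative "
                             f"{self.representative!r} not a member")


@dataclass
class GRNEdge:
    source: str                   # family id
    target: str                   # gene id
    condition: str                # A_specific | B_specific | shared
    supporting_peaks: frozenset[str]
    self_edge: bool = False

    def __post_init__(self):
        if not self.supporting_peaks:
            raise ValueError(f"edge {self.source}->{self.target}: no "
                             "supporting peaks")

    @property
    def key(self) -> tuple[str, str]:
        return (self.source, self.target)


class GRNetwork:
    """Directed TF-family -> gene network backed by a networkx DiGraph."""

    def __init__(self, edges: Iterable[GRNEdge] = (),
                 provenance: dict | None = None):
        self.graph = nx.DiGraph()
        self.provenance = provenance or {}
        self._edges: dict[tuple[str, str], GRNEdge] = {}
        for e in edges:
            self.add_edge(e)

    @property
    def edges(self) -> list[GRNEdge]:
        return [self._edges[k] for k in sorted(self._edges)]

    def edge_keys(self) -> set[tuple[str, str]]:
        return set(self._edges)

    def add_edge(self, edge: GRNEdge) -> None:
        prev = self._edges.get(edge.key)
        if prev is not None:
            conditions = {prev.condition, edge.condition}
            cond = edge.condition if len(conditions) == 1 else COND_SHARED
            edge = GRNEdge(edge.source, edge.target, cond,
                           prev.supporting_peaks | edge.supporting_peaks,
                           prev.self_edge or edge.self_edge)
        self._edges[edge.key] = edge
        self.graph.add_node(edge.source, type="family")
        if self.graph.nodes.get(edge.target, {}).get("type") != "family":
            self.graph.add_node(edge.target, type="gene")
        self.graph.add_edge(edge.source, edge.target,
                            condition=edge.condition,
                            supporting_peaks=sorted(edge.supporting_peaks),
                            self_edge=edge.self_edge)

    def set_node_expression(self, log2fc_by_node: Mapping[str, float]) -> None:
        for node in self.graph.nodes:
            if node in log2fc_by_node:
                self.graph.nodes[node]["expression_log2fc"] = float(
                    log2fc_by_node[node])

    def __len__(self) -> int:
        return len(self._edges)


@dataclass
class NetworkComparison:
    gained: set[tuple[str, str]]  # edges present in B, absent in A
    lost: set[tuple[str, str]]    # edges present in A, absent in B
    per_family: pd.DataFrame      # index family; columns gained, lost


@dataclass
class ModuleOverlap:
    module_genes: frozenset[str]
    query_genes: frozenset[str]
    universe_size: int
    overlap: int
    fraction_of_query: float
    p_value: float


# ---------------------------------------------------------------------------
# Family grouping
# ---------------------------------------------------------------------------

def group_tf_families(family_table: Mapping[str, Sequence[str]],
                      expression: Mapping[str, float],
                      motif_by_family: Mapping[str, str] | None = None,
                      ) -> list[TFFamily]:
    """Group TF genes into families and pick each family's representative.

    The representative is the member with the highest expression value
    (lexicographically smallest gene on ties).  Members absent from the
    expression table count as 0 with a warning; families whose members are
    all zero are flagged.
    """
    out = []
    for fam in sorted(family_table):
        members = list(family_table[fam])
        if not members:
            raise ValueError(f"family {fam!r} has no members")
        values = {}
        for m in members:
            if m not in expression:
                warnings.warn(f"family {fam}: member {m!r} missing from "
                              "expression table, treated as 0", stacklevel=2)
            values[m] = float(expression.get(m, 0.0))
        rep = min(values, key=lambda g: (-values[g], g))
        motif = motif_by_family.get(fam, fam) if motif_by_family else fam
        out.append(TFFamily(fam, members, motif, rep, values[rep],
                            all_zero=all(v == 0 for v in values.values())))
    return out


# ---------------------------------------------------------------------------
# Edge inference
# ---------------------------------------------------------------------------

def infer_network(diff_calls: Sequence[DifferentialCall],
                  assignments: Sequence[GeneAssignment],
                  occurrences: Sequence[MotifOccurrence],
                  families: Sequence[TFFamily],
                  condition_scope: str = "all",
                  keep_self_edges: bool = True) -> GRNetwork:
    """Infer family -> gene edges from motif-bearing annotated peaks.

    For every peak in scope, every family whose motif occurs in it, and
    every gene the peak is annotated to, the edge (family -> gene) gains the
    peak as support.  Edge identity is the (family, gene) pair; an edge's
    condition is the shared differential label of its supporting peaks
    (mixed support, or support from unchanged peaks, yields "shared").
    ``condition_scope`` restricts the peaks considered: "A_specific",
    "B_specific", or "all".  Self-edges (target inside the source family)
    are kept and flagged unless ``keep_self_edges`` is False.
    """
    if condition_scope not in (COND_A, COND_B, "all"):
        raise ValueError(f"unknown condition_scope {condition_scope!r}")
    label_by_peak = {c.peak_id: c.label for c in diff_calls}
    genes_by_peak = {a.peak_id: a.genes for a in assignments
                     if a.method != "unassigned"}
    family_by_motif = {f.motif_id: f for f in families}
    members: dict[str, set[str]] = {f.family_id: set(f.member_genes)
                                    for f in families}

    net = GRNetwork(provenance={
        "families": sorted(f.family_id for f in families),
        "condition_scope": condition_scope,
    })
    for occ in occurrences:
        if occ.peak_id is None:
            continue
        if occ.peak_id not in label_by_peak:
            raise ValueError(f"occurrence in peak {occ.peak_id!r} has no "
                             "differential call")
        fam = family_by_motif.get(occ.motif_id)
        if fam is None:
            continue
        label = label_by_peak[occ.peak_id]
        cond = _LABEL_TO_COND.get(label, COND_SHARED)
        if condition_scope != "all" and cond != condition_scope:
            continue
        for gene in sorted(genes_by_peak.get(occ.peak_id, ())):
            self_edge = gene in members[fam.family_id]
            if self_edge and not keep_self_edges:
                continue
            net.add_edge(GRNEdge(fam.family_id, gene, cond,
                                 frozenset([occ.peak_id]), self_edge))
    return net


def condition_network(network: GRNetwork, condition: str) -> GRNetwork:
    """Edges active in one condition: condition-specific plus shared."""
    if condition not in ("A", "B"):
        raise ValueError("condition must be 'A' or 'B'")
    want = {COND_A if condition == "A" else COND_B, COND_SHARED}
    return GRNetwork([e for e in network.edges if e.condition in want],
                     provenance=dict(network.provenance,
                                     condition=condition))


# ---------------------------------------------------------------------------
# Network differencing, modules, overlap statistics
# ---------------------------------------------------------------------------

def compare_networks(net_a: GRNetwork, net_b: GRNetwork,
                     tf_only: Iterable[str] | None = None
                     ) -> NetworkComparison:
    """Edges gained and lost between two condition networks.

    Keys are (source family, target gene) pairs: gained = B \\ A, lost =
    A \\ B, with per-family tallies.  ``tf_only`` restricts targets to a set
    of TF genes, reproducing TF-subnetwork views.  Both networks must carry
    the same family namespace.
    """
    fams_a = net_a.provenance.get("families")
    fams_b = net_b.provenance.get("families")
    if fams_a is not None and fams_b is not None and fams_a != fams_b:
        offending = sorted(set(fams_a) ^ set(fams_b))
        raise ValueError(f"family namespace mismatch: {offending}")
    keys_a = net_a.edge_keys()
    keys_b = net_b.edge_keys()
    if tf_only is not None:
        tf_set = set(tf_only)
        keys_a = {k for k in keys_a if k[1] in tf_set}
        keys_b = {k for k in keys_b if k[1] in tf_set}
    gained = keys_b - keys_a
    lost = keys_a - keys_b
    fams = sorted({k[0] for k in keys_a | keys_b})
    per_family = pd.DataFrame(
        {"gained": [sum(1 for s, _ in gained if s == f) for f in fams],
         "lost": [sum(1 for s, _ in lost if s == f) for f in fams]},
        index=pd.Index(fams, name="family"))
    return NetworkComparison(gained, lost, per_family)


def extract_module(network: GRNetwork, family_id: str) -> set[str]:
    """All distinct target genes of one family's edges (its module)."""
    known = network.provenance.get("families")
    if known is not None and family_id not in known:
        raise KeyError(f"unknown family {family_id!r}")
    if known is None and family_id not in {e.source for e in network.edges}:
        raise KeyError(f"unknown family {family_id!r}")
    return {e.target for e in network.edges if e.source == family_id}


def hypergeometric_overlap(set_a: Iterable[str], set_b: Iterable[str],
                           universe_size: int) -> ModuleOverlap:
    """One-sided upper-tail hypergeometric test of two gene sets' overlap.

    p = P(X >= overlap) with X ~ Hypergeom(N=universe, K=|A|, n=|B|) — the
    probability of seeing at least the observed overlap when |B| genes are
    drawn without replacement from a universe containing |A| marked genes.
    """
    a = frozenset(set_a)
    b = frozenset(set_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError(f"set sizes ({len(a)}, {len(b)}) exceed universe "
                         f"{universe_size}")
    k = len(a & b)
    p = float(hypergeom.sf(k - 1, universe_size, len(a), len(b)))
    frac = k / len(b) if b else 0.0
    return ModuleOverlap(a, b, universe_size, k, frac, p)


# ---------------------------------------------------------------------------
# Expression gene-list filters
# ---------------------------------------------------------------------------

def filter_de_genes(expression_a: Mapping[str, float] | None = None,
                    expression_b: Mapping[str, float] | None = None,
                    de_table: pd.DataFrame | None = None,
                    fc_threshold: float = 2.0,
                    adj_p_threshold: float = 0.1,
                    pseudocount: float = 1.0) -> dict[str, str]:
    """Label genes up/down/unchanged between two conditions.

    With raw expression tables only the fold-change criterion applies
    (FC = (B + c)/(A + c); up iff FC >= threshold, down iff FC <= 1/threshold).
    With a precomputed DE table (columns gene, fold_change, adj_p) the
    adjusted-p criterion (< 0.1 by default) applies as well.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must be > 1")
    labels: dict[str, str] = {}
    if de_table is not None:
        if "adj_p" not in de_table.columns:
            raise ValueError("DE table lacks an 'adj_p' column; supply it or "
                             "use raw expression tables")
        for row in de_table.itertuples(index=False):
            fc, p = float(row.fold_change), float(row.adj_p)
            if fc >= fc_threshold and p < adj_p_threshold:
                labels[row.gene] = "up"
            elif fc <= 1.0 / fc_threshold and p < adj_p_threshold:
                labels[row.gene] = "down"
            else:
                labels[row.gene] = "unchanged"
        return labels
    if expression_a is None or expression_b is None:
        raise ValueError("supply either a DE table or both expression tables")
    for gene in sorted(set(expression_a) | set(expression_b)):
        a = float(expression_a.get(gene, 0.0)) + pseudocount
        b = float(expression_b.get(gene, 0.0)) + pseudocount
        if a == 0:
            raise ValueError(f"gene {gene!r}: zero denominator; use a "
                             "positive pseudocount")
        fc = b / a
        if fc >= fc_threshold:
            labels[gene] = "up"
        elif fc <= 1.0 / fc_threshold:
            labels[gene] = "down"
        else:
            labels[gene] = "unchanged"
    return labels


def filter_aml_specific(sample_expressions: Sequence[Mapping[str, float]],
                        reference: Mapping[str, float],
                        fold: float = 2.0,
                        min_samples: int = 1,
                        pseudocount: float = 1.0) -> set[str]:
    """Genes strictly more than ``fold``-fold above a reference tissue in at
    least ``min_samples`` of the supplied samples (disease-specificity
    filter)."""
    if not reference:
        raise ValueError("reference expression is empty")
    genes = set(reference)
    for s in sample_expressions:
        genes |= set(s)
    out = set()
    for gene in genes:
        ref = float(reference.get(gene, 0.0)) + pseudocount
        n_pass = sum(
            1 for s in sample_expressions
            if (float(s.get(gene, 0.0)) + pseudocount) / ref > fold)
        if n_pass >= min_samples:
            out.add(gene)
    return out
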