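import math

import pandas as pd
import pytest

from grnrewire import (GRNEdge, GRNetwork, GeneAssignment, MotifOccurrence,
                       compare_networks, condition_network, extract_module,
                       filter_aml_specific, filter_de_genes,
                       group_tf_families, hypergeometric_overlap,
                       infer_network)
from grnrewire.io import GenomicInterval
from grnrewire.network import TFFamily
from grnrewire.peaks import DifferentialCall

from conftest import hypergeom_upper_tail_exact


def call(pid, label, fold=1.0):
    return DifferentialCall(pid, fold, label, 3.0)


def assign(pid, genes):
    return GeneAssignment(pid, frozenset(genes), "closest", 100)


def occ(motif, pid):
    return MotifOccurrence(motif, pid, GenomicInterval("chr1", 0, 10, "+"),
                           "+", 10.0, 1.0)


def family(fid, members, motif=None, rep=None):
    return TFFamily(fid, members, motif or f"M_{fid}", rep or members[0],
                    10.0)


class TestFamilyGrouping:
    def test_highest_expressed_member_is_representative(self):
        fams = group_tf_families({"AP1": ["FOS", "FOSB", "JUN"]},
                                 {"FOS": 120.0, "FOSB": 4.0, "JUN": 60.0})
        assert fams[0].representative == "FOS"
        assert fams[0].representative_expression == 120.0

    def test_expression_tie_breaks_lexicographically(self):
        fams = group_tf_families({"F": ["Y", "X"]}, {"X": 10.0, "Y": 10.0})
        assert fams[0].representative == "X"

    def test_missing_member_counts_as_zero_with_warning(self):
        with pytest.warns(UserWarning, match="ZNF"):
            fams = group_tf_families({"F": ["ZNF", "A"]}, {"A": 5.0})
        assert fams[0].representative == "A"

    def test_all_zero_family_flagged(self):
        fams = group_tf_families({"F": ["A", "B"]}, {"A": 0.0, "B": 0.0})
        assert fams[0].all_zero

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError, match="no members"):
            group_tf_families({"F": []}, {})


class TestInference:
    def test_single_peak_single_edge(self):
        net = infer_network([call("p1", "specific_to_A")],
                            [assign("p1", {"GATA2"})],
                            [occ("M_RUNX", "p1")],
                            [family("RUNX", ["RUNX1"], motif="M_RUNX")])
        (edge,) = net.edges
        assert edge.key == ("RUNX", "GATA2")
        assert edge.condition == "A_specific"
        assert edge.supporting_peaks == {"p1"}

    def test_self_edge_kept_and_flagged(self):
        net = infer_network([call("p1", "unchanged")],
                            [assign("p1", {"RUNX1"})],
                            [occ("M_RUNX", "p1")],
                            [family("RUNX", ["RUNX1"], motif="M_RUNX")])
        (edge,) = net.edges
        assert edge.self_edge
        net2 = infer_network([call("p1", "unchanged")],
                             [assign("p1", {"RUNX1"})],
                             [occ("M_RUNX", "p1")],
                             [family("RUNX", ["RUNX1"], motif="M_RUNX")],
                             keep_self_edges=False)
        assert len(net2) == 0

    def test_unknown_peak_in_occurrences_rejected(self):
        with pytest.raises(ValueError, match="differential call"):
            infer_network([], [assign("p1", {"G"})], [occ("M_F", "p1")],
                          [family("F", ["TF1"], motif="M_F")])

    def test_mixed_condition_support_becomes_shared(self):
        net = infer_network(
            [call("p1", "specific_to_A"), call("p2", "specific_to_B")],
            [assign("p1", {"G"}), assign("p2", {"G"})],
            [occ("M_F", "p1"), occ("M_F", "p2")],
            [family("F", ["TF1"], motif="M_F")])
        (edge,) = net.edges
        assert edge.condition == "shared"
        assert edge.supporting_peaks == {"p1", "p2"}

    def test_edge_inference_is_monotone_in_occurrences(self):
        calls = [call(f"p{i}", "unchanged") for i in range(4)]
        assigns = [assign(f"p{i}", {f"G{i}"}) for i in range(4)]
        fams = [family("F", ["TF1"], motif="M_F")]
        occs = [occ("M_F", f"p{i}") for i in range(4)]
        prev: set = set()
        for k in range(5):
            keys = infer_network(calls, assigns, occs[:k], fams).edge_keys()
            assert prev <= keys
            prev = keys

    def test_condition_scope_restricts_peaks(self):
        calls = [call("p1", "specific_to_A"), call("p2", "unchanged")]
        assigns = [assign("p1", {"G1"}), assign("p2", {"G2"})]
        occs = [occ("M_F", "p1"), occ("M_F", "p2")]
        fams = [family("F", ["TF1"], motif="M_F")]
        net = infer_network(calls, assigns, occs, fams, "A_specific")
        assert net.edge_keys() == {("F", "G1")}


class TestComparison:
    def _net(self, keys, cond="shared"):
        return GRNetwork([GRNEdge(s, t, cond, frozenset(["p"]))
                          for s, t in keys])

    def test_gained_and_lost_are_set_differences(self):
        cmp_ = compare_networks(self._net([("F", "g1"), ("F", "g2")]),
                                self._net([("F", "g2"), ("F", "g3")]))
        assert cmp_.gained == {("F", "g3")} and cmp_.lost == {("F", "g1")}
        assert cmp_.per_family.loc["F", "gained"] == 1

    def test_identical_networks_change_nothing(self):
        n = self._net([("F", "g1")])
        cmp_ = compare_networks(n, n)
        assert not cmp_.gained and not cmp_.lost

    def test_empty_baseline_gains_everything(self):
        cmp_ = compare_networks(self._net([]), self._net([("F", "g1")]))
        assert cmp_.gained == {("F", "g1")} and not cmp_.lost

    def test_antisymmetry_under_argument_swap(self):
        a = self._net([("F", "g1"), ("G", "g2")])
        b = self._net([("F", "g1"), ("G", "g3")])
        fwd = compare_networks(a, b)
        rev = compare_networks(b, a)
        assert fwd.gained == rev.lost and fwd.lost == rev.gained

    def test_tf_only_filter(self):
        a = self._net([])
        b = self._net([("F", "TF9"), ("F", "g1")])
        cmp_ = compare_networks(a, b, tf_only={"TF9"})
        assert cmp_.gained == {("F", "TF9")}

    def test_family_namespace_mismatch_rejected(self):
        a = GRNetwork(provenance={"families": ["F1"]})
        b = GRNetwork(provenance={"families": ["F2"]})
        with pytest.raises(ValueError, match="F1.*F2|F2.*F1"):
            compare_networks(a, b)

    def test_condition_network_includes_shared(self):
        net = GRNetwork([GRNEdge("F", "g1", "A_specific", frozenset(["p"])),
                         GRNEdge("F", "g2", "shared", frozenset(["q"])),
                         GRNEdge("F", "g3", "B_specific", frozenset(["r"]))])
        assert condition_network(net, "A").edge_keys() == \
            {("F", "g1"), ("F", "g2")}
        assert condition_network(net, "B").edge_keys() == \
            {("F", "g2"), ("F", "g3")}


class TestModules:
    def test_targets_deduplicated(self):
        net = GRNetwork([GRNEdge("F", "g1", "shared", frozenset(["p", "q"])),
                         GRNEdge("F", "g2", "shared", frozenset(["p"]))])
        assert extract_module(net, "F") == {"g1", "g2"}

    def test_family_without_edges_is_empty(self):
        net = GRNetwork(provenance={"families": ["F", "H"]})
        assert extract_module(net, "H") == set()

    def test_unknown_family_rejected(self):
        with pytest.raises(KeyError):
            extract_module(GRNetwork(), "NOPE")

    def test_module_of_union_is_union_of_modules(self):
        a = [GRNEdge("F", "g1", "A_specific", frozenset(["p"]))]
        b = [GRNEdge("F", "g2", "B_specific", frozenset(["q"]))]
        merged = GRNetwork(a + b)
        assert extract_module(merged, "F") == \
            extract_module(GRNetwork(a), "F") | \
            extract_module(GRNetwork(b), "F")


class TestHypergeometricOverlap:
    def test_small_universe_exact_value(self):
        # worked example: |A|=5, |B|=4, overlap 4 in universe 10
        a = {"g1", "g2", "g3", "g4", "g5"}
        b = {"g1", "g2", "g3", "g4"}
        ov = hypergeometric_overlap(a, b, 10)
        assert ov.overlap == 4
        assert ov.p_value == pytest.approx(5 / 210, abs=1e-12)
        assert ov.fraction_of_query == pytest.approx(1.0)

    def test_empty_query_certain(self):
        ov = hypergeometric_overlap(set(), {"g1"}, 10)
        assert ov.overlap == 0 and ov.p_value == pytest.approx(1.0)

    def test_forced_overlap_certain(self):
        universe = {f"g{i}" for i in range(10)}
        ov = hypergeometric_overlap(universe, {"g1", "g2"}, 10)
        assert ov.overlap == 2 and ov.p_value == pytest.approx(1.0)

    def test_sets_exceeding_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_overlap({f"g{i}" for i in range(5)}, set(), 3)

    @pytest.mark.parametrize("N,sa,sb,k", [(12, 6, 5, 3), (20, 9, 9, 7),
                                           (25, 12, 10, 2), (7, 3, 3, 0)])
    def test_matches_draw_enumeration(self, N, sa, sb, k):
        a = {f"c{i}" for i in range(k)} | {f"a{i}" for i in range(sa - k)}
        b = {f"c{i}" for i in range(k)} | {f"b{i}" for i in range(sb - k)}
        ov = hypergeometric_overlap(a, b, N)
        assert ov.p_value == pytest.approx(
            hypergeom_upper_tail_exact(N, sa, sb, k), abs=1e-9)


class TestExpressionFilters:
    def test_de_table_applies_both_criteria(self):
        table = pd.DataFrame({"gene": ["a", "b", "c"],
                              "fold_change": [2.5, 2.5, 1.9],
                              "adj_p": [0.05, 0.2, 0.001]})
        labels = filter_de_genes(de_table=table)
        assert labels == {"a": "up", "b": "unchanged", "c": "unchanged"}

    def test_de_table_without_adj_p_rejected(self):
        with pytest.raises(ValueError, match="adj_p"):
            filter_de_genes(de_table=pd.DataFrame({"gene": ["a"],
                                                   "fold_change": [3.0]}))

    def test_raw_expression_uses_fold_only(self):
        labels = filter_de_genes({"a": 10.0, "b": 40.0}, {"a": 45.0, "b": 9.0},
                                 pseudocount=0.0)
        assert labels == {"a": "up", "b": "down"}

    def test_aml_specificity_strict_fold(self):
        ref = {"g": 10.0}
        # 3x in one of three samples passes min_samples=1
        keep = filter_aml_specific([{"g": 30.0}, {"g": 10.0}, {"g": 10.0}],
                                   ref, pseudocount=0.0)
        assert keep == {"g"}
        # exactly 2x is excluded (strict >)
        assert filter_aml_specific([{"g": 20.0}], ref,
                                   pseudocount=0.0) == set()
        # min_samples counting
        assert filter_aml_specific([{"g": 30.0}, {"g": 30.0}, {"g": 10.0}],
                                   ref, min_samples=3,
                                   pseudocount=0.0) == set()
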