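import math

import numpy as np
import pytest

from grnrewire import (CapacityError, ParameterError, SimulationParams,
                       generate_genome, generate_landscape,
                       plant_regulatory_landscape, simulate_expression,
                       simulate_tag_counts)
from grnrewire.motifs import reverse_complement
from grnrewire.synthetic import nb_draw

from conftest import tiny_params


class TestGenome:
    def test_identical_seed_identical_sequence(self):
        p = tiny_params(seed=7, chromosome_length=10_000)
        assert generate_genome(p) == generate_genome(p)

    def test_different_seed_differs(self):
        a = generate_genome(tiny_params(seed=1, chromosome_length=10_000))
        b = generate_genome(tiny_params(seed=2, chromosome_length=10_000))
        assert a != b

    def test_pure_gc_boundary(self):
        g = generate_genome(tiny_params(gc_fraction=1.0,
                                        chromosome_length=5_000))
        assert set(g["chr1"]) <= {"G", "C"}

    def test_gc_fraction_within_binomial_error(self):
        # SE of GC at n=100,000 is sqrt(0.4*0.6/1e5) ~ 0.0015; 0.01 > 6 SE
        g = generate_genome(tiny_params(gc_fraction=0.4,
                                        chromosome_length=100_000))
        gc = sum(c in "GC" for c in g["chr1"]) / 100_000
        assert abs(gc - 0.4) < 0.01

    def test_invalid_params_name_the_field(self):
        with pytest.raises(ParameterError, match="gc_fraction"):
            generate_genome(tiny_params(gc_fraction=1.5))
        with pytest.raises(ParameterError, match="n_genes"):
            generate_genome(tiny_params(n_genes=0))


class TestPlanting:
    def test_zero_density_gives_empty_truth(self):
        land = generate_landscape(tiny_params(edge_density=0.0))
        assert not land.truth_edges and not land.motif_placements
        assert land.truth_network_a == set() == land.truth_network_b

    def test_truth_edge_count_is_rounded_product(self):
        p = tiny_params(n_tf_families=3, n_genes=50, edge_density=0.1,
                        n_peaks=60)
        assert p.n_truth_edges == 15
        land = generate_landscape(p)
        assert len(land.truth_network_a | land.truth_network_b) == 15

    def test_manifest_edges_verified_by_genome_rescan(self, tiny_landscape):
        """Re-read the genome at every planted coordinate and match the
        family consensus (independent of the scanner)."""
        land = tiny_landscape
        by_peak = {pl["peak_id"]: pl for pl in land.motif_placements}
        assert {e.peak_id for e in land.truth_edges} == set(by_peak)
        for e in land.truth_edges:
            pl = by_peak[e.peak_id]
            seq = land.genome[pl["chrom"]][pl["start"]:pl["end"]]
            cons = land.consensi[e.family]
            assert seq == (cons if pl["strand"] == "+"
                           else reverse_complement(cons))

    def test_no_stray_consensus_matches_in_genome(self, tiny_landscape):
        land = tiny_landscape
        planted = {(pl["chrom"], pl["start"]) for pl in land.motif_placements}
        for fam, cons in land.consensi.items():
            for pat in (cons, reverse_complement(cons)):
                for chrom, seq in land.genome.items():
                    pos = seq.find(pat)
                    while pos != -1:
                        assert (chrom, pos) in planted
                        pos = seq.find(pat, pos + 1)

    def test_peaks_never_merge_after_extension(self, tiny_landscape):
        ivs = sorted((p.interval.chrom, p.interval.start, p.interval.end)
                     for p in tiny_landscape.peaks)
        for (c1, s1, e1), (c2, s2, e2) in zip(ivs, ivs[1:]):
            if c1 == c2:
                assert s2 - e1 > 2 * 200

    def test_every_edge_condition_realized_by_peak_label(self, tiny_landscape):
        for e in tiny_landscape.truth_edges:
            label = tiny_landscape.peak_labels[e.peak_id]
            if e.condition == "shared":
                assert label == "unchanged"
            else:
                assert label == e.condition

    def test_hic_fraction_of_peaks_linked(self, tiny_landscape):
        land = tiny_landscape
        expected = round(land.params.hic_link_fraction * land.params.n_peaks)
        assert len(land.manifest["hic_peaks"]) == expected
        assert len(land.hic_links) == expected

    def test_infeasible_packing_raises_capacity_error(self):
        with pytest.raises(CapacityError):
            generate_landscape(tiny_params(chromosome_length=20_000,
                                           n_peaks=500))

    def test_landscape_determinism(self):
        a = generate_landscape(tiny_params(seed=5))
        b = generate_landscape(tiny_params(seed=5))
        assert a.genome == b.genome
        assert a.manifest["edges"] == b.manifest["edges"]
        assert a.counts.equals(b.counts)
        assert a.expression_a == b.expression_a


class TestTagCounts:
    def test_deterministic_sentinel_exact_means(self):
        p = tiny_params(nb_dispersion=math.inf, sequencing_depth=100.0,
                        planted_fold_change=4.0)
        land = generate_landscape(p)
        for peak in land.peaks:
            label = land.peak_labels[peak.peak_id]
            expect = {"A_specific": (400.0, 100.0),
                      "B_specific": (100.0, 400.0),
                      "unchanged": (100.0, 100.0)}[label]
            assert (peak.counts["sample_A"], peak.counts["sample_B"]) == expect

    def test_zero_depth_zero_counts(self):
        land = generate_landscape(tiny_params(sequencing_depth=0.0,
                                              nb_dispersion=10.0))
        assert all(v == 0 for p in land.peaks for v in p.counts.values())

    @pytest.mark.parametrize("mu", [10.0, 100.0, 1000.0])
    def test_nb_mean_within_three_standard_errors(self, mu):
        rng = np.random.default_rng(123)
        size = 10.0
        draws = nb_draw(rng, mu, size, size=10_000)
        se = math.sqrt((mu + mu * mu / size) / 10_000)
        assert abs(draws.mean() - mu) <= 3 * se

    def test_nb_variance_matches_parameterization(self):
        rng = np.random.default_rng(7)
        mu, size = 100.0, 10.0
        draws = nb_draw(rng, mu, size, size=200_000)
        assert draws.var() == pytest.approx(mu + mu * mu / size, rel=0.05)


class TestExpression:
    def test_zero_noise_recovers_planted_folds_exactly(self):
        land = generate_landscape(tiny_params(expression_noise_sd=0.0))
        planted = land.manifest["planted_log2fc"]
        for g, lfc in planted.items():
            got = math.log2(land.expression_b[g] / land.expression_a[g])
            assert got == pytest.approx(lfc, abs=1e-9)
        unplanted = set(land.expression_a) - set(planted)
        for g in unplanted:
            assert land.expression_a[g] == land.expression_b[g]

    def test_representative_planted_highest_at_zero_noise(self):
        land = generate_landscape(tiny_params(expression_noise_sd=0.0))
        for fam, members in land.families.items():
            rep = land.representatives[fam]
            top = max(members, key=lambda m: land.expression_a[m])
            assert top == rep

    def test_noise_sd_calibration(self):
        # recovered-minus-planted log2FC is a difference of two N(0, sd)
        land = generate_landscape(tiny_params(
            n_genes=1000, n_peaks=60, edge_density=0.02,
            expression_noise_sd=0.1, chromosome_length=2_000_000))
        planted = land.manifest["planted_log2fc"]
        errs = []
        for g in land.expression_a:
            got = math.log2(land.expression_b[g] / land.expression_a[g])
            errs.append(got - planted.get(g, 0.0))
        sd = np.std(errs)
        assert abs(sd - 0.1 * math.sqrt(2)) <= 0.1 * 0.1 * math.sqrt(2)


def test_spacing_simulator_plants_exact_offsets():
    from grnrewire import simulate_spacing_occurrences
    occ_a, occ_b = simulate_spacing_occurrences(n_peaks=10, spacing=35,
                                                decoys_per_peak=0, seed=3)
    by_peak = {o.peak_id: o.center for o in occ_a}
    planted = [o for o in occ_b if abs(o.center - by_peak[o.peak_id]) == 35]
    assert len(planted) == 10
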