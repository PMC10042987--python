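"""Simulator determinism, truth-recount equality and parameter recovery."""

import math
from collections import Counter

import pytest

import mitocomp as mc
import mitocomp.codon_usage as cu
from mitocomp.composition import base_composition
from mitocomp.genome_io import extract_feature_sequence, partition_regions
from mitocomp.simulate import (SimulationConfig, generate_cds, gene_plan,
                               plant_insertion, simulate_mitogenome)


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        r1, t1 = simulate_mitogenome(mc.ancestral_config(42))
        r2, t2 = simulate_mitogenome(mc.ancestral_config(42))
        assert r1.sequence == r2.sequence
        assert r1.features == r2.features
        assert t1.to_json() == t2.to_json()

    def test_different_seeds_differ(self):
        r1, _ = simulate_mitogenome(mc.ancestral_config(1))
        r2, _ = simulate_mitogenome(mc.ancestral_config(2))
        assert r1.sequence != r2.sequence


class TestDefaultPlan:
    def test_gene_census(self, ancestral_genome):
        record, _ = ancestral_genome
        assert len(record.features_by_category("PCG")) == 13
        assert len(record.features_by_category("tRNA")) == 22
        assert len(record.features_by_category("rRNA")) == 2
        assert len(record.features_by_category("control")) == 1

    def test_strand_census_matches_moth_genome(self, ancestral_genome):
        record, _ = ancestral_genome
        minus_trna = [f for f in record.features_by_category("tRNA")
                      if f.strand == "-"]
        minus_pcg = [f for f in record.features_by_category("PCG")
                     if f.strand == "-"]
        assert len(minus_trna) == 8
        assert len(minus_pcg) == 4

    def test_length_in_moth_regime(self, ancestral_genome, variant_genome):
        for record, _ in (ancestral_genome, variant_genome):
            assert 15_000 <= record.length <= 17_100

    def test_bad_pcg_length_rejected(self):
        plan = (("ND2", "PCG", 11, "+"),)   # 11 % 3 == 2
        with pytest.raises(ValueError):
            SimulationConfig(seed=0, plan=plan)


class TestTruthRecount:
    def test_codon_counts_recount_exactly(self, ancestral_genome):
        record, truth = ancestral_genome
        for f in record.features_by_category("PCG"):
            seq = extract_feature_sequence(record, f)
            table = cu.count_codons([seq])
            assert table.counts == Counter(truth.codon_counts[f.name]), f.name
            assert table.truncated == (1 if f.name in truth.truncated_genes
                                       else 0)

    def test_composition_recount_exactly(self, variant_genome):
        record, truth = variant_genome
        regions = dict(partition_regions(record))
        regions["Mitogenome"] = record.sequence
        for label, expected in truth.realized_composition.items():
            row = base_composition(regions[label])
            assert math.isclose(row.pct_a, expected["A"], abs_tol=1e-12)
            assert math.isclose(row.pct_g, expected["G"], abs_tol=1e-12)


class TestCompositionRecovery:
    def test_regions_within_three_sigma_of_targets(self, ancestral_genome):
        record, truth = ancestral_genome
        regions = partition_regions(record)
        for category, region_label in (("tRNA", "tRNAs"), ("rRNA", "rRNAs"),
                                       ("control", "D-loop")):
            seq = regions[category]
            row = base_composition(seq)
            weights = truth.target_base_weights[category]
            p = weights["A"] + weights["T"]
            sigma = 100 * math.sqrt(p * (1 - p) / len(seq))
            assert abs(row.pct_at - 100 * p) < 3 * sigma, category

    def test_high_at_control_region(self):
        config = mc.SimulationConfig(
            seed=3,
            base_weights={"tRNA": dict(A=0.4, T=0.4, C=0.1, G=0.1),
                          "rRNA": dict(A=0.4, T=0.4, C=0.1, G=0.1),
                          "control": dict(A=0.475, T=0.475, C=0.03, G=0.02),
                          "spacer": dict(A=0.475, T=0.475, C=0.03, G=0.02)})
        record, _ = simulate_mitogenome(config)
        row = base_composition(partition_regions(record)["control"])
        sigma = 100 * math.sqrt(0.95 * 0.05 / row.length)
        assert abs(row.pct_at - 95.0) < 3 * sigma


class TestGenerateCds:
    def test_degenerate_leu_weights_saturate_rscu(self):
        weights = {c: 1.0 for c in cu.INVERTEBRATE_MITO.sense_codons}
        for c in ("CUA", "CUC", "CUG", "CUU", "UUG"):
            weights[c] = 0.0
        weights["UUA"] = 1.0
        seq, _ = generate_cds(2000, weights, seed=0, start_codon="AUG")
        values = cu.rscu(cu.count_codons([seq]))
        assert math.isclose(values["UUA"], 6.0, rel_tol=1e-9)

    def test_truncated_stop_emits_trailing_t(self):
        weights = {c: 1.0 for c in cu.INVERTEBRATE_MITO.sense_codons}
        seq, _ = generate_cds(50, weights, truncated_stop=True, seed=1)
        assert len(seq) == 151 and seq.endswith("T")
        assert cu.count_codons([seq]).truncated == 1

    def test_two_seeds_same_length_different_sequence(self):
        weights = {c: 1.0 for c in cu.INVERTEBRATE_MITO.sense_codons}
        s1, _ = generate_cds(100, weights, seed=1)
        s2, _ = generate_cds(100, weights, seed=2)
        assert len(s1) == len(s2) == 300
        assert s1 != s2

    def test_zero_weight_family_rejected(self):
        weights = {c: 1.0 for c in cu.INVERTEBRATE_MITO.sense_codons}
        for c in cu.INVERTEBRATE_MITO.families["G"]:
            weights[c] = 0.0
        with pytest.raises(ValueError):
            generate_cds(10, weights, seed=0)


class TestPlantInsertion:
    def test_recovered_after_planting(self, ancestral_genome):
        record, _ = ancestral_genome
        grown = plant_insertion(record, ("trnS2", "ND1"), 423, 1.0, seed=9)
        assert grown.length == record.length + 423
        found = mc.detect_at_insertions(grown)
        assert [(i.left_gene, i.right_gene) for i in found] == \
            [("trnS2", "ND1")]
        assert found[0].length >= 423      # tract plus any spacer in the gap

    def test_two_junctions_order_preserved(self, ancestral_genome):
        record, _ = ancestral_genome
        grown = plant_insertion(record, ("trnR", "trnN"), 205, 1.0, seed=1)
        grown = plant_insertion(grown, ("trnE", "trnF"), 178, 1.0, seed=2)
        found = mc.detect_at_insertions(grown)
        names = [(i.left_gene, i.right_gene) for i in found]
        assert names == [("trnR", "trnN"), ("trnE", "trnF")]

    def test_zero_length_is_identity(self, ancestral_genome):
        record, _ = ancestral_genome
        assert plant_insertion(record, ("trnE", "trnF"), 0) is record

    def test_unknown_junction_rejected(self, ancestral_genome):
        record, _ = ancestral_genome
        with pytest.raises(ValueError):
            plant_insertion(record, ("COI", "ND5"), 100)


class TestConfigFile:
    def test_flat_key_value_parsing(self, tmp_path):
        path = tmp_path / "sim.cfg"
        path.write_text(
            "seed = 11\n"
            "preset = conopomorpha\n"
            "insert = trnR|trnA,205,1.0\n"
            "spacer = 0,0\n"
            "coi_cga_start = true\n")
        config = SimulationConfig.from_file(path)
        assert config.seed == 11
        assert config.plan == gene_plan("conopomorpha")
        assert config.planted_insertions == ((("trnR", "trnA"), 205, 1.0),)

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "sim.cfg"
        path.write_text("sede = 1\n")
        with pytest.raises(ValueError):
            SimulationConfig.from_file(path)
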