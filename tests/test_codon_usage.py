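"""Codon counting, RSCU, ENC, GC-by-position, PR2 and the start/stop census.

Independent oracles: RSCU and ENC are recomputed with naive standalone
loops (no shared code with the implementation) and must agree to machine
precision.
"""

import math
from collections import Counter

import pytest
from hypothesis import given, strategies as st

import mitocomp.codon_usage as cu
from mitocomp.codon_usage import INVERTEBRATE_MITO as CODE
from mitocomp.genome_io import GeneFeature, MitogenomeRecord
from mitocomp.reference_data import (CODON_COUNTS, RSCU_REPORTED,
                                     START_CODON_COUNTS)
from mitocomp.utils import round_half_up


def brute_force_rscu(counts: dict, families: dict) -> dict:
    """Naive RSCU: loop over families, k*count/total."""
    out = {}
    for codons in families.values():
        total = 0
        for c in codons:
            total += counts.get(c, 0)
        if total == 0:
            continue
        for c in codons:
            out[c] = len(codons) * counts.get(c, 0) / total
    return out


def brute_force_enc(counts: dict, families: dict) -> float:
    """Naive Wright estimator with class averaging and imputation."""
    per_class: dict = {}
    for codons in families.values():
        n = sum(counts.get(c, 0) for c in codons)
        if n < 2:
            continue
        f = (n * sum((counts.get(c, 0) / n) ** 2 for c in codons) - 1) / (n - 1)
        if f > 0:
            per_class.setdefault(len(codons), []).append(f)
    averages = {k: sum(v) / len(v) for k, v in per_class.items()}
    fallback = sum(averages.values()) / len(averages)
    total = 0.0
    sizes = Counter(len(c) for c in families.values())
    for k, n_aa in sizes.items():
        total += n_aa / averages.get(k, fallback)
    return min(max(total, 20.0), 62.0)


def reference_table() -> cu.CodonUsageTable:
    table = cu.CodonUsageTable(Counter(CODON_COUNTS), CODE)
    table.start_counts = Counter(START_CODON_COUNTS)
    return table


class TestGeneticCode:
    def test_table5_family_structure(self):
        sizes = Counter(len(c) for c in CODE.families.values())
        assert sizes == {2: 12, 4: 6, 6: 1, 8: 1}
        assert CODE.stop_codons == {"UAA", "UAG"}
        assert CODE.n_amino_acids == 20
        assert CODE.synonymous_capacity == 62

    def test_every_codon_maps_once(self):
        assert len(CODE.forward) + len(CODE.stop_codons) == 64


class TestCountCodons:
    def test_basic_triplets(self):
        t = cu.count_codons(["ATGAAATAA"])
        assert t.counts == Counter({"AUG": 1, "AAA": 1, "UAA": 1})
        assert t.n_codons == 3

    def test_truncated_stop_remainder(self):
        t = cu.count_codons(["ATGAAAT"])
        assert t.counts == Counter({"AUG": 1, "AAA": 1})
        assert t.truncated == 1

    def test_n_containing_codons_excluded(self):
        t = cu.count_codons(["ATGANATAA"])
        assert t.counts == Counter({"AUG": 1, "UAA": 1})
        assert t.ambiguous == 1

    def test_too_short_sequence_contributes_nothing(self):
        t = cu.count_codons(["AT"])
        assert t.n_codons == 0 and t.truncated == 0

    def test_simulated_counts_match_multinomial_expectation(
            self, ancestral_genome):
        # middle codons are uniform over 20 families; each family's share of
        # counts should be near n/20 within 4 sigma
        record, truth = ancestral_genome
        pooled = Counter()
        for gene_counts in truth.codon_counts.values():
            pooled += Counter(gene_counts)
        # drop start and stop codons which follow their own conventions
        n_genes = len(truth.codon_counts)
        n = sum(pooled.values()) - 2 * n_genes + len(truth.truncated_genes)
        p = 1 / 20
        sigma = math.sqrt(n * p * (1 - p))
        for aa, codons in CODE.families.items():
            fam_total = sum(pooled.get(c, 0) for c in codons)
            assert abs(fam_total - n * p) < 4 * sigma + 3


class TestRscu:
    def test_reported_spot_values(self):
        values = cu.rscu(reference_table())
        for codon, expected in RSCU_REPORTED.items():
            assert round_half_up(values[codon], 2) == expected, codon

    def test_agrees_with_brute_force_oracle(self):
        table = reference_table()
        values = cu.rscu(table)
        families = dict(CODE.families)
        families["Ter"] = tuple(sorted(CODE.stop_codons))
        oracle = brute_force_rscu(dict(table.counts), families)
        assert set(values) == set(oracle)
        for codon in values:
            assert math.isclose(values[codon], oracle[codon], rel_tol=1e-12)

    def test_uniform_usage_gives_rscu_one(self):
        counts = Counter({c: 5 for c in CODE.sense_codons})
        values = cu.rscu(cu.CodonUsageTable(counts, CODE))
        assert all(math.isclose(v, 1.0) for v in values.values())

    def test_met_start_compat_reproduces_folded_family(self):
        # published convention: starts folded into Met -> {AUA,AUG,AUU,CGA}
        values = cu.rscu(reference_table(), met_start_compat=True)
        assert round_half_up(values["AUA"], 2) == 3.61
        assert round_half_up(values["AUG"], 2) == 0.32

    def test_unused_family_absent(self):
        t = cu.count_codons(["ATGAAATAA"])
        values = cu.rscu(t)
        assert "GGA" not in values            # no Gly observed
        assert values["AAG"] == 0.0           # Lys family used via AAA only

    @given(st.dictionaries(st.sampled_from(sorted(CODE.sense_codons)),
                           st.integers(min_value=0, max_value=500),
                           min_size=5))
    def test_family_sums_equal_family_size(self, counts):
        table = cu.CodonUsageTable(Counter(counts), CODE)
        if table.n_codons == 0:
            return
        values = cu.rscu(table)
        for aa, codons in CODE.families.items():
            if sum(counts.get(c, 0) for c in codons) == 0:
                continue
            assert math.isclose(sum(values[c] for c in codons), len(codons),
                                rel_tol=1e-9)


class TestPositionGC:
    def test_all_gc_sequence(self):
        gc = cu.codon_position_gc(["GGGGGG"])
        assert gc.gc1 == gc.gc2 == gc.gc3 == 100.0

    def test_hand_counted_example(self):
        # codons AUG, CAU: GC at position 1 in 1/2, position 2 in 0/2,
        # position 3 in 1/2
        gc = cu.codon_position_gc(["ATGCAT"])
        assert (gc.gc1, gc.gc2, gc.gc3) == (50.0, 0.0, 50.0)

    def test_overall_is_mean_of_positions(self, variant_genome):
        record, _ = variant_genome
        cds = [cu.extract_feature_sequence(record, f)
               for f in record.features_by_category("PCG")]
        gc = cu.codon_position_gc(cds)
        assert math.isclose(gc.gc_overall, (gc.gc1 + gc.gc2 + gc.gc3) / 3,
                            abs_tol=1e-9)

    def test_at_biased_third_position_in_simulation(self, variant_genome):
        record, _ = variant_genome
        cds = [cu.extract_feature_sequence(record, f)
               for f in record.features_by_category("PCG")]
        gc = cu.codon_position_gc(cds)
        assert gc.gc3 < gc.gc1 and gc.gc3 < gc.gc2

    def test_no_codons_is_error(self):
        with pytest.raises(ValueError):
            cu.codon_position_gc(["TAA"])     # stop-only input


class TestEnc:
    def test_single_codon_per_family_floor(self):
        counts = Counter({codons[0]: 10
                          for codons in CODE.families.values()})
        assert cu.enc(cu.CodonUsageTable(counts, CODE)).enc == 20.0

    def test_uniform_usage_reaches_capacity(self):
        counts = Counter({c: 400 for c in CODE.sense_codons})
        assert cu.enc(cu.CodonUsageTable(counts, CODE)).enc == 62.0

    def test_agrees_with_brute_force_oracle(self):
        table = reference_table()
        oracle = brute_force_enc(dict(table.counts), dict(CODE.families))
        assert math.isclose(cu.enc(table).enc, oracle, rel_tol=1e-12)

    def test_bias_strength_orders_enc(self):
        # sharper within-family concentration => lower ENC
        import numpy as np
        rng = np.random.default_rng(0)
        encs = []
        for conc in (0.05, 1.0, 50.0):
            counts = Counter()
            for codons in CODE.families.values():
                p = rng.dirichlet([conc] * len(codons))
                draws = rng.multinomial(400, p)
                counts.update({c: int(n) for c, n in zip(codons, draws)})
            encs.append(cu.enc(cu.CodonUsageTable(counts, CODE)).enc)
        assert encs[0] < encs[1] < encs[2]

    def test_no_scorable_family_is_error(self):
        counts = Counter({"AUG": 1})
        with pytest.raises(ValueError):
            cu.enc(cu.CodonUsageTable(counts, CODE))

    @given(st.dictionaries(st.sampled_from(sorted(CODE.sense_codons)),
                           st.integers(min_value=0, max_value=300),
                           min_size=10))
    def test_enc_bounds(self, counts):
        table = cu.CodonUsageTable(Counter(counts), CODE)
        try:
            result = cu.enc(table)
        except ValueError:
            return
        assert 20.0 <= result.enc <= 62.0


class TestEncExpected:
    def test_midpoint(self):
        assert cu.enc_expected(0.5) == 60.5

    def test_endpoints(self):
        assert cu.enc_expected(0.0) == 31.0
        assert cu.enc_expected(1.0) == 32.0

    def test_curve_maximum_near_half(self):
        grid = [i / 1000 for i in range(1001)]
        values = [cu.enc_expected(s) for s in grid]
        assert abs(grid[values.index(max(values))] - 0.5) < 0.01

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cu.enc_expected(1.2)


class TestEncFilter:
    def test_reported_screen_arithmetic(self):
        values = [30.0] * 152 + [40.0] * 17
        below, above, pct = cu.enc_filter(values, threshold=35)
        assert (below, above) == (152, 17)
        assert round_half_up(pct, 2) == 10.06

    def test_all_below(self):
        below, above, pct = cu.enc_filter([20.0, 30.0], threshold=35)
        assert (below, above, pct) == (2, 0, 0.0)

    def test_constructed_exceedances_recovered_exactly(self):
        values = [34.9, 35.0, 35.1, 50.0]
        below, above, pct = cu.enc_filter(values)
        assert (below, above) == (2, 2)
        assert pct == 50.0


class TestPr2:
    def test_balanced_third_positions(self):
        counts = Counter({"AAA": 5, "AAU": 5, "AAG": 5, "AAC": 5})
        p = cu.pr2_point(cu.CodonUsageTable(counts, CODE))
        assert (p.x, p.y) == (0.5, 0.5)

    def test_undefined_component_signalled(self):
        counts = Counter({"AAA": 3, "AAU": 1})
        p = cu.pr2_point(cu.CodonUsageTable(counts, CODE))
        assert p.x is None and p.y == 0.75

    def test_uc_biased_simulation_lands_below_left(self):
        # third-position weights favouring U and C => y < 0.5 and x < 0.5
        import mitocomp as mc
        weights = {c: (5.0 if c[2] in "UC" else 1.0)
                   for c in CODE.sense_codons}
        config = mc.SimulationConfig(seed=5, codon_weights=weights,
                                     coi_cga_start=False)
        record, _ = mc.simulate_mitogenome(config)
        cds = {f.name: cu.extract_feature_sequence(record, f)
               for f in record.features_by_category("PCG")}
        p = cu.pr2_point(cu.count_codons(cds))
        assert p.y < 0.5 and p.x < 0.5

    @given(st.dictionaries(
        st.sampled_from(sorted(c for c in CODE.sense_codons
                               if not c.startswith("UA"))),
        st.integers(min_value=0, max_value=200), min_size=8))
    def test_complement_symmetry(self, counts):
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        flipped = Counter()
        for codon, n in counts.items():
            flipped[codon[:2] + comp[codon[2]]] += n
        t1 = cu.CodonUsageTable(Counter(counts), CODE)
        t2 = cu.CodonUsageTable(flipped, CODE)
        try:
            p1, p2 = cu.pr2_point(t1), cu.pr2_point(t2)
        except ValueError:
            return
        if p1.x is not None and p2.x is not None:
            assert math.isclose(p1.x, 1 - p2.x, abs_tol=1e-12)
        if p1.y is not None and p2.y is not None:
            assert math.isclose(p1.y, 1 - p2.y, abs_tol=1e-12)


class TestStartStopCensus:
    def test_nonstandard_start_and_truncation_flags(self):
        seq = "CGAAAATAA" + "ATTAAAT" + "AAAA"
        rec = MitogenomeRecord(
            "toy", seq + "A" * 30,
            features=(GeneFeature("COI", "PCG", 0, 9, "+"),
                      GeneFeature("ND2", "PCG", 9, 16, "+")))
        census = {c.gene: c for c in cu.start_stop_census(rec)}
        assert census["COI"].start_codon == "CGA"
        assert census["COI"].nonstandard_start
        assert census["COI"].stop == "UAA" and not census["COI"].truncated
        assert census["ND2"].start_codon == "AUU"
        assert not census["ND2"].nonstandard_start
        assert census["ND2"].truncated and census["ND2"].stop == "U"

    def test_simulated_record_flags_only_coi(self, variant_genome):
        record, truth = variant_genome
        census = cu.start_stop_census(record)
        assert [c.gene for c in census if c.nonstandard_start] == ["COI"]
        assert sorted(c.gene for c in census if c.truncated) == \
            sorted(truth.truncated_genes)


class TestPerGeneStats:
    def test_one_row_per_pcg_with_finite_stats(self, variant_genome):
        record, _ = variant_genome
        df = cu.per_gene_stats(record)
        assert len(df) == 13
        assert df["ENC"].between(20, 62).all()
        assert df["GC3"].between(0, 100).all()
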