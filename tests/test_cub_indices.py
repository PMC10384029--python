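"""ENc, RSCU, CAI, optimal codons, Gravy and Aroma."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from cubkit.cub_indices import (
    UnresolvableWeightError,
    aroma,
    cai,
    cai_weights,
    enc,
    enc_expected,
    enc_ratio,
    family_f,
    gravy,
    optimal_codons,
    rscu,
)
from cubkit.multivariate import build_rscu_matrix
from cubkit.sequence_io import CdsRecord, CodonCounts, count_codons
from cubkit.synthetic_data import SyntheticSpec, generate_corpus


def make_counts(counts, code, gene_id="g"):
    n = sum(v for c, v in counts.items() if c not in code.excluded_codons)
    return CodonCounts(gene_id, counts, n)


class TestFamilyF:
    @pytest.mark.parametrize("c", [0, 1, 17, 10_000])
    def test_balanced_twofold_is_exactly_half(self, c):
        assert family_f([c, c]) == pytest.approx(0.5, abs=1e-15)

    def test_single_observation_twofold(self):
        assert family_f([1, 0]) == pytest.approx((2 / 3) ** 2 + (1 / 3) ** 2)

    @given(st.lists(st.integers(0, 500), min_size=6, max_size=6))
    def test_sixfold_matches_literal_summation(self, counts):
        assert family_f(counts) == pytest.approx(
            oracles.family_f_literal(counts), rel=1e-12
        )

    def test_zero_counts_give_uniform_value(self):
        assert family_f([0, 0, 0, 0]) == pytest.approx(0.25)

    def test_singleton_family_rejected(self):
        with pytest.raises(ValueError):
            family_f([5], m=1)


class TestEnc:
    def test_uniform_usage_is_exactly_61(self, code):
        counts = {c: 7 for c in code.analyzed_codons}
        assert enc(make_counts(counts, code), code) == pytest.approx(61.0, abs=1e-12)

    def test_one_codon_per_family_approaches_20(self, code):
        counts = {fam.codons[0]: 10_000 for fam in code.cub_families}
        assert enc(make_counts(counts, code), code) == pytest.approx(20.0, abs=0.05)

    def test_random_gene_matches_brute_force(self, code, random_counts):
        for seed in range(5):
            cc = random_counts(80, seed=seed)
            assert enc(cc, code) == pytest.approx(
                oracles.enc_literal(cc.counts), rel=1e-12
            )

    def test_monotone_decrease_as_one_codon_dominates(self, code):
        values = []
        for extra in (0, 5, 20, 100):
            counts = {c: 10 for c in code.analyzed_codons}
            counts["GCT"] += extra
            values.append(enc(make_counts(counts, code), code))
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_scale_invariance_at_large_counts(self, code):
        # pseudocounts vanish relative to large counts, so scaling changes
        # ENc only at O(m/n)
        rng = np.random.default_rng(9)
        counts = {c: int(rng.integers(500, 1500)) for c in code.analyzed_codons}
        base = make_counts(counts, code)
        scaled = make_counts({c: 7 * n for c, n in counts.items()}, code)
        assert enc(scaled, code) == pytest.approx(enc(base, code), abs=0.05)

    def test_empty_gene_raises(self, code):
        with pytest.raises(ValueError):
            enc(CodonCounts("g", {"ATG": 1}, 0), code)


class TestEncExpectedCurve:
    @pytest.mark.parametrize("s,val", [(0.5, 60.5), (0.0, 31.0), (1.0, 32.0)])
    def test_printed_anchor_points(self, s, val):
        assert enc_expected(s) == pytest.approx(val)

    def test_pointwise_formula_on_grid(self):
        for s in np.linspace(0, 1, 1000):
            assert enc_expected(s) == pytest.approx(
                oracles.enc_expected_literal(s), rel=1e-14
            )

    def test_near_maximum_at_half(self):
        # true max sits at s ≈ 0.502 because of the linear term
        grid = np.linspace(0, 1, 1001)
        vals = [enc_expected(s) for s in grid]
        assert grid[int(np.argmax(vals))] == pytest.approx(0.5, abs=0.01)
        assert max(vals) == pytest.approx(60.5, abs=0.005)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            enc_expected(1.2)


class TestEncRatio:
    def test_worked_quotient(self):
        assert enc_ratio(50.0, 40.0) == pytest.approx(0.2)

    def test_identity_is_zero(self):
        assert enc_ratio(42.0, 42.0) == 0.0

    def test_recomputed_band_on_random_genes(self, code, random_counts):
        from cubkit.composition import composition_profile

        for seed in range(5):
            cc = random_counts(200, seed=seed)
            gc3s = composition_profile(cc, code).gc3s
            ratio = enc_ratio(enc_expected(gc3s), enc(cc, code))
            assert -1.0 < ratio < 1.0

    def test_nonpositive_expected_raises(self):
        with pytest.raises(ValueError):
            enc_ratio(0.0, 10.0)


class TestRscu:
    def test_balanced_twofold_unbiased(self, code):
        t = rscu(make_counts({"AAA": 2, "AAG": 2}, code), code)
        assert t["AAA"] == t["AAG"] == 1.0
        assert t.classes["AAA"] == "unbiased"

    def test_three_to_one_twofold(self, code):
        t = rscu(make_counts({"AAA": 3, "AAG": 1}, code), code)
        assert t["AAA"] == pytest.approx(1.5)
        assert t["AAG"] == pytest.approx(0.5)
        assert t.classes["AAA"] == "average" and t.classes["AAG"] == "under"

    def test_over_representation_class(self, code):
        t = rscu(make_counts({"GCT": 9, "GCA": 1, "GCC": 1, "GCG": 1}, code), code)
        assert t["GCT"] == pytest.approx(3.0) and t.classes["GCT"] == "over"

    @given(st.lists(st.integers(0, 99), min_size=6, max_size=6).filter(sum))
    def test_sixfold_family_sums_to_degeneracy(self, code, counts):
        leu = next(f for f in code.cub_families if f.amino_acid == "L")
        t = rscu(dict(zip(leu.codons, counts)), code)
        assert sum(t[c] for c in leu.codons) == pytest.approx(6.0)

    def test_matches_normalization_oracle(self, code, random_counts):
        cc = random_counts(400, seed=21)
        want = oracles.rscu_literal(cc.counts)
        got = rscu(cc, code)
        assert got.values.keys() == want.keys()
        for c, v in want.items():
            assert got[c] == pytest.approx(v, rel=1e-12)

    def test_scale_invariance_exact(self, code, random_counts):
        cc = random_counts(150, seed=4)
        scaled = rscu({c: 13 * n for c, n in cc.counts.items()}, code)
        base = rscu(cc, code)
        for c in base.values:
            assert scaled[c] == pytest.approx(base[c], rel=1e-12)

    def test_unobserved_family_flagged_not_nan(self, code):
        t = rscu(make_counts({"AAA": 4}, code), code)
        assert "R" in t.undefined_families
        assert not any(v != v for v in t.values.values())  # no NaN


class TestCaiWeights:
    def test_ratio_to_max(self, code):
        ref = {c: 1 for c in code.analyzed_codons}
        ref.update({"AAA": 10, "AAG": 5})
        w = cai_weights(make_counts(ref, code, "ref"), code)
        assert w["AAA"] == 1.0 and w["AAG"] == 0.5

    def test_uniform_reference_all_ones(self, code):
        w = cai_weights(make_counts({c: 3 for c in code.analyzed_codons}, code), code)
        assert all(v == 1.0 for v in w.values())

    def test_matches_ratio_oracle_with_pseudo(self, code, random_counts):
        ref = random_counts(500, seed=8)
        want = oracles.cai_weights_literal(ref.counts)
        got = cai_weights(ref, code)
        assert got.keys() == want.keys()
        for c, v in want.items():
            assert got[c] == pytest.approx(v, rel=1e-12)

    def test_family_max_is_one(self, code, random_counts):
        w = cai_weights(random_counts(500, seed=12), code)
        for fam in code.cub_families:
            assert max(w[c] for c in fam.codons) == pytest.approx(1.0)

    def test_missing_family_raises_named_error(self, code):
        with pytest.raises(UnresolvableWeightError, match="R"):
            cai_weights(make_counts({"AAA": 5}, code), code)


class TestCai:
    def test_all_optimal_gene_is_one(self, code, random_counts):
        w = cai_weights(random_counts(800, seed=3, gene_id="ref"), code)
        best = {fam.amino_acid: max(fam.codons, key=lambda c: w[c])
                for fam in code.cub_families}
        gene = make_counts({c: 5 for c in best.values()}, code)
        assert cai(gene, w) == pytest.approx(1.0)

    def test_two_codon_geometric_mean(self, code):
        w = {"AAA": 1.0, "GCT": 0.25}
        gene = make_counts({"AAA": 1, "GCT": 1}, code)
        assert cai(gene, w) == pytest.approx(0.5)

    def test_matches_exp_mean_log_oracle(self, code, random_counts):
        ref = random_counts(600, seed=5, gene_id="ref")
        w = cai_weights(ref, code)
        for seed in range(4):
            cc = random_counts(150, seed=seed)
            assert cai(cc, w) == pytest.approx(
                oracles.cai_literal(cc.counts, w), rel=1e-12
            )

    def test_range_and_length_invariance(self, code, random_counts):
        w = cai_weights(random_counts(600, seed=5, gene_id="ref"), code)
        cc = random_counts(120, seed=6)
        value = cai(cc, w)
        assert 0.0 < value <= 1.0
        tripled = make_counts({c: 3 * n for c, n in cc.counts.items()}, code)
        assert cai(tripled, w) == pytest.approx(value, rel=1e-12)


class TestOptimalCodons:
    def test_uniform_corpus_has_no_signal(self, code):
        genes = [
            make_counts({c: 10 + (i % 2) for c in code.analyzed_codons}, code, f"g{i}")
            for i in range(12)
        ]
        matrix = build_rscu_matrix(genes, code)
        encs = [enc(cc, code) for cc in genes]
        result = optimal_codons(matrix.values, encs, code)
        assert all(oc.codon is None for oc in result)

    def test_recovers_planted_codon_per_family(self, code):
        spec = SyntheticSpec(
            n_genes=80, preference_strength=2.5, gc3_target=0.5, seed=42
        )
        records, truth = generate_corpus(spec)
        genes = [count_codons(r, code) for r in records]
        matrix = build_rscu_matrix(genes, code)
        encs = [enc(cc, code) for cc in genes]
        result = optimal_codons(matrix.values, encs, code)
        chosen = {oc.amino_acid: oc.codon for oc in result}
        hits = sum(
            chosen[aa] == codon for aa, codon in truth.preferred_codons.items()
        )
        assert hits >= 16  # at least 16/18 families at this strength

    def test_too_few_genes_raises(self, code, random_counts):
        genes = [random_counts(100, seed=s, gene_id=f"g{s}") for s in range(4)]
        matrix = build_rscu_matrix(genes, code)
        with pytest.raises(ValueError):
            optimal_codons(matrix.values, [50.0] * 4, code)


class TestProteinProps:
    def test_poly_ile_gravy(self, code):
        assert gravy(make_counts({"ATT": 40}, code), code) == pytest.approx(4.5)

    def test_ile_asn_mean(self, code):
        cc = make_counts({"ATT": 10, "AAT": 10}, code)
        assert gravy(cc, code) == pytest.approx(0.5)

    def test_hydrophilic_gene_negative(self, code):
        cc = make_counts({"AAA": 5, "GAT": 5, "CGT": 5}, code)  # K, D, R
        assert gravy(cc, code) < 0

    def test_aroma_counts_trp_in_both_sides(self, code):
        # F, Y, G and one W: aromatic = 3 of 4 residues
        cc = make_counts({"TTT": 1, "TAT": 1, "GGT": 1, "TGG": 1}, code)
        assert aroma(cc, code) == pytest.approx(3 / 4)

    def test_no_aromatics_is_zero(self, code):
        assert aroma(make_counts({"GCT": 10}, code), code) == 0.0

    def test_random_gene_matches_residue_tally_oracle(self, code, random_counts):
        cc = random_counts(300, seed=13)
        assert gravy(cc, code) == pytest.approx(
            oracles.gravy_literal(cc.counts), rel=1e-12
        )
        assert aroma(cc, code) == pytest.approx(
            oracles.aroma_literal(cc.counts), rel=1e-12
        )
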