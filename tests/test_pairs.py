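import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from codonbias.pairs import (
    NONSYNONYMOUS_PAIRS,
    audic_claverie_p,
    audic_claverie_pmf,
    call_bias,
    call_pair_bias,
    classify_high_frequency_pairs,
    count_pairs,
    junction_profile,
    pair_family_shares,
    rscpu,
)
from codonbias.seqio import OrfRecord
from codonbias.synth import GeneratorSpec, generate_corpus, sc_shuffle
from codonbias.tables import CODON_TO_AA, DEGENERACY, SENSE_CODONS, STOP_CODONS

from conftest import make_orf


def brute_force_pairs(records, distance):
    """Independent oracle: double loop over interior codons of each gene."""
    counts = Counter()
    for rec in records:
        interior = rec.codons()[1:-1]
        for t in range(len(interior) - 1 - distance):
            counts[(interior[t], interior[t + 1 + distance])] += 1
    return counts


class TestCountPairs:
    def test_toy_neighbouring(self, toy3):
        pt = count_pairs([toy3], 0)
        assert pt.count("CTG", "CTG") == 2
        assert pt.total_pairs == 2

    def test_toy_spaced(self, toy3):
        pt = count_pairs([toy3], 1)
        assert pt.count("CTG", "CTG") == 1
        assert pt.total_pairs == 1

    def test_no_cross_gene_pairs(self):
        g1 = OrfRecord(id="a", cds="ATGGAAGAGTAA")
        g2 = OrfRecord(id="b", cds="ATGCTGCTGTAA")
        combined = count_pairs([g1, g2], 0)
        separate = count_pairs([g1], 0).counts + count_pairs([g2], 0).counts
        assert np.array_equal(combined.counts, separate)

    def test_matches_brute_force_oracle(self):
        records, _ = generate_corpus(GeneratorSpec(n_genes=4, seed=42))
        for d in (0, 2, 5):
            pt = count_pairs(records, d)
            oracle = brute_force_pairs(records, d)
            for (a, b), n in oracle.items():
                assert pt.count(a, b) == n
            assert pt.total_pairs == sum(oracle.values())

    def test_total_pairs_budget(self):
        records, _ = generate_corpus(GeneratorSpec(n_genes=20, seed=7))
        for d in range(6):
            pt = count_pairs(records, d)
            expected = sum(
                max(0, (r.n_codons - 2) - 1 - d) for r in records
            )
            assert pt.total_pairs == expected

    def test_frequency_normalisation(self, uniform_corpus):
        pt = count_pairs(uniform_corpus[:200], 0)
        assert pt.obs_freq.sum() == pytest.approx(1.0, abs=1e-9)
        assert pt.exp_freq.sum() == pytest.approx(1.0, abs=1e-9)


def brute_force_rscpu(records):
    """Oracle for RSCPU from raw definitions."""
    pair_counts = brute_force_pairs(records, 0)
    fam_counts = Counter()
    for (a, b), n in pair_counts.items():
        fam_counts[(CODON_TO_AA[a], CODON_TO_AA[b])] += n
    out = {}
    for (a, b), n in pair_counts.items():
        if (a, b) in NONSYNONYMOUS_PAIRS:
            continue
        fam = fam_counts[(CODON_TO_AA[a], CODON_TO_AA[b])]
        expected = fam / (DEGENERACY[CODON_TO_AA[a]] * DEGENERACY[CODON_TO_AA[b]])
        out[(a, b)] = n / expected
    return out


class TestRscpu:
    def test_hand_glu_glu(self):
        # four GAGGAG pairs and nothing else in the GluGlu family
        rec = OrfRecord(id="g", cds="ATG" + "GAG" * 5 + "TAA")
        table = count_pairs([rec], 0)
        values = rscpu(table)
        assert values[("GAG", "GAG")] == pytest.approx(4.0)

    def test_uniform_corpus_near_one(self, uniform_corpus):
        values = rscpu(count_pairs(uniform_corpus, 0))
        arr = np.array(list(values.values()))
        # heavy families are tight; allow the 10% recovery tolerance
        assert np.median(np.abs(arr - 1.0)) < 0.1

    def test_matches_brute_force_oracle(self):
        records, _ = generate_corpus(GeneratorSpec(n_genes=5, seed=13))
        values = rscpu(count_pairs(records, 0))
        oracle = brute_force_rscpu(records)
        for pair, v in oracle.items():
            assert values[pair] == pytest.approx(v, abs=1e-12)

    def test_family_mean_is_one(self, uniform_corpus):
        pt = count_pairs(uniform_corpus[:300], 0)
        values = rscpu(pt)
        by_family: dict = {}
        for (a, b), v in values.items():
            by_family.setdefault((CODON_TO_AA[a], CODON_TO_AA[b]), []).append(v)
        for (aa1, aa2), vals in by_family.items():
            expected_members = DEGENERACY[aa1] * DEGENERACY[aa2]
            if len(vals) == expected_members:  # family fully enumerated
                assert np.mean(vals) == pytest.approx(1.0, abs=1e-9)


class TestHighFrequencyPairs:
    def test_rscpu_gate(self):
        rm = {("CTG", "CTG"): 5.82, ("CTG", "CTT"): 0.4}
        shares = {("CTG", "CTG"): 0.5, ("CTG", "CTT"): 0.1}
        assert classify_high_frequency_pairs(rm, shares) == {("CTG", "CTG")}

    def test_share_gate(self):
        rm = {("GAG", "GAG"): 1.2}
        shares = {("GAG", "GAG"): 0.62}
        assert classify_high_frequency_pairs(rm, shares) == {("GAG", "GAG")}

    def test_uniform_none(self):
        rm = {("GAG", "GAA"): 1.0}
        shares = {("GAG", "GAA"): 0.25}
        assert classify_high_frequency_pairs(rm, shares) == set()


def brute_force_ac_pmf(x, y, ratio):
    return (
        ratio**y
        * math.factorial(x + y)
        / (math.factorial(x) * math.factorial(y) * (1 + ratio) ** (x + y + 1))
    )


class TestAudicClaverie:
    def test_closed_form_zero_zero(self):
        assert audic_claverie_pmf(0, 0, 100, 100) == pytest.approx(0.5)
        assert audic_claverie_p(0, 0, 100, 100) == pytest.approx(1.0)

    def test_closed_form_five_zero(self):
        assert audic_claverie_pmf(5, 0, 100, 100) == pytest.approx(1 / 64)

    def test_symmetric_counts_p_one(self):
        for x in (0, 3, 17):
            assert audic_claverie_p(x, x, 1000, 1000) == pytest.approx(1.0)

    @pytest.mark.parametrize("x,y", [(0, 0), (2, 5), (10, 3), (7, 7)])
    def test_pmf_matches_factorial_formula(self, x, y):
        for n1, n2 in [(100, 100), (50, 200)]:
            oracle = brute_force_ac_pmf(x, y, n2 / n1)
            assert audic_claverie_pmf(x, y, n1, n2) == pytest.approx(oracle)

    def test_two_sided_is_doubled_smaller_tail(self):
        # oracle: explicit tail sums of the pmf
        x, n1, n2 = 6, 120, 80
        for y in (0, 4, 9):
            lower = sum(brute_force_ac_pmf(x, k, n2 / n1) for k in range(y + 1))
            upper = 1 - sum(
                brute_force_ac_pmf(x, k, n2 / n1) for k in range(y)
            )
            expected = min(1.0, 2 * min(lower, upper))
            assert audic_claverie_p(x, y, n1, n2) == pytest.approx(expected)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            audic_claverie_p(-1, 0, 10, 10)


class TestCallBias:
    def test_strong_ratio_significant(self):
        observed = {"a": 800, "b": 100}
        expected = {"a": 0.1, "b": 0.9}
        calls = {c.item: c for c in call_bias(observed, expected, 900)}
        assert calls["a"].verdict == "preferred"
        assert calls["b"].verdict == "avoided"

    def test_small_n_gated_by_significance(self):
        # 8-fold ratio but tiny counts: not significant
        observed = {"a": 2, "b": 6}
        expected = {"a": 1 / 32, "b": 31 / 32}
        calls = {c.item: c for c in call_bias(observed, expected, 8)}
        assert calls["a"].verdict == "unbiased"

    def test_p_floor(self):
        observed = {"a": 10000, "b": 0}
        expected = {"a": 0.01, "b": 0.99}
        calls = call_bias(observed, expected, 10000, floor=1e-10)
        assert min(c.p for c in calls) >= 1e-10

    def test_continuity_correction_on_zero(self):
        observed = {"a": 0, "b": 100}
        expected = {"a": 0.2, "b": 0.8}
        calls = {c.item: c for c in call_bias(observed, expected, 100)}
        assert calls["a"].log2_ratio == pytest.approx(math.log2(0.5 / 20.5))


class TestInjectionAndNull:
    def test_injected_pair_detected(self):
        spec = GeneratorSpec(n_genes=400, seed=5, pair_coupling={("TCG", "TCG"): 8.0})
        records, truth = generate_corpus(spec)
        calls = call_pair_bias(count_pairs(records, 0))
        preferred = {c.item for c in calls if c.verdict == "preferred"}
        assert preferred == {("TCG", "TCG")}

    def test_distance_decay(self):
        spec = GeneratorSpec(n_genes=400, seed=5, pair_coupling={("TCG", "TCG"): 8.0})
        records, _ = generate_corpus(spec)
        n_sig_d0 = sum(
            c.verdict != "unbiased"
            for c in call_pair_bias(count_pairs(records, 0))
        )
        for d in range(1, 6):
            n_sig = sum(
                c.verdict != "unbiased"
                for c in call_pair_bias(count_pairs(records, d))
            )
            assert n_sig <= n_sig_d0

    def test_sc_shuffle_type_i_control(self, uniform_corpus):
        shuffled = sc_shuffle(uniform_corpus[:500], seed=3)
        calls = call_pair_bias(count_pairs(shuffled, 0))
        frac = sum(c.verdict != "unbiased" for c in calls) / len(calls)
        assert frac <= 0.01


class TestJunctionProfile:
    def test_junction_extraction(self, uniform_corpus):
        profile = junction_profile(count_pairs(uniform_corpus[:200], 0))
        assert set(len(k) for k in profile) == {2}
        assert len(profile) == 16
        # GAG|GAA style pairs land in the GG group: group sizes must sum to 3721
        assert sum(v["n_pairs"] for v in profile.values()) == 61 * 61

    def test_null_medians_near_one(self, uniform_corpus):
        profile = junction_profile(count_pairs(uniform_corpus, 0))
        for v in profile.values():
            assert v["median"] == pytest.approx(1.0, abs=0.1)
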