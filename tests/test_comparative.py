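import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster

from codonbias.comparative import (
    build_profiles,
    cluster_species_rscu,
    context_residuals,
    linkage_to_newick,
    pca_gene_rscu,
    pca_rscu,
    species_context_tree,
)
from codonbias.pairs import PairTable, count_pairs
from codonbias.synth import GeneratorSpec, generate_corpus


def _corpus(seed, codon_weights=None, n_genes=60):
    records, _ = generate_corpus(
        GeneratorSpec(n_genes=n_genes, seed=seed, codon_weights=codon_weights or {})
    )
    return records


@pytest.fixture(scope="module")
def clade_profiles():
    """Two clades with distinct RSCU centroids plus per-species noise seeds."""
    biased = {"E": [0.9, 0.1], "K": [0.9, 0.1], "Q": [0.9, 0.1], "L": None}
    biased = {k: v for k, v in biased.items() if v}
    corpora = {}
    for i in range(3):
        corpora[f"cladeA_{i}"] = _corpus(100 + i, biased)
    for i in range(3):
        corpora[f"cladeB_{i}"] = _corpus(200 + i, {k: v[::-1] for k, v in biased.items()})
    return build_profiles(corpora, prefiltered=True)


class TestBuildProfiles:
    def test_identical_corpora_identical_profiles(self):
        records = _corpus(1)
        profiles = build_profiles(
            {"s1": records, "s2": records}, prefiltered=True
        )
        a, b = profiles
        assert np.array_equal(a.rscu_vector, b.rscu_vector)
        assert np.array_equal(a.residual_matrix, b.residual_matrix)
        assert a.n_codons == b.n_codons

    def test_gc3_ordering_recovered(self):
        lo = _corpus(2, {"E": [0.8, 0.2], "K": [0.8, 0.2], "D": [0.8, 0.2]})
        hi = _corpus(3, {"E": [0.2, 0.8], "K": [0.2, 0.8], "D": [0.8, 0.2]})
        profiles = build_profiles({"low": lo, "high": hi}, prefiltered=True)
        by_name = {p.name: p for p in profiles}
        assert by_name["low"].gc.gc3 < by_name["high"].gc.gc3

    def test_empty_corpus_excluded(self):
        profiles = build_profiles({"ok": _corpus(4), "empty": []})
        assert [p.name for p in profiles] == ["ok"]


class TestClustering:
    def test_identical_pair_merges_first(self):
        records = _corpus(5)
        other = _corpus(6, {"E": [0.95, 0.05], "K": [0.95, 0.05]})
        profiles = build_profiles(
            {"A": records, "B": records, "C": other}, prefiltered=True
        )
        species_tree, _, _ = cluster_species_rscu(profiles)
        # A and B identical -> first merge joins leaves 0 and 1 at height ~0
        first = species_tree.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-9)

    def test_clade_partition_recovered(self, clade_profiles):
        species_tree, _, heat = cluster_species_rscu(clade_profiles)
        assign = fcluster(species_tree.linkage, t=2, criterion="maxclust")
        groups = {}
        for label, cl in zip(species_tree.labels, assign):
            groups.setdefault(cl, set()).add(label.split("_")[0])
        assert set(map(frozenset, groups.values())) == {
            frozenset({"cladeA"}),
            frozenset({"cladeB"}),
        }
        assert heat.shape == (6, 59)

    def test_newick_roundtrip_topology(self, clade_profiles):
        from io import StringIO

        from Bio import Phylo

        species_tree, _, _ = cluster_species_rscu(clade_profiles)
        tree = Phylo.read(StringIO(species_tree.newick), "newick")
        names = sorted(t.name for t in tree.get_terminals())
        assert names == sorted(p.name for p in clade_profiles)

    def test_rank_metric_supported(self, clade_profiles):
        species_tree, _, _ = cluster_species_rscu(clade_profiles, metric="spearman")
        assert species_tree.linkage.shape == (5, 4)

    def test_deterministic(self, clade_profiles):
        t1, _, h1 = cluster_species_rscu(clade_profiles)
        t2, _, h2 = cluster_species_rscu(clade_profiles)
        assert t1.newick == t2.newick
        assert h1.equals(h2)


class TestPca:
    def test_variance_ratios_sum_to_one(self, clade_profiles):
        result = pca_rscu(clade_profiles)
        assert result.variance_ratios.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rank_one_case(self):
        base = np.linspace(0.5, 1.5, 59)
        m = np.vstack([base * s for s in (1.0, 1.3, 1.9, 2.4)])
        result = pca_gene_rscu(m, ["a", "b", "c", "d"])
        assert result.variance_ratios[0] == pytest.approx(1.0)

    def test_group_separation_on_pc1(self, clade_profiles):
        result = pca_rscu(clade_profiles)
        pc1 = result.scores["PC1"]
        a = [pc1[p.name] for p in clade_profiles if "cladeA" in p.name]
        b = [pc1[p.name] for p in clade_profiles if "cladeB" in p.name]
        assert max(a) < min(b) or max(b) < min(a)
        assert result.variance_ratios[0] > 0.8

    def test_input_order_invariance_up_to_sign(self, clade_profiles):
        r1 = pca_rscu(clade_profiles)
        r2 = pca_rscu(clade_profiles[::-1])
        for name in r1.scores.index:
            assert r1.scores.loc[name, "PC1"] == pytest.approx(
                r2.scores.loc[name, "PC1"], abs=1e-8
            )


class TestContextResiduals:
    def test_hand_2x2_block(self):
        counts = np.zeros((61, 61), dtype=np.int64)
        counts[0, 0] = 10
        counts[1, 1] = 10
        pt = PairTable(0, counts, 20, np.ones(61) / 61)
        r = context_residuals(pt)
        assert r[0, 0] == pytest.approx(4.4721, abs=1e-4)
        assert r[0, 1] == pytest.approx(-4.4721, abs=1e-4)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(11)
        counts = rng.integers(0, 50, size=(61, 61))
        pt = PairTable(0, counts, int(counts.sum()), np.ones(61) / 61)
        r = context_residuals(pt)
        n = counts.sum()
        row = counts.sum(1)
        col = counts.sum(0)
        for i in (0, 17, 60):
            for j in (3, 44):
                e = row[i] * col[j] / n
                denom = np.sqrt(e * (1 - row[i] / n) * (1 - col[j] / n))
                assert r[i, j] == pytest.approx((counts[i, j] - e) / denom)

    def test_null_residuals_standard_normal(self, uniform_corpus):
        r = context_residuals(count_pairs(uniform_corpus, 0))
        inside = np.mean(np.abs(r) < 2)
        assert inside > 0.93
        assert 0.9 < r.std() < 1.1

    def test_injected_pair_large_residual(self):
        records, _ = generate_corpus(
            GeneratorSpec(n_genes=400, seed=5, pair_coupling={("TCG", "TCG"): 8.0})
        )
        from codonbias.tables import SENSE_INDEX

        r = context_residuals(count_pairs(records, 0))
        i = SENSE_INDEX["TCG"]
        assert r[i, i] > 5


class TestContextTree:
    def test_identical_matrices_zero_heights(self):
        records = _corpus(12)
        profiles = build_profiles(
            {"a": records, "b": records, "c": records}, prefiltered=True
        )
        tree = species_context_tree(profiles)
        assert np.allclose(tree.linkage[:, 2], 0.0, atol=1e-9)

    def test_anticorrelated_merged_last(self):
        profiles = build_profiles(
            {"a": _corpus(13), "b": _corpus(14), "c": _corpus(15)},
            prefiltered=True,
        )
        profiles[2].residual_matrix = -profiles[0].residual_matrix
        tree = species_context_tree(profiles)
        # the last merge height reflects distance ~2 for anticorrelation
        assert tree.linkage[-1, 2] > 1.5

    def test_clade_recovery(self):
        # each clade shares its own neighbouring-pair coupling pattern
        pairs_a = [
            ("GAG", "GAG"), ("CTG", "CTG"), ("TCG", "TCG"), ("AGA", "GGA"),
            ("TCC", "AGA"), ("TCC", "ACC"), ("CTG", "GCC"), ("CAG", "CTG"),
            ("GCC", "ATC"), ("AAA", "AAA"),
        ]
        pairs_b = [
            ("GAA", "GAA"), ("CTT", "CTT"), ("TCA", "TCA"), ("CGT", "GGT"),
            ("AGT", "CGT"), ("ACT", "ACT"), ("CTA", "GCA"), ("CAA", "CTA"),
            ("GCT", "ATT"), ("AAG", "AAG"),
        ]
        corpora = {}
        for i in range(2):
            corpora[f"ctxA_{i}"], _ = generate_corpus(
                GeneratorSpec(
                    n_genes=300, seed=300 + i,
                    pair_coupling={p: 5.0 for p in pairs_a},
                )
            )
            corpora[f"ctxB_{i}"], _ = generate_corpus(
                GeneratorSpec(
                    n_genes=300, seed=400 + i,
                    pair_coupling={p: 5.0 for p in pairs_b},
                )
            )
        tree = species_context_tree(build_profiles(corpora, prefiltered=True))
        assign = fcluster(tree.linkage, t=2, criterion="maxclust")
        groups = {}
        for label, cl in zip(tree.labels, assign):
            groups.setdefault(cl, set()).add(label.split("_")[0])
        assert set(map(frozenset, groups.values())) == {
            frozenset({"ctxA"}),
            frozenset({"ctxB"}),
        }


def test_newick_sanitizes_labels():
    z = np.array([[0.0, 1.0, 0.5, 2.0]])
    nwk = linkage_to_newick(z, ["Danio rerio", "Gadus morhua"])
    assert "Danio_rerio" in nwk and " " not in nwk
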