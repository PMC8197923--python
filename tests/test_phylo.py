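import itertools

import numpy as np
import pandas as pd
import pytest

from oracles import brute_global_alignment_score, random_additive_tree
from phenofish import phylo
from phenofish.synthdata import evolve_sequences


class TestPairwiseAlign:
    def test_identical_sequences(self):
        a, b, score = phylo.pairwise_align("ACGT", "ACGT")
        assert (a, b, score) == ("ACGT", "ACGT", 4.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            phylo.pairwise_align("A", "")

    def test_single_gap_case(self):
        _, _, score = phylo.pairwise_align("AC", "C")
        assert score == -1.0

    def test_matches_exhaustive_enumeration(self, rng):
        """Optimal score equals brute-force enumeration on short sequences."""
        bases = np.array(list("ACGT"))
        for _ in range(15):
            la, lb = rng.integers(1, 8, size=2)
            a = "".join(rng.choice(bases, la))
            b = "".join(rng.choice(bases, lb))
            _, _, score = phylo.pairwise_align(a, b)
            assert score == pytest.approx(
                brute_global_alignment_score(a, b), abs=1e-9)

    def test_aligned_pair_reproduces_score(self, rng):
        bases = np.array(list("ACGT"))
        a = "".join(rng.choice(bases, 30))
        b = "".join(rng.choice(bases, 28))
        aa, bb, score = phylo.pairwise_align(a, b)
        recomputed = sum(
            -2.0 if "-" in (x, y) else (1.0 if x == y else -1.0)
            for x, y in zip(aa, bb))
        assert recomputed == pytest.approx(score)


class TestJcDistance:
    def test_identical_sequences_zero(self):
        assert phylo.jc_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_at_p_ten_percent(self):
        a = "A" * 100
        b = "A" * 90 + "C" * 10
        assert phylo.jc_distance(a, b) == pytest.approx(0.10733, abs=1e-5)

    def test_gap_and_n_sites_excluded(self):
        d = phylo.jc_distance("AC-GN", "ACCGT")
        assert d == 0.0   # only A, C, G compared

    def test_saturation_flagged(self):
        with pytest.raises(ValueError, match="saturated"):
            phylo.jc_distance("AAAA", "CCCC")

    def test_jc_at_least_p_distance(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(20):
            a = "".join(rng.choice(bases, 200))
            b = "".join(rng.choice(bases, 200))
            p, _ = phylo.p_distance(a, b)
            if p >= 0.75:
                continue
            assert phylo.jc_distance(a, b) >= p - 1e-12

    def test_estimator_consistency_on_simulated_divergence(self):
        """JC distance estimated from sequences evolved at t = 0.1 along a
        two-taxon tree converges to 0.1 (100 kb, 3 SEs)."""
        seqs = evolve_sequences("(A:0.05,B:0.05);", 100_000, seed=77)
        d = phylo.jc_distance(seqs["A"], seqs["B"])
        p, n = phylo.p_distance(seqs["A"], seqs["B"])
        # delta-method SE of the JC estimator
        se = np.sqrt(p * (1 - p) / n) / (1 - 4 * p / 3)
        assert abs(d - 0.1) < 3 * se


class TestNeighborJoining:
    ADDITIVE = pd.DataFrame(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
        index=list("ABCD"), columns=list("ABCD"), dtype=float)

    def test_additive_four_taxon_exact(self):
        """Recovers AB|CD with branch lengths (1, 2, 1, 3, 4) exactly."""
        tree = phylo.neighbor_joining(self.ADDITIVE)
        assert phylo.bipartitions(tree) == {frozenset({"A", "B"})}
        lengths = {t.name: t.length for t in tree.tips()}
        internal = [n.length for n in tree.non_tips(include_self=False)]
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0,
                                         "D": 4.0})
        assert internal == pytest.approx([1.0])

    def test_three_taxa_closed_form(self):
        D = pd.DataFrame([[0, 3, 4], [3, 0, 5], [4, 5, 0]],
                         index=list("ABC"), columns=list("ABC"), dtype=float)
        tree = phylo.neighbor_joining(D)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            phylo.neighbor_joining(self.ADDITIVE.iloc[:2, :2])

    @pytest.mark.parametrize("n", [4, 5, 6, 8])
    def test_random_additive_matrices_recover_topology(self, n, rng):
        """RF distance to the generating random tree is zero and the path
        distances are reproduced."""
        nwk, dists = random_additive_tree(n, rng)
        ids = sorted({x for fs in dists for x in fs})
        D = pd.DataFrame(0.0, index=ids, columns=ids)
        for fs, d in dists.items():
            a, b = sorted(fs)
            D.loc[a, b] = D.loc[b, a] = d
        tree = phylo.neighbor_joining(D)
        true = phylo.read_newick(nwk)
        assert phylo.robinson_foulds(tree, true)["robinson_foulds"] == 0
        tt = tree.tip_tip_distances(endpoints=ids)
        for fs, d in dists.items():
            a, b = sorted(fs)
            assert tt[ids.index(a), ids.index(b)] == pytest.approx(d, abs=1e-9)

    def test_taxon_order_invariance(self, rng):
        nwk, dists = random_additive_tree(6, rng)
        ids = sorted({x for fs in dists for x in fs})
        D = pd.DataFrame(0.0, index=ids, columns=ids)
        for fs, d in dists.items():
            a, b = sorted(fs)
            D.loc[a, b] = D.loc[b, a] = d
        t1 = phylo.neighbor_joining(D)
        perm = list(rng.permutation(ids))
        t2 = phylo.neighbor_joining(D.loc[perm, perm])
        assert phylo.bipartitions(t1) == phylo.bipartitions(t2)


class TestConcordance:
    def test_identical_trees(self):
        t = "((A:1,B:2):1,(C:1,D:1):2);"
        out = phylo.tree_concordance(phylo.read_newick(t),
                                     phylo.read_newick(t))
        assert out["robinson_foulds"] == 0
        assert out["cophenetic_correlation"] == pytest.approx(1.0)

    def test_conflicting_quartets(self):
        t1 = phylo.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = phylo.read_newick("((A:1,C:1):1,(B:1,D:1):1);")
        out = phylo.robinson_foulds(t1, t2)
        assert out["robinson_foulds"] == 2
        assert out["normalized_rf"] == pytest.approx(1.0)

    def test_leaf_set_mismatch_reported(self):
        t1 = phylo.read_newick("((A:1,B:1):1,C:1);")
        t2 = phylo.read_newick("((A:1,B:1):1,D:1);")
        with pytest.raises(ValueError, match="leaf sets differ"):
            phylo.robinson_foulds(t1, t2)

    def test_rf_matches_dendropy(self, rng):
        """RF equals an independent bipartition computation (dendropy) on
        random tree pairs."""
        import dendropy

        for trial in range(8):
            n = int(rng.integers(4, 9))
            nwk1, _ = random_additive_tree(n, rng)
            nwk2, _ = random_additive_tree(n, rng)
            ours = phylo.robinson_foulds(phylo.read_newick(nwk1),
                                         phylo.read_newick(nwk2))
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=nwk1, schema="newick",
                                   taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=nwk2, schema="newick",
                                   taxon_namespace=tns)
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            ref = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert ours["robinson_foulds"] == ref


class TestNewickRoundTrip:
    def test_topology_lengths_supports_preserved(self):
        nwk = "((A:0.1,B:0.2)95:0.05,(C:0.3,D:0.4)80:0.06,E:0.5);"
        tree = phylo.read_newick(nwk)
        back = phylo.read_newick(phylo.write_newick(tree))
        assert phylo.bipartitions(tree) == phylo.bipartitions(back)
        ids = sorted(t.name for t in tree.tips())
        d1 = tree.tip_tip_distances(endpoints=ids)
        d2 = back.tip_tip_distances(endpoints=ids)
        np.testing.assert_allclose(d1.data, d2.data, atol=1e-9)
        sup1 = sorted(n.name for n in tree.non_tips() if n.name)
        sup2 = sorted(n.name for n in back.non_tips() if n.name)
        assert sup1 == sup2


class TestBootstrap:
    def test_clean_split_fully_supported(self):
        seqs = evolve_sequences("((A:0.02,B:0.02):0.2,(C:0.02,D:0.02):0.2);",
                                5000, seed=5)
        out = phylo.bootstrap_support(seqs, n_replicates=100, seed=9)
        assert out["support"][frozenset({"A", "B"})] == pytest.approx(100.0)

    def test_identical_sequences_uninformative(self):
        seqs = {k: "ACGT" * 100 for k in "ABCDE"}
        out = phylo.bootstrap_support(seqs, n_replicates=50, seed=1)
        # distances all zero: whatever topology appears carries no signal,
        # and the full-data tree has height zero
        tree = out["tree"]
        assert all((t.length or 0.0) == pytest.approx(0.0)
                   for t in tree.traverse())

    def test_fixed_seed_reproducible(self):
        seqs = evolve_sequences("((A:0.05,B:0.05):0.1,(C:0.05,D:0.05):0.1);",
                                2000, seed=3)
        a = phylo.bootstrap_support(seqs, n_replicates=60, seed=42)
        b = phylo.bootstrap_support(seqs, n_replicates=60, seed=42)
        assert a["support"] == b["support"]

    def test_short_alignment_rejected(self):
        with pytest.raises(ValueError):
            phylo.bootstrap_support({"A": "ACG", "B": "ACG", "C": "ACG"},
                                    n_replicates=10, seed=0)


def test_reference_msa_passthrough_and_projection():
    seqs = {"A": "ACGTACGT", "B": "ACGTACGT"}
    assert phylo.reference_msa(seqs) == seqs
    seqs2 = {"A": "ACGTACGTAA", "B": "ACGACGTAA"}   # B lost one T
    msa = phylo.reference_msa(seqs2)
    assert len(msa["A"]) == len(msa["B"])
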