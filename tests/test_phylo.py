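"""Distances, NJ, GTR+Gamma likelihood (with exhaustive oracle), bootstrap."""

import itertools
import math

import dendropy
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from acaryopan.phylo import (AlignmentMatrix, SaturatedDistanceError,
                             SubstModel, concatenate, neighbor_joining,
                             optimize_branch_lengths, pairwise_distance,
                             read_alignment_fasta, read_alignment_phylip,
                             read_distance_tsv, select_single_copy,
                             site_loglik, write_alignment_fasta,
                             write_alignment_phylip, write_distance_tsv,
                             bootstrap_support, nj_builder, _bipartitions)


def exhaustive_loglik(tree, aln, model):
    """Total lnL by summing over every internal-state assignment.

    Independent of the pruning code: enumerates all 4^n_internal labelings
    per site and per rate category.
    """
    taxa_idx = {t: i for i, t in enumerate(aln.taxa)}
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    pi = np.asarray(model.freqs)
    rates, weights = model.category_rates()
    edges = [(n, n.parent_node) for n in tree.preorder_node_iter()
             if n.parent_node is not None]
    total = 0.0
    for site in range(aln.n_sites):
        like = 0.0
        for rate, wgt in zip(rates, weights):
            P = {n: model.transition_matrix(n.edge.length or 0.0, rate)
                 for n, _ in edges}
            site_like = 0.0
            for states in itertools.product(range(4), repeat=len(internals)):
                s_of = dict(zip(internals, states))
                prob = pi[s_of[tree.seed_node]]
                for child, parent in edges:
                    if child.is_leaf():
                        code = aln.data[taxa_idx[child.taxon.label], site]
                        if code < 4:
                            prob *= P[child][s_of[parent], code]
                        else:
                            prob *= 1.0  # missing data sums over the child
                    else:
                        prob *= P[child][s_of[parent], s_of[child]]
                site_like += prob
            like += wgt * site_like
        total += math.log(like)
    return total


def _random_tree_and_alignment(rng, n_tips, n_sites, model, alpha_len=0.3):
    from acaryopan.synthetic import simulate_alignment, simulate_species_tree
    tree = simulate_species_tree(n_tips, int(rng.integers(0, 10 ** 6)))
    for e in tree.preorder_edge_iter():
        if e.head_node is not tree.seed_node:
            e.length = float(rng.uniform(0.02, alpha_len))
    aln = simulate_alignment(tree, n_sites, model,
                             int(rng.integers(0, 10 ** 6)))
    return tree, aln


class TestDistances:
    def test_p_distance_hand_case(self):
        aln = AlignmentMatrix.from_dict({"a": "AAAA", "b": "AAAT"})
        d = pairwise_distance(aln, "p")
        assert d[0, 1] == pytest.approx(0.25)

    def test_jc_correction_formula(self):
        aln = AlignmentMatrix.from_dict({"a": "AAAACCCC", "b": "AAAACCGG"})
        p = 0.25
        d = pairwise_distance(aln, "JC")
        assert d[0, 1] == pytest.approx(-0.75 * math.log(1 - 4 * p / 3))

    def test_gap_columns_excluded_per_pair(self):
        aln = AlignmentMatrix.from_dict({"a": "A-AA", "b": "ATAT",
                                         "c": "ATAT"})
        d = pairwise_distance(aln, "p")
        assert d[0, 1] == pytest.approx(1.0 / 3.0)
        assert d[1, 2] == 0.0

    def test_saturation_raises(self):
        aln = AlignmentMatrix.from_dict({"a": "AAAA", "b": "TTTT"})
        with pytest.raises(SaturatedDistanceError):
            pairwise_distance(aln, "JC")

    def test_distance_tsv_roundtrip(self, tmp_path):
        d = np.array([[0.0, 0.1], [0.1, 0.0]])
        p = tmp_path / "d.tsv"
        write_distance_tsv(d, ["a", "b"], str(p))
        back, labels = read_distance_tsv(str(p))
        assert labels == ["a", "b"]
        assert np.allclose(back, d)


class TestNeighborJoining:
    def _tree_distances(self, tree, labels):
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        n = len(labels)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = pdm.patristic_distance(
                    taxa[labels[i]], taxa[labels[j]])
        return out

    def test_additive_matrix_recovered_exactly(self):
        # caterpillar ((a,b),(c,d),e) with known branch lengths
        newick = "((a:1,b:2):1.5,(c:0.5,d:1):2,e:3);"
        src = dendropy.Tree.get(data=newick, schema="newick")
        labels = ["a", "b", "c", "d", "e"]
        d = self._tree_distances(src, labels)
        tree = neighbor_joining(d, labels)
        back = self._tree_distances(tree, labels)
        assert np.allclose(back, d, atol=1e-9)

    def test_random_additive_matrices(self):
        rng = np.random.default_rng(61)
        from acaryopan.synthetic import simulate_species_tree
        for trial in range(10):
            src = simulate_species_tree(6, int(rng.integers(10 ** 6)))
            for e in src.preorder_edge_iter():
                if e.head_node is not src.seed_node:
                    e.length = float(rng.uniform(0.1, 2.0))
            labels = sorted(lf.taxon.label for lf in src.leaf_node_iter())
            d = self._tree_distances(src, labels)
            back = self._tree_distances(neighbor_joining(d, labels), labels)
            assert np.allclose(back, d, atol=1e-8), trial

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            neighbor_joining(np.array([[0.0, 1.0], [2.0, 0.0]]), ["a", "b"])


class TestLikelihood:
    def test_jc_two_taxon_closed_form(self):
        # lnL of k differing + m matching sites under JC at distance t
        t = 0.3
        match = 0.25 * (0.25 + 0.75 * math.exp(-4 * t / 3))
        diff = 0.25 * 0.25 * (1 - math.exp(-4 * t / 3))
        aln = AlignmentMatrix.from_dict({"a": "AAAC", "b": "AATC"})
        tree = dendropy.Tree.get(data=f"(a:{t / 2},b:{t / 2});",
                                 schema="newick")
        model = SubstModel()
        got = site_loglik(tree, aln, model).total
        want = 3 * math.log(match) + 1 * math.log(diff)
        assert got == pytest.approx(want, abs=1e-10)

    def test_pruning_equals_exhaustive_small_trees(self):
        rng = np.random.default_rng(62)
        model = SubstModel(exchangeabilities=(1.0, 2.5, 1.2, 0.8, 3.0, 1.0),
                           freqs=(0.3, 0.2, 0.2, 0.3), alpha=0.7, ncat=3)
        for trial in range(5):
            tree, aln = _random_tree_and_alignment(rng, 4, 6, model)
            got = site_loglik(tree, aln, model).total
            want = exhaustive_loglik(tree, aln, model)
            assert got == pytest.approx(want, abs=1e-8), trial

    def test_transition_matrix_properties(self):
        model = SubstModel(exchangeabilities=(1.0, 2.0, 0.5, 0.7, 2.2, 1.0),
                           freqs=(0.1, 0.4, 0.3, 0.2))
        pi = np.asarray(model.freqs)
        for t in (0.01, 0.2, 1.5):
            P = model.transition_matrix(t)
            assert np.allclose(P.sum(axis=1), 1.0)
            # detailed balance of the reversible chain
            assert np.allclose(pi[:, None] * P, (pi[:, None] * P).T)
        # expected rate 1: -sum pi_i Q_ii == 1
        Q = model.rate_matrix()
        assert -(pi * np.diag(Q)).sum() == pytest.approx(1.0)

    def test_gamma_rates_mean_one(self):
        model = SubstModel(alpha=0.5, ncat=4)
        rates, weights = model.category_rates()
        assert float((rates * weights).sum()) == pytest.approx(1.0)

    def test_invariant_sites_scaling(self):
        model = SubstModel(alpha=1.0, p_inv=0.2)
        rates, weights = model.category_rates()
        assert float((rates * weights).sum()) == pytest.approx(1.0 / 0.8)

    def test_optimize_increases_loglik(self):
        rng = np.random.default_rng(63)
        model = SubstModel()
        tree, aln = _random_tree_and_alignment(rng, 5, 200, model)
        before = site_loglik(tree, aln, model).total
        after = optimize_branch_lengths(tree, aln, model, max_sweeps=2)
        assert after >= before - 1e-9


class TestBootstrapAndUtils:
    def test_select_single_copy(self):
        import pandas as pd
        counts = pd.DataFrame([[1, 1], [1, 2], [0, 1]],
                              index=["g1", "g2", "g3"], columns=["a", "b"])
        assert select_single_copy(counts) == ["g1"]

    def test_concatenate_reorders_taxa(self):
        a = AlignmentMatrix.from_dict({"x": "AC", "y": "GT"})
        b = AlignmentMatrix.from_dict({"y": "TT", "x": "AA"})
        cat = concatenate([a, b])
        d = cat.to_dict()
        assert d["x"] == "ACAA" and d["y"] == "GTTT"

    def test_bootstrap_support_resolves_clear_split(self):
        rng = np.random.default_rng(64)
        model = SubstModel()
        tree = dendropy.Tree.get(
            data="((a:0.05,b:0.05):0.3,(c:0.05,d:0.05):0.3);",
            schema="newick")
        from acaryopan.synthetic import simulate_alignment
        aln = simulate_alignment(tree, 600, model, 9)
        support = bootstrap_support(aln, nj_builder("JC"), B=50, seed=1)
        split = frozenset({"a", "b"})
        assert support.get(split, 0.0) >= 90.0

    def test_bipartitions_of_quartet(self):
        tree = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        bps = _bipartitions(tree, ["a", "b", "c", "d"])
        assert frozenset({"a", "b"}) in bps or frozenset({"c", "d"}) in bps


class TestAlignmentIO:
    def test_fasta_roundtrip(self, tmp_path):
        aln = AlignmentMatrix.from_dict({"a": "ACGT-N", "b": "TTAACC"})
        p = tmp_path / "a.fasta"
        write_alignment_fasta(aln, str(p))
        back = read_alignment_fasta(str(p))
        assert back.taxa == aln.taxa
        assert np.array_equal(back.data, aln.data)

    def test_phylip_roundtrip(self, tmp_path):
        aln = AlignmentMatrix.from_dict({"taxon_one": "ACGTAC",
                                         "t2": "GGTTAA"})
        p = tmp_path / "a.phy"
        write_alignment_phylip(aln, str(p))
        back = read_alignment_phylip(str(p))
        assert back.taxa == aln.taxa
        assert np.array_equal(back.data, aln.data)

    def test_phylip_header_mismatch(self, tmp_path):
        p = tmp_path / "bad.phy"
        p.write_text("2 4\na AC\n")
        with pytest.raises(ValueError):
            read_alignment_phylip(str(p))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            AlignmentMatrix.from_dict({"a": "ACG", "b": "AC"})

    @given(st.lists(st.sampled_from("ACGT-N"), min_size=1, max_size=30))
    def test_code_roundtrip(self, chars):
        seq = "".join(chars)
        aln = AlignmentMatrix.from_dict({"x": seq})
        # '-'/'N' both map to missing; ACGT round-trip exactly
        back = aln.to_dict()["x"]
        for orig, rt in zip(seq, back):
            if orig in "ACGT":
                assert rt == orig
            else:
                assert rt == "-"
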