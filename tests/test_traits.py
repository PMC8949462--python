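"""Fitch and Dollo parsimony against exhaustive oracles; trait covariation."""

import itertools

import dendropy
import numpy as np
import pytest

from acaryopan.traits import (covariation, dollo_reconstruction,
                              fitch_parsimony, read_trait_matrix,
                              trait_column)


def exhaustive_min_changes(tree, states, max_gains=None):
    """Minimum #changes over all internal labelings by brute force.

    Unknown tips are free (either state, no cost).  ``max_gains`` restricts
    the number of trait origins (0->1 branches, plus one if the root itself
    is in state 1) -- the Dollo oracle when 1.
    """
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    leaves = list(tree.leaf_node_iter())
    unknown = [lf for lf in leaves if states.get(lf.taxon.label) is None]
    best = None
    for istates in itertools.product((0, 1), repeat=len(internals)):
        lab = dict(zip(internals, istates))
        for ustates in itertools.product((0, 1), repeat=len(unknown)):
            full = dict(lab)
            for lf in leaves:
                v = states.get(lf.taxon.label)
                full[lf] = ustates[unknown.index(lf)] if v is None else v
            changes = 0
            gains = full[tree.seed_node]
            ok = True
            for node in tree.preorder_node_iter():
                p = node.parent_node
                if p is None:
                    continue
                if full[p] != full[node]:
                    changes += 1
                    if full[node] == 1:
                        gains += 1
            if max_gains is not None and gains > max_gains:
                ok = False
            if ok and (best is None or changes < best):
                best = changes
    return best


def _random_tree(rng, n_tips):
    from acaryopan.synthetic import simulate_species_tree
    return simulate_species_tree(n_tips, int(rng.integers(10 ** 6)))


class TestFitch:
    def test_hand_case_single_gain(self):
        tree = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        rec = fitch_parsimony(tree, {"a": 1, "b": 1, "c": 0, "d": 0})
        assert rec.n_changes == 1
        assert rec.events == [("a|b", "gain")] or rec.events == \
            [("c|d", "loss")]

    def test_matches_exhaustive_on_random_cases(self):
        rng = np.random.default_rng(81)
        for trial in range(100):
            n = int(rng.integers(3, 9))
            tree = _random_tree(rng, n)
            labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
            states = {}
            for lbl in labels:
                r = rng.random()
                states[lbl] = None if r < 0.15 else int(r < 0.55)
            if all(v is None for v in states.values()):
                states[labels[0]] = 1
            rec = fitch_parsimony(tree, states)
            want = exhaustive_min_changes(tree, states)
            assert rec.n_changes == want, (trial, states)
            # the emitted event list realizes exactly that many changes
            assert len(rec.events) == want

    def test_matches_exhaustive_on_multifurcating_trees(self):
        # e.g. the trifurcating root of a neighbor-joining tree
        rng = np.random.default_rng(84)
        newicks = ["(a,b,c,d);", "((a,b),c,(d,e));", "((a,b,c),(d,e,f));",
                   "(a,(b,c,d),e);"]
        for nwk in newicks:
            tree = dendropy.Tree.get(data=nwk, schema="newick")
            labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
            for _ in range(20):
                states = {l: int(rng.random() < 0.5) for l in labels}
                states[labels[0]] = 1
                rec = fitch_parsimony(tree, states)
                want = exhaustive_min_changes(tree, states)
                assert rec.n_changes == want, (nwk, states)
                assert len(rec.events) == want

    def test_labelling_consistent_with_events(self):
        rng = np.random.default_rng(82)
        tree = _random_tree(rng, 7)
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        states = {l: int(i % 2 == 0) for i, l in enumerate(labels)}
        rec = fitch_parsimony(tree, states)
        # every known tip keeps its observed state in the final labelling
        for l, v in states.items():
            assert rec.ancestral_states[l] == v

    def test_all_unknown_raises(self):
        tree = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        with pytest.raises(ValueError):
            fitch_parsimony(tree, {"a": None, "b": None, "c": None,
                                   "d": None})

    def test_nonbinary_state_raises(self):
        tree = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        with pytest.raises(ValueError):
            fitch_parsimony(tree, {"a": 2, "b": 0, "c": 0, "d": 0})


class TestDollo:
    def test_single_gain_two_losses(self):
        tree = dendropy.Tree.get(data="(((a,b),(c,d)),(e,f));",
                                 schema="newick")
        states = {"a": 1, "b": 0, "c": 1, "d": 0, "e": 0, "f": 0}
        rec = dollo_reconstruction(tree, states, root_state="absent")
        assert rec.extra["gains"] == 1
        assert rec.extra["losses"] == 2
        assert rec.n_changes == 3
        gain_nodes = [k for k, kind in rec.events if kind == "gain"]
        assert gain_nodes == ["a|b|c|d"]

    def test_matches_exhaustive_one_gain_bound(self):
        rng = np.random.default_rng(83)
        for trial in range(60):
            n = int(rng.integers(3, 8))
            tree = _random_tree(rng, n)
            labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
            states = {l: int(rng.random() < 0.5) for l in labels}
            if not any(states.values()):
                states[labels[0]] = 1
            rec = dollo_reconstruction(tree, states, root_state="infer")
            want = exhaustive_min_changes(tree, states, max_gains=1)
            assert rec.n_changes == want, (trial, states)

    def test_root_present_forces_zero_gains(self):
        tree = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        rec = dollo_reconstruction(tree, {"a": 0, "b": 0, "c": 0, "d": 0},
                                   root_state="present")
        assert rec.extra["gains"] == 0
        assert rec.extra["losses"] >= 1

    def test_absent_everywhere_zero_events(self):
        tree = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        rec = dollo_reconstruction(tree, {"a": 0, "b": 0, "c": 0, "d": 0})
        assert rec.n_changes == 0 and rec.events == []

    def test_reports_fitch_comparison(self):
        tree = dendropy.Tree.get(data="(((a,b),(c,d)),(e,f));",
                                 schema="newick")
        states = {"a": 1, "b": 0, "c": 1, "d": 0, "e": 1, "f": 0}
        rec = dollo_reconstruction(tree, states)
        fitch = fitch_parsimony(tree, states)
        assert rec.extra["fitch_changes"] == fitch.n_changes
        assert rec.n_changes >= fitch.n_changes

    def test_unknown_tips_do_not_cost_losses(self):
        tree = dendropy.Tree.get(data="(((a,b),c),d);", schema="newick")
        states = {"a": 1, "b": None, "c": 1, "d": 0}
        rec = dollo_reconstruction(tree, states, root_state="absent")
        # b unknown: riding along with presence costs nothing
        assert rec.extra["losses"] == 0
        assert rec.n_changes == 1

    def test_bad_root_state(self):
        tree = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        with pytest.raises(ValueError):
            dollo_reconstruction(tree, {"a": 1, "b": 0, "c": 0, "d": 0},
                                 root_state="maybe")


class TestCovariation:
    def test_complete_covariation(self):
        a = {"s1": 1, "s2": 0, "s3": 1}
        assert covariation(a, dict(a)) == {
            "agreement": 1.0, "discordant": [], "complete": True,
            "n_compared": 3}

    def test_discordant_listed(self):
        a = {"s1": 1, "s2": 0, "s3": 1}
        b = {"s1": 1, "s2": 1, "s3": 1}
        out = covariation(a, b)
        assert out["discordant"] == ["s2"]
        assert out["agreement"] == pytest.approx(2 / 3)

    def test_unknowns_excluded(self):
        a = {"s1": 1, "s2": None}
        b = {"s1": 1, "s2": 0}
        assert covariation(a, b)["n_compared"] == 1

    def test_strain_set_mismatch(self):
        with pytest.raises(ValueError):
            covariation({"s1": 1}, {"s2": 1})

    def test_no_overlap_raises(self):
        with pytest.raises(ValueError):
            covariation({"s1": None}, {"s1": 0})


class TestTraitIO:
    def test_matrix_roundtrip(self, tmp_path):
        p = tmp_path / "traits.tsv"
        p.write_text("strain\tplasmid_block\thgt_cassette\n"
                     "S1\t1\t0\nS2\t0\t\nS3\t1\t1\n")
        df = read_trait_matrix(str(p))
        col = trait_column(df, "plasmid_block")
        assert col == {"S1": 1, "S2": 0, "S3": 1}
        col2 = trait_column(df, "hgt_cassette")
        assert col2 == {"S1": 0, "S2": None, "S3": 1}
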