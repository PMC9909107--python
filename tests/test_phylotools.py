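"""Neighbor joining, Robinson-Foulds and Fitch parsimony, with forward
simulation and brute-force oracles."""

import math
from itertools import product

import dendropy
import numpy as np
import pytest

from gadpopgen.phylotools import (
    clade_concordance,
    fitch_parsimony,
    is_monophyletic,
    jc_distance_matrix,
    neighbor_joining,
    nj_tree_from_alignment,
    robinson_foulds,
)
from gadpopgen.seqio import SequenceRecord

from conftest import random_coding_alignment


def random_tree_and_distances(rng, n):
    """Forward-simulate a random binary tree with exponential branch
    lengths; return (tree, additive leaf distance matrix, labels)."""
    labels = [f"t{i}" for i in range(n)]
    tns = dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        nd = dendropy.Node()
        nd.taxon = tns.get_taxon(lab)
        nodes.append(nd)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = dendropy.Node()
        for k in (i, j):
            nodes[k].edge.length = float(rng.exponential(0.4)) + 0.05
            parent.add_child(nodes[k])
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    root = dendropy.Node()
    nodes[0].edge.length = float(rng.exponential(0.4)) + 0.05
    nodes[1].edge.length = float(rng.exponential(0.4)) + 0.05
    root.add_child(nodes[0])
    root.add_child(nodes[1])
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    pdm = tree.phylogenetic_distance_matrix()
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                D[i, j] = pdm.distance(
                    tns.get_taxon(labels[i]), tns.get_taxon(labels[j])
                )
    return tree, D, labels


class TestJCDistance:
    def test_identical_sequences_zero(self):
        recs = [SequenceRecord("a", "ACGTACGT", "nt"),
                SequenceRecord("b", "ACGTACGT", "nt")]
        D, _ = jc_distance_matrix(recs)
        assert D[0, 1] == 0.0

    def test_closed_form_at_p_005(self):
        seq = "A" * 100
        other = "C" * 5 + "A" * 95
        recs = [SequenceRecord("a", seq, "nt"), SequenceRecord("b", other, "nt")]
        D, _ = jc_distance_matrix(recs)
        assert D[0, 1] == pytest.approx(-0.75 * math.log(1 - 0.2 / 3))

    def test_symmetric_zero_diagonal(self, rng):
        aln = random_coding_alignment(rng, n=5, n_codons=40)
        D, _ = jc_distance_matrix(list(aln.records))
        assert np.allclose(D, D.T)
        assert np.all(np.diag(D) == 0)

    def test_saturation_rejected(self):
        recs = [SequenceRecord("a", "AAAA", "nt"),
                SequenceRecord("b", "CCCC", "nt")]
        with pytest.raises(ValueError, match="3/4"):
            jc_distance_matrix(recs)


class TestNeighborJoining:
    def test_three_taxa_branch_lengths(self):
        D = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = neighbor_joining(D, ["a", "b", "c"])
        pdm = tree.phylogenetic_distance_matrix()
        tns = tree.taxon_namespace
        get = lambda x, y: pdm.distance(
            tns.get_taxon(x), tns.get_taxon(y)
        )
        assert get("a", "b") == pytest.approx(0.3)
        assert get("a", "c") == pytest.approx(0.5)
        assert get("b", "c") == pytest.approx(0.6)

    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_exact_recovery_on_additive_matrices(self, n, rng):
        for _ in range(12):
            true_tree, D, labels = random_tree_and_distances(rng, n)
            est = neighbor_joining(D, labels)
            assert robinson_foulds(true_tree, est) == 0
            # branch lengths: leaf-to-leaf path distances reproduced
            pdm = est.phylogenetic_distance_matrix()
            tns = est.taxon_namespace
            for i in range(n):
                for j in range(i + 1, n):
                    got = pdm.distance(
                        tns.get_taxon(labels[i]), tns.get_taxon(labels[j])
                    )
                    assert got == pytest.approx(D[i, j], abs=1e-9)

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1.0, 2], [1.1, 0, 1], [2, 1, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(D, list("abc"))

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="3 taxa"):
            neighbor_joining(np.zeros((2, 2)), ["a", "b"])


class TestRobinsonFoulds:
    def test_identical_trees_zero(self, rng):
        tree, D, labels = random_tree_and_distances(rng, 8)
        assert robinson_foulds(tree, tree) == 0

    def test_two_quartet_topologies(self):
        t1 = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        t2 = dendropy.Tree.get(data="((a,c),(b,d));", schema="newick")
        assert robinson_foulds(t1, t2) == 2

    def test_bounded_by_2n_minus_6(self, rng):
        for n in (5, 8, 10):
            t1, _, _ = random_tree_and_distances(rng, n)
            t2, _, _ = random_tree_and_distances(rng, n)
            assert 0 <= robinson_foulds(t1, t2) <= 2 * (n - 3)

    def test_metric_axioms_spot_check(self, rng):
        trees = [random_tree_and_distances(rng, 7)[0] for _ in range(4)]
        for a in trees:
            assert robinson_foulds(a, a) == 0
        for a in trees:
            for b in trees:
                assert robinson_foulds(a, b) == robinson_foulds(b, a)
        for a in trees:
            for b in trees:
                for c in trees:
                    assert robinson_foulds(a, c) <= (
                        robinson_foulds(a, b) + robinson_foulds(b, c)
                    )

    def test_leaf_set_mismatch_rejected(self):
        t1 = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        t2 = dendropy.Tree.get(data="((a,b),(c,e));", schema="newick")
        with pytest.raises(ValueError, match="leaf"):
            robinson_foulds(t1, t2)


def brute_force_parsimony(tree, states):
    """Minimum changes over all internal-node state assignments."""
    internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    leaves = [nd for nd in tree.leaf_node_iter()]
    alphabet = sorted(set(states.values()))
    best = math.inf
    for combo in product(alphabet, repeat=len(internal)):
        assign = dict(zip((id(nd) for nd in internal), combo))
        for lf in leaves:
            assign[id(lf)] = states[lf.taxon.label]
        changes = 0
        for nd in tree.preorder_node_iter():
            for child in nd.child_nodes():
                changes += assign[id(nd)] != assign[id(child)]
        best = min(best, changes)
    return best


class TestFitchAndConcordance:
    def test_matches_brute_force_small_trees(self, rng):
        for n in (5, 6, 7, 8):
            tree, _, labels = random_tree_and_distances(rng, n)
            states = {lab: ["x", "y", "z"][rng.integers(0, 3)] for lab in labels}
            assert fitch_parsimony(tree, states) == brute_force_parsimony(
                tree, states
            )

    def test_alternating_caterpillar(self):
        newick = "(a,(b,(c,(d,(e,f)))));"
        tree = dendropy.Tree.get(data=newick, schema="newick")
        states = dict(zip("abcdef", "010101"))
        assert fitch_parsimony(tree, states) == brute_force_parsimony(
            tree, states
        )

    def test_single_clade_monophyletic_one_origin(self):
        tree = dendropy.Tree.get(
            data="((a,b),((c,d),(e,f)));", schema="newick"
        )
        grouping = {"a": "g1", "b": "g1", "c": "g2", "d": "g2",
                    "e": "g2", "f": "g2"}
        report = clade_concordance(tree, grouping)
        assert report["groups"]["g1"]["monophyletic"]
        assert report["groups"]["g2"]["monophyletic"]
        assert report["fitch_changes"] == 1
        assert not report["multiple_gain_loss"]

    def test_repeated_gain_loss_detected(self):
        tree = dendropy.Tree.get(
            data="((a,b),((c,d),(e,f)));", schema="newick"
        )
        grouping = {"a": "op", "b": "no", "c": "op", "d": "no",
                    "e": "op", "f": "no"}
        report = clade_concordance(tree, grouping)
        assert report["multiple_gain_loss"]

    def test_single_group_trivially_monophyletic(self):
        tree = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        report = clade_concordance(
            tree, {l: "only" for l in "abcd"}
        )
        assert report["groups"]["only"]["monophyletic"]
        assert report["fitch_changes"] == 0

    def test_unassigned_leaf_rejected(self):
        tree = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        with pytest.raises(ValueError, match="without group"):
            clade_concordance(tree, {"a": "g", "b": "g", "c": "g"})


class TestEndToEnd:
    def test_nj_from_alignment_runs(self, rng):
        aln = random_coding_alignment(rng, n=6, n_codons=60, mutation_rate=0.05)
        tree = nj_tree_from_alignment(list(aln.records))
        assert len(tree.leaf_nodes()) == 6
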