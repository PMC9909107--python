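"""Distance trees and topology comparison.

Jukes–Cantor distances, canonical Saitou–Nei neighbor joining (with a
deterministic lowest-index tie rule), Robinson–Foulds distances, and a
clade-concordance report (monophyly + Fitch parsimony count of a
grouping character).  Trees are dendropy objects throughout, so Newick
I/O and rerooting come for free.
"""

from __future__ import annotations

import math
from pathlib import Path

import dendropy
import numpy as np

from .seqio import SequenceRecord


def jc_distance_matrix(
    records: list[SequenceRecord],
) -> tuple[np.ndarray, list[str]]:
    """Pairwise Jukes–Cantor distances over jointly ungapped sites."""
    labels = [r.id for r in records]
    n = len(records)
    D = np.zeros((n, n))
    for i in range(n):
        si = records[i].seq
        for j in range(i + 1, n):
            sj = records[j].seq
            total = diff = 0
            for a, b in zip(si, sj):
                if a in "N-" or b in "N-":
                    continue
                total += 1
                diff += a != b
            if total == 0:
                raise ValueError(
                    f"no jointly ungapped overlap between {labels[i]!r} and "
                    f"{labels[j]!r}"
                )
            p = diff / total
            if p >= 0.75:
                raise ValueError(
                    f"Jukes-Cantor undefined: mismatch proportion {p:.3f} >= 3/4 "
                    f"between {labels[i]!r} and {labels[j]!r}"
                )
            D[i, j] = D[j, i] = -0.75 * math.log1p(-4.0 * p / 3.0)
    return D, labels


def neighbor_joining(D: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Saitou–Nei neighbor joining; exact on additive matrices.

    Q-matrix ties are broken by joining the lowest-index pair, so the
    output is deterministic.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if len(labels) != n:
        raise ValueError("labels/matrix size mismatch")

    taxa = dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(lab)
        nodes.append(node)
    active = list(range(n))
    D = D.copy()

    while len(active) > 2:
        m = len(active)
        totals = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        best_q = math.inf
        for ai in range(m):
            for bi in range(ai + 1, m):
                i, j = active[ai], active[bi]
                q = (m - 2) * D[i, j] - totals[i] - totals[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best
        d_ij = D[i, j]
        vi = 0.5 * d_ij + (totals[i] - totals[j]) / (2.0 * (m - 2))
        vj = d_ij - vi
        parent = dendropy.Node()
        for child, edge in ((nodes[i], vi), (nodes[j], vj)):
            child.edge.length = max(edge, 0.0)
            parent.add_child(child)
        # distances from the new node
        new_row = np.zeros(D.shape[0] + 1)
        D = np.pad(D, ((0, 1), (0, 1)))
        new_idx = D.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            D[new_idx, k] = D[k, new_idx] = 0.5 * (D[i, k] + D[j, k] - d_ij)
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [new_idx]

    i, j = active
    root = dendropy.Node()
    nodes[i].edge.length = max(D[i, j], 0.0)
    nodes[j].edge.length = 0.0
    root.add_child(nodes[j])
    root.add_child(nodes[i])
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unrooted symmetric (Robinson–Foulds) bipartition distance."""
    if {t.label for t in t1.taxon_namespace} != {
        t.label for t in t2.taxon_namespace
    }:
        raise ValueError("trees have different leaf sets")
    tns = dendropy.TaxonNamespace(sorted(t.label for t in t1.taxon_namespace))
    a = dendropy.Tree.get(data=t1.as_string("newick"), schema="newick",
                          taxon_namespace=tns)
    b = dendropy.Tree.get(data=t2.as_string("newick"), schema="newick",
                          taxon_namespace=tns)
    a.is_rooted = b.is_rooted = False
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(a, b))


def fitch_parsimony(tree: dendropy.Tree, states: dict[str, str]) -> int:
    """Minimum number of state changes of a leaf character on the
    topology (Fitch; the tree is treated as rooted at its seed node)."""
    changes = 0

    def down(node):
        nonlocal changes
        if node.is_leaf():
            label = node.taxon.label
            if label not in states:
                raise ValueError(f"leaf {label!r} has no assigned state")
            return {states[label]}
        acc = None
        for child in node.child_nodes():
            s = down(child)
            if acc is None:
                acc = s
            elif acc & s:
                acc = acc & s
            else:
                changes += 1
                acc = acc | s
        return acc

    down(tree.seed_node)
    return changes


def is_monophyletic(tree: dendropy.Tree, leaves: set[str]) -> bool:
    """True iff the leaf set forms one side of an edge bipartition
    (unrooted monophyly)."""
    all_leaves = {t.taxon.label for t in tree.leaf_node_iter()}
    if leaves == all_leaves or len(leaves) == 1:
        return True
    for node in tree.preorder_node_iter():
        clade = {lf.taxon.label for lf in node.leaf_iter()}
        if clade == leaves or (all_leaves - clade) == leaves:
            return True
    return False


def clade_concordance(
    gene_tree: dendropy.Tree, grouping: dict[str, str]
) -> dict[str, dict]:
    """Per-group monophyly (on the unrooted topology) plus the Fitch
    parsimony count of the grouping character; a count above the number
    of groups minus one indicates repeated gain/loss."""
    leaves = {t.taxon.label for t in gene_tree.leaf_node_iter()}
    unassigned = leaves - set(grouping)
    if unassigned:
        raise ValueError(f"leaves without group assignment: {sorted(unassigned)}")
    report: dict[str, dict] = {}
    changes = fitch_parsimony(gene_tree, grouping)
    groups = sorted({grouping[l] for l in leaves})
    for g in groups:
        members = {l for l in leaves if grouping[l] == g}
        report[g] = {
            "n_leaves": len(members),
            "monophyletic": is_monophyletic(gene_tree, members),
        }
    return {
        "groups": report,
        "fitch_changes": changes,
        "min_possible_changes": len(groups) - 1,
        "multiple_gain_loss": changes > len(groups) - 1,
    }


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick")


def nj_tree_from_alignment(records: list[SequenceRecord]) -> dendropy.Tree:
    D, labels = jc_distance_matrix(records)
    return neighbor_joining(D, labels)
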