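"""Tree arithmetic for topology testing and clustering.

Trees are dendropy ``Tree`` objects throughout. This module adds the split
(bipartition) arithmetic the topology tests need: strict consensus with a
count of collapsed branches, counting the binary resolutions of a
multifurcating tree, building the constraint-topology set for alternative
placements of a focal clade, constraint compatibility checks, pruning of the
fastest-evolving taxa, and UPGMA.

Splits are canonical frozensets of leaf labels: the side of the bipartition
NOT containing the lexicographically smallest label, so a split compares
equal regardless of input rotation or rooting. Trivial splits (singleton or
full complement) are excluded everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform


class TreeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Newick I/O

def read_newick(text_or_path: str, *, from_file: bool = False) -> dendropy.Tree:
    """Parse a Newick string (or file) into a dendropy Tree."""
    src = {"path": text_or_path} if from_file else {"data": text_or_path}
    try:
        tree = dendropy.Tree.get(
            **src, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"Newick parse error: {exc}") from exc
    labels = leaf_labels(tree)
    if len(set(labels)) != len(labels):
        raise TreeError("duplicate leaf labels")
    if len(labels) < 2:
        raise TreeError("tree needs at least 2 leaves")
    return tree


def read_newick_list(path) -> list[dendropy.Tree]:
    with open(path) as fh:
        return [read_newick(line.strip()) for line in fh if line.strip()]


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# Split arithmetic

def _canonical(side: frozenset, all_leaves: frozenset) -> frozenset:
    ref = min(all_leaves)
    return frozenset(all_leaves - side) if ref in side else frozenset(side)


def splits(tree: dendropy.Tree, restrict_to: frozenset | None = None) -> set[frozenset]:
    """Non-trivial splits of the (implicitly unrooted) tree.

    If ``restrict_to`` is given, splits are first restricted to that leaf set.
    """
    all_leaves = frozenset(leaf_labels(tree))
    universe = all_leaves if restrict_to is None else frozenset(restrict_to) & all_leaves
    out: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = below & universe
        if 1 < len(side) < len(universe) - 1:
            out.add(_canonical(side, universe))
    return out


def tree_from_splits(split_set: set[frozenset], leaves: frozenset,
                     ) -> dendropy.Tree:
    """Build the (multifurcating) unrooted tree displaying exactly ``split_set``.

    The splits must be pairwise compatible; they are nested greedily from the
    largest side downward.
    """
    taxa = dendropy.TaxonNamespace(sorted(leaves))
    tree = dendropy.Tree(taxon_namespace=taxa)
    ref = min(leaves)
    # represent each split by the side not containing the reference leaf
    # build smallest clades first so nested splits find their members as
    # sibling nodes under a common parent
    sides = sorted((s if ref not in s else leaves - s for s in split_set),
                   key=lambda s: (len(s), sorted(s)))
    root = tree.seed_node
    holder: dict[str, dendropy.Node] = {}
    for lab in sorted(leaves):
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        root.add_child(node)
        holder[lab] = node
    for side in sides:
        members = {holder[lab] for lab in side}
        parents = {m.parent_node for m in members}
        if len(parents) != 1:
            raise TreeError("incompatible split set")
        parent = parents.pop()
        spanned = sum(1 if m.is_leaf() else len(m.leaf_nodes()) for m in members)
        if spanned != len(side):
            raise TreeError("incompatible split set")
        new = dendropy.Node()
        parent.add_child(new)
        for c in members:
            parent.remove_child(c)
            new.add_child(c)
        for lab in side:
            holder[lab] = new
    tree.is_rooted = False
    return tree


@dataclass
class ConsensusResult:
    tree: dendropy.Tree
    shared_splits: set[frozenset]
    collapsed_count: int


def strict_consensus(treeA: dendropy.Tree, treeB: dendropy.Tree) -> ConsensusResult:
    """Strict consensus of two trees plus the number of collapsed branches.

    The collapsed count is the number of internal branches the consensus
    lacks relative to a fully resolved unrooted tree: (n-3) minus the number
    of shared non-trivial splits. This is the degrees of freedom of the
    consensus polytomies, and is well defined even when an input is itself
    multifurcating.
    """
    la, lb = frozenset(leaf_labels(treeA)), frozenset(leaf_labels(treeB))
    if la != lb:
        raise TreeError(f"leaf sets differ: {sorted(la ^ lb)}")
    sa, sb = splits(treeA), splits(treeB)
    shared = sa & sb
    collapsed = (len(la) - 3) - len(shared)
    return ConsensusResult(tree_from_splits(shared, la), shared, collapsed)


def _double_factorial(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


def count_binary_resolutions(tree: dendropy.Tree) -> int:
    """Number of fully binary unrooted trees compatible with ``tree``.

    Product over internal vertices of degree d >= 4 of (2d-5)!!; 1 for a
    binary tree. The tree is treated as unrooted (a rooted bifurcation at the
    seed node counts as one vertex of degree 3).
    """
    total = 1
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        degree = len(node.child_nodes()) + (0 if node.parent_node is None else 1)
        if node.parent_node is None and degree == 2:
            continue  # rooted representation of an unrooted edge
        if degree >= 4:
            total *= _double_factorial(2 * degree - 5)
    return total


# ---------------------------------------------------------------------------
# Constraint topologies

PLACEMENTS = ("HC-sister", "H-sister", "C-sister")


def build_constraint_set(groups: dict[str, list[str]]) -> list[tuple[str, dendropy.Tree]]:
    """Construct the six constraint topologies for the focal-clade placements.

    ``groups`` must name five disjoint leaf sets: ``leptophytes``,
    ``haptophytes``, ``cryptophytes``, ``other_red_complex`` (the remaining
    red-complex plastid lineages) and ``red_algae``. For each of the three
    placements of leptophytes within the cryptophyte–haptophyte–leptophyte
    clade (sister to haptophytes+cryptophytes, to haptophytes, or to
    cryptophytes) two trees are built: one constraining all complex plastids
    (CHL + other red-complex) to be monophyletic, one leaving that free —
    six trees in total.

    Returns ``[(label, tree), ...]`` with labels like ``"H-sister+CPmono"``.
    """
    required = ["leptophytes", "haptophytes", "cryptophytes",
                "other_red_complex", "red_algae"]
    missing = [g for g in required if not groups.get(g)]
    if missing:
        raise TreeError(f"missing or empty groups: {missing}")
    sets = {g: list(dict.fromkeys(groups[g])) for g in required}
    flat = [x for g in required for x in sets[g]]
    if len(set(flat)) != len(flat):
        raise TreeError("groups overlap")

    def clade(labels: list[str]) -> str:
        return labels[0] if len(labels) == 1 else "(" + ",".join(labels) + ")"

    L, H, C = sets["leptophytes"], sets["haptophytes"], sets["cryptophytes"]
    O, R = sets["other_red_complex"], sets["red_algae"]
    inner = {
        "HC-sister": f"({clade(L)},({clade(H)},{clade(C)}))",
        "H-sister": f"(({clade(L)},{clade(H)}),{clade(C)})",
        "C-sister": f"(({clade(L)},{clade(C)}),{clade(H)})",
    }
    out = []
    for placement in PLACEMENTS:
        chl = inner[placement]
        for cp_mono in (True, False):
            if cp_mono:
                newick = f"({','.join(R)},({clade(O)},{chl}));"
            else:
                newick = f"({','.join(R)},{clade(O)},{chl});"
            label = placement + ("+CPmono" if cp_mono else "+CPfree")
            out.append((label, read_newick(newick)))
    return out


def is_compatible(tree: dendropy.Tree, constraint: dendropy.Tree) -> bool:
    """True iff every constraint split, restricted to shared leaves, is in the tree."""
    shared = frozenset(leaf_labels(constraint)) & frozenset(leaf_labels(tree))
    cons = splits(constraint, restrict_to=shared)
    have = splits(tree, restrict_to=shared)
    return cons <= have


# ---------------------------------------------------------------------------
# Fast-taxon removal and UPGMA

def root_to_tip_distances(tree: dendropy.Tree) -> dict[str, float]:
    dists = {}
    for lf in tree.leaf_node_iter():
        d, node = 0.0, lf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        dists[lf.taxon.label] = d
    return dists


def remove_fastest_taxa(tree: dendropy.Tree, n: int) -> tuple[dendropy.Tree, list[str]]:
    """Prune the n leaves with the largest root-to-tip path length.

    Ties broken by label order (lexicographically first removed first).
    """
    labels = leaf_labels(tree)
    if n >= len(labels):
        raise TreeError(f"cannot remove {n} of {len(labels)} leaves")
    if n == 0:
        return tree.clone(depth=1), []
    dists = root_to_tip_distances(tree)
    order = sorted(labels, key=lambda t: (-dists[t], t))
    drop = order[:n]
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels([t for t in labels if t not in drop])
    pruned.suppress_unifurcations()
    return pruned, drop


def upgma(distance_matrix: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Average-linkage agglomeration into a rooted ultrametric tree.

    Node heights are half the merge distance; sklearn/scipy's deterministic
    tie order is used.
    """
    D = np.asarray(distance_matrix, dtype=float)
    if D.shape != (len(labels), len(labels)):
        raise TreeError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T, atol=1e-12):
        raise TreeError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(D)) > 1e-12):
        raise TreeError("distance matrix diagonal must be zero")
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    if len(labels) == 1:
        tree.seed_node.taxon = taxa.get_taxon(labels[0])
        return tree
    Z = average(squareform(D, checks=False))
    nodes: dict[int, tuple[dendropy.Node, float]] = {}
    for i, lab in enumerate(labels):
        nodes[i] = (dendropy.Node(taxon=taxa.get_taxon(lab)), 0.0)
    nxt = len(labels)
    for a, b, dist, _ in Z:
        height = dist / 2.0
        parent = dendropy.Node()
        for child_id in (int(a), int(b)):
            child, child_h = nodes.pop(child_id)
            child.edge.length = height - child_h
            parent.add_child(child)
        nodes[nxt] = (parent, height)
        nxt += 1
    (root, _), = nodes.values()
    tree.seed_node = root
    tree.is_rooted = True
    return tree


def root_children_partition(tree: dendropy.Tree) -> tuple[list[str], list[str]]:
    """Split a rooted binary-rooted tree's leaves into the two root clades."""
    kids = tree.seed_node.child_nodes()
    if len(kids) != 2:
        raise TreeError("root is not bifurcating")
    g1 = [lf.taxon.label for lf in kids[0].leaf_iter()]
    g2 = [lf.taxon.label for lf in kids[1].leaf_iter()]
    return g1, g2
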