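import numpy as np
import pytest

from leptokit import align, phylolik, synthdata, treeops


@pytest.fixture(scope="session")
def lg_g4():
    return phylolik.load_model("LG", gamma_shape=0.8, n_cats=4)


@pytest.fixture(scope="session")
def poisson():
    return phylolik.load_model("POISSON")


@pytest.fixture(scope="session")
def six_taxon_tree():
    return treeops.read_newick(
        "((A:0.1,B:0.2):0.15,(C:0.12,D:0.25):0.08,(E:0.3,F:0.05):0.2);")


@pytest.fixture(scope="session")
def eight_taxon_tree():
    return treeops.read_newick(
        "(((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05):0.05,"
        "((E:0.1,F:0.1):0.05,(G:0.1,H:0.1):0.05):0.05);")


@pytest.fixture(scope="session")
def small_alignment(six_taxon_tree, lg_g4):
    aln, _ = synthdata.sim_alignment(six_taxon_tree, lg_g4, 400, seed=101)
    return aln


@pytest.fixture
def toy_alignment():
    return align.Alignment.from_sequences(
        {"t1": "ARND-", "t2": "ARNDC", "t3": "AR-DC", "t4": "GRNDC"})


def enumerate_binary_trees(labels):
    """All unrooted binary tree Newick strings on ``labels`` by stepwise
    addition (independent of the package's tree code)."""
    if len(labels) < 3:
        raise ValueError("need >= 3 labels")

    def grow(tree, leaf):
        # tree is a nested tuple; insert leaf on every edge
        results = []

        def insert_everywhere(node, path):
            if isinstance(node, tuple):
                for i, child in enumerate(node):
                    insert_everywhere(child, path + (i,))
            results.append(path)

        insert_everywhere(tree, ())
        out = []
        for path in results:
            if path == ():
                continue

            def rebuild(node, p):
                if not p:
                    return (node, leaf)
                i = p[0]
                return tuple(rebuild(c, p[1:]) if j == i else c
                             for j, c in enumerate(node))

            out.append(rebuild(tree, path))
        return out

    trees = [(labels[0], labels[1], labels[2])]
    for leaf in labels[3:]:
        trees = [t2 for t in trees for t2 in grow(t, leaf)]

    def to_newick(node):
        if isinstance(node, tuple):
            return "(" + ",".join(to_newick(c) for c in node) + ")"
        return node

    return [to_newick(t) + ";" for t in trees]


def dendropy_splits(tree):
    """Non-trivial splits via dendropy's own bipartition machinery —
    the independent oracle for split arithmetic."""
    t = tree.clone(depth=1)
    t.is_rooted = False
    t.update_bipartitions(suppress_unifurcations=True)
    labels = sorted(lf.taxon.label for lf in t.leaf_node_iter())
    n = len(labels)
    out = set()
    for bp in t.bipartition_encoding:
        mask = bp.split_bitmask
        side = frozenset(lab for lab in labels
                         if mask & t.taxon_namespace.taxon_bitmask(
                             t.taxon_namespace.get_taxon(lab)))
        if 1 < len(side) < n - 1:
            comp = frozenset(labels) - side
            out.add(side if min(labels) not in side else comp)
    return out
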