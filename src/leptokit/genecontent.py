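"""Gene presence/absence analysis: matrix building, dual UPGMA clustering
and Dollo-parsimony loss counting under alternative host-tree scenarios.

Under Dollo parsimony a gene is gained once (at the origin, here the root of
the supplied scenario tree) and can only be lost; the minimum number of
losses for a gene is the number of maximal clades whose leaves all lack it.
Comparing the summed minima across two candidate host trees asks which
scenario requires fewer parallel losses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from . import treeops


class GeneContentError(ValueError):
    pass


@dataclass
class GeneMatrix:
    """Binary taxa x genes presence/absence matrix."""

    data: pd.DataFrame  # index = taxa, columns = genes, values in {0, 1}
    dropped_genes: list[str] = field(default_factory=list)
    groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise GeneContentError("matrix entries must be 0/1")
        if self.data.index.duplicated().any() or self.data.columns.duplicated().any():
            raise GeneContentError("duplicate taxon or gene names")

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def genes(self) -> list[str]:
        return list(self.data.columns)


def build_matrix(ortholog_table: pd.DataFrame, min_taxa: int = 3) -> GeneMatrix:
    """Convert a long-format ortholog table to a binary presence matrix.

    ``ortholog_table`` has columns gene, taxon, count. Presence is count >= 1;
    genes present in fewer than ``min_taxa`` taxa are dropped (and logged).
    """
    need = {"gene", "taxon", "count"}
    if not need <= set(ortholog_table.columns):
        raise GeneContentError(f"ortholog table needs columns {sorted(need)}")
    wide = (ortholog_table.assign(present=lambda d: (d["count"] >= 1).astype(int))
            .pivot_table(index="taxon", columns="gene", values="present",
                         aggfunc="max", fill_value=0))
    keep = wide.columns[wide.sum(axis=0) >= min_taxa]
    dropped = sorted(set(wide.columns) - set(keep))
    return GeneMatrix(wide[keep].astype(int), dropped_genes=dropped)


def cluster_matrix(matrix: GeneMatrix, axis: str = "taxa",
                   metric: str = "euclidean") -> dendropy.Tree:
    """UPGMA dendrogram of taxa (rows) or genes (columns).

    ``metric`` is ``euclidean`` (default) or ``jaccard``
    (|symmetric difference| / |union| on the binary vectors).
    """
    if axis not in ("taxa", "genes"):
        raise GeneContentError("axis must be 'taxa' or 'genes'")
    M = matrix.data.to_numpy(float)
    labels = matrix.taxa
    if axis == "genes":
        M, labels = M.T, matrix.genes
    if len(labels) < 2:
        raise GeneContentError("need at least 2 items to cluster")
    if metric == "euclidean":
        D = np.sqrt(((M[:, None, :] - M[None, :, :]) ** 2).sum(axis=2))
    elif metric == "jaccard":
        inter = M @ M.T
        union = M.sum(axis=1)[:, None] + M.sum(axis=1)[None, :] - inter
        with np.errstate(invalid="ignore"):
            D = np.where(union > 0, 1.0 - inter / union, 0.0)
        np.fill_diagonal(D, 0.0)
    else:
        raise GeneContentError(f"unknown metric {metric!r}")
    return treeops.upgma(D, labels)


@dataclass
class LossReport:
    scenario: str
    per_gene: dict[str, int]
    total: int
    all_absent_genes: list[str]
    assumptions: dict = field(default_factory=dict)


def dollo_losses(matrix: GeneMatrix, host_tree: dendropy.Tree,
                 scenario: str = "scenario") -> LossReport:
    """Minimum Dollo loss count per gene on a rooted host tree.

    Presence is assumed at the root (the gain); the minimum number of losses
    is the number of maximal all-absent clades. A gene absent from every
    taxon counts one loss at the origin and is flagged.
    """
    tree_leaves = set(treeops.leaf_labels(host_tree))
    missing = set(matrix.taxa) - tree_leaves
    if missing:
        raise GeneContentError(f"taxa missing from host tree: {sorted(missing)}")
    work = host_tree.clone(depth=1)
    if tree_leaves - set(matrix.taxa):
        work.retain_taxa_with_labels(matrix.taxa)
        work.suppress_unifurcations()
    nodes = list(work.postorder_node_iter())
    per_gene: dict[str, int] = {}
    all_absent: list[str] = []
    presence = matrix.data
    for gene in matrix.genes:
        col = presence[gene]
        absent: dict = {}
        losses = 0
        for node in nodes:
            if node.is_leaf():
                absent[node] = col[node.taxon.label] == 0
            else:
                absent[node] = all(absent[c] for c in node.child_nodes())
        for node in nodes:
            if absent[node] and (node.parent_node is None
                                 or not absent[node.parent_node]):
                losses += 1
        if absent[nodes[-1]]:
            all_absent.append(gene)
        per_gene[gene] = losses
    return LossReport(scenario, per_gene, sum(per_gene.values()), all_absent,
                      {"origin": "root of scenario tree", "model": "Dollo"})


def compare_scenarios(matrix: GeneMatrix, scenarioA: dendropy.Tree,
                      scenarioB: dendropy.Tree,
                      labels: tuple[str, str] = ("A", "B")) -> dict:
    """Dollo loss totals under two host-tree scenarios plus a per-gene table."""
    ra = dollo_losses(matrix, scenarioA, labels[0])
    rb = dollo_losses(matrix, scenarioB, labels[1])
    table = pd.DataFrame({
        "gene": matrix.genes,
        f"losses_{labels[0]}": [ra.per_gene[g] for g in matrix.genes],
        f"losses_{labels[1]}": [rb.per_gene[g] for g in matrix.genes],
    })
    table["difference"] = (table[f"losses_{labels[0]}"]
                           - table[f"losses_{labels[1]}"])
    return {"reportA": ra, "reportB": rb,
            "totalA": ra.total, "totalB": rb.total, "table": table}
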