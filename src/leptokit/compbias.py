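"""Amino-acid compositional-bias classification.

Five-step procedure producing the enriched/depleted amino-acid classes that
branch-specific frequency-shift models consume: (1) per-taxon residue counts,
(2) chi-squared homogeneity test with Pearson residuals, (3) UPGMA of taxa on
their residual profiles cut at the root into two groups, (4) per-residue
two-sided binomial tests between the groups with a signed -log10(p) score,
(5) classification into enriched / depleted / other at a score threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest, chi2

from . import treeops
from .align import Alignment, residue_counts


class CompBiasError(ValueError):
    pass


@dataclass
class ResidualTable:
    """Observed/expected residue counts and Pearson residuals per taxon."""

    taxa: list[str]
    residues: list[str]
    observed: np.ndarray
    expected: np.ndarray
    residuals: np.ndarray
    chi2: float
    df: int
    p: float


def residual_table(counts: np.ndarray | pd.DataFrame,
                   taxa: list[str] | None = None,
                   residues: list[str] | None = None) -> ResidualTable:
    """Chi-squared homogeneity test on a taxa x residues count table.

    Expected counts come from the row/column marginals; Pearson residuals are
    (O - E) / sqrt(E) and chi2 is their squared sum with (T-1)(K-1) df.
    """
    if isinstance(counts, pd.DataFrame):
        taxa = list(counts.index)
        residues = list(counts.columns)
        O = counts.to_numpy(float)
    else:
        O = np.asarray(counts, float)
        taxa = taxa or [f"t{i}" for i in range(O.shape[0])]
        residues = residues or [f"r{j}" for j in range(O.shape[1])]
    if (O < 0).any():
        raise CompBiasError("counts must be nonnegative")
    rows, cols = O.sum(axis=1), O.sum(axis=0)
    if (rows == 0).any():
        raise CompBiasError(f"all-zero row: {taxa[int(np.argmax(rows == 0))]!r}")
    if (cols == 0).any():
        raise CompBiasError(
            f"all-zero column: {residues[int(np.argmax(cols == 0))]!r}")
    E = np.outer(rows, cols) / O.sum()
    R = (O - E) / np.sqrt(E)
    stat = float((R ** 2).sum())
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    p = float(chi2.sf(stat, df)) if df > 0 else 1.0
    return ResidualTable(taxa, residues, O, E, R, stat, df, p)


@dataclass
class GroupSplit:
    group1: list[str]
    group2: list[str]
    tree: "treeops.dendropy.Tree"
    no_signal: bool = False


def split_taxa(residuals: ResidualTable) -> GroupSplit:
    """Cut a UPGMA tree of taxon residual profiles at the root into 2 groups.

    Distances are Euclidean between Pearson-residual rows. Group 1 is the
    root clade containing the lexicographically smallest taxon label, so the
    orientation (and hence "enriched" vs "depleted") is reproducible.
    """
    R = residuals.residuals
    if R.shape[0] < 2:
        raise CompBiasError("need at least 2 taxa to split")
    D = np.sqrt(((R[:, None, :] - R[None, :, :]) ** 2).sum(axis=2))
    tree = treeops.upgma(D, residuals.taxa)
    g1, g2 = treeops.root_children_partition(tree)
    if min(g1) > min(g2):
        g1, g2 = g2, g1
    no_signal = bool(np.allclose(D, 0.0))
    return GroupSplit(sorted(g1), sorted(g2), tree, no_signal)


@dataclass
class CompositionClasses:
    """Signed per-residue scores and the enriched/depleted/other partition.

    Scores are sign(freq_group1 - freq_group2) * -log10(binomial p); positive
    means over-represented in group 1 ("enriched" is relative to group 1).
    """

    scores: dict[str, float]
    p_values: dict[str, float]
    enriched: set[str]
    depleted: set[str]
    other: set[str]
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for res in sorted(self.scores):
            cls = ("enriched" if res in self.enriched
                   else "depleted" if res in self.depleted else "other")
            rows.append({"residue": res, "score": self.scores[res],
                         "p": self.p_values[res], "class": cls})
        return pd.DataFrame(rows)


def classify_residues(counts: pd.DataFrame | np.ndarray, split: GroupSplit,
                      threshold: float = 2.0,
                      taxa: list[str] | None = None,
                      residues: list[str] | None = None) -> CompositionClasses:
    """Binomial enrichment test per residue between the two taxon groups.

    For residue a with group counts x1, x2 and group totals N1, N2, a
    two-sided exact binomial test of x1 successes in x1+x2 trials at success
    probability N1/(N1+N2) yields p_a. The score is
    sign(x1/N1 - x2/N2) * -log10(p_a); residues with score >= ``threshold``
    are enriched (in group 1), <= -``threshold`` depleted, the rest other.
    """
    if isinstance(counts, pd.DataFrame):
        taxa, residues = list(counts.index), list(counts.columns)
        O = counts.to_numpy(float)
    else:
        O = np.asarray(counts, float)
    if not set(split.group1) | set(split.group2) >= set(taxa):
        raise CompBiasError("split does not cover the count table's taxa")
    i1 = [i for i, t in enumerate(taxa) if t in set(split.group1)]
    i2 = [i for i, t in enumerate(taxa) if t in set(split.group2)]
    if not i1 or not i2:
        raise CompBiasError("empty group")
    x1 = O[i1].sum(axis=0)
    x2 = O[i2].sum(axis=0)
    N1, N2 = x1.sum(), x2.sum()
    scores, pvals = {}, {}
    for j, res in enumerate(residues):
        n = int(x1[j] + x2[j])
        if n == 0:
            scores[res], pvals[res] = 0.0, 1.0
            continue
        p = binomtest(int(x1[j]), n, N1 / (N1 + N2), alternative="two-sided").pvalue
        sign = np.sign(x1[j] / N1 - x2[j] / N2)
        pvals[res] = float(p)
        scores[res] = float(sign * -np.log10(max(p, 1e-300)))
    enriched = {r for r, s in scores.items() if s >= threshold}
    depleted = {r for r, s in scores.items() if s <= -threshold}
    other = set(scores) - enriched - depleted
    return CompositionClasses(scores, pvals, enriched, depleted, other,
                              threshold)


def classify_alignment(aln: Alignment, threshold: float = 2.0,
                       ) -> tuple[ResidualTable, GroupSplit, CompositionClasses]:
    """Run the full five-step procedure on an alignment."""
    counts = pd.DataFrame(residue_counts(aln), index=aln.taxa,
                          columns=list(aln.alphabet))
    rt = residual_table(counts)
    split = split_taxa(rt)
    classes = classify_residues(counts, split, threshold)
    return rt, split, classes


def write_gfmix_classes(classes: CompositionClasses, path) -> None:
    """Write the class file consumed by frequency-shift mixture models.

    Line 1: enriched residues (single letters, alphabetical, no separators);
    line 2: depleted residues.
    """
    with open(path, "w") as fh:
        fh.write("".join(sorted(classes.enriched)) + "\n")
        fh.write("".join(sorted(classes.depleted)) + "\n")


def read_gfmix_classes(path) -> tuple[set[str], set[str]]:
    with open(path) as fh:
        enriched = set(fh.readline().strip())
        depleted = set(fh.readline().strip())
    return enriched, depleted
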