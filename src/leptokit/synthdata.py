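"""Seeded generators for every input the pipeline consumes.

Each generator returns its dataset together with a :class:`TruthRecord`
holding the parameters that produced it, so planted signal can be checked
exactly: alignments evolved on known trees (optionally with a clade-
restricted compositional shift), marker-gene complements with planted
completeness/redundancy, coverage matrices with correlated organelle pairs
and detection dropouts, and gene presence/absence matrices from Dollo loss
on a known tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .align import Alignment
from .genecontent import GeneMatrix
from .organelle_qc import MarkerSet
from .phylolik import SubstModel
from .treeops import leaf_labels


@dataclass
class TruthRecord:
    generator: str
    seed: int
    params: dict = field(default_factory=dict)

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"generator\t{self.generator}\nseed\t{self.seed}\n")
            for k, v in self.params.items():
                fh.write(f"{k}\t{v}\n")


# ---------------------------------------------------------------------------
# Sequence evolution

def _shifted_model(model: SubstModel, delta: np.ndarray) -> SubstModel:
    """Model with frequencies displaced as pi' ∝ pi * exp(delta)."""
    delta = np.asarray(delta, float)
    if delta.shape != (model.k,):
        raise ValueError("delta must have one entry per state")
    pi = model.frequencies * np.exp(delta)
    pi = pi / pi.sum()
    return SubstModel(model.alphabet, model.exchangeabilities, pi,
                      model.gamma_shape, model.n_cats,
                      name=model.name + "+shift")


def sim_alignment(tree: dendropy.Tree, model: SubstModel, n_sites: int,
                  seed: int, shift: dict | None = None,
                  ) -> tuple[Alignment, TruthRecord]:
    """Evolve an alignment along ``tree`` under ``model``.

    Within the clade named by ``shift`` (``{"clade": [labels...],
    "delta": array}``) substitution happens under the frequency-displaced
    model, so the shifted taxa form a proper (non-stationary) Markov chain
    rather than having residues swapped after the fact. Per-site Gamma rates
    are drawn when the model has a shape parameter.
    """
    rng = np.random.default_rng(seed)
    taxa = leaf_labels(tree)
    k = model.k
    states = np.arange(k)
    shifted = _shifted_model(model, shift["delta"]) if shift else None
    shift_clade = set(shift["clade"]) if shift else set()

    def in_shift(node) -> bool:
        if not shift_clade:
            return False
        below = {lf.taxon.label for lf in node.leaf_iter()}
        return below <= shift_clade

    if model.gamma_shape is None:
        rates = np.ones(n_sites)
    elif model.n_cats > 1:
        # sample from the model's own discrete categories so simulation and
        # inference share the rate distribution exactly
        rates = rng.choice(model.category_rates(), size=n_sites)
    else:
        rates = rng.gamma(model.gamma_shape, 1.0 / model.gamma_shape, n_sites)

    seqs: dict = {}
    root = tree.seed_node
    if n_sites == 0:
        aln = Alignment(list(taxa),
                        np.empty((len(taxa), 0), dtype="<U1"), model.alphabet)
        return aln, TruthRecord("sim_alignment", seed, {"n_sites": 0})

    node_states = {root: rng.choice(states, size=n_sites, p=model.frequencies)}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        m = shifted if (shifted is not None and in_shift(node)) else model
        t = node.edge.length or 0.0
        parent_states = node_states[node.parent_node]
        child = parent_states.copy()
        # group sites by (rounded) rate for vectorized transition sampling
        for rate in np.unique(rates):
            idx = np.nonzero(rates == rate)[0]
            P = m.transition_matrix(t, float(rate))
            u = rng.random(len(idx))
            cdf = np.cumsum(P[parent_states[idx]], axis=1)
            child[idx] = (u[:, None] > cdf).sum(axis=1)
        node_states[node] = child
        if node.is_leaf():
            seqs[node.taxon.label] = child

    alpha = np.array(list(model.alphabet))
    mat = np.array([alpha[seqs[t]] for t in taxa])
    aln = Alignment(list(taxa), mat, model.alphabet)
    truth = TruthRecord("sim_alignment", seed, {
        "n_sites": n_sites, "model": model.name,
        "gamma_shape": model.gamma_shape,
        "shift_clade": sorted(shift_clade),
        "delta": None if shift is None else list(np.asarray(shift["delta"])),
    })
    return aln, truth


# ---------------------------------------------------------------------------
# Organelle complements and coverage

def sim_genome_complement(markers: MarkerSet, completeness_frac: float,
                          redundancy_frac: float, seed: int,
                          ) -> tuple[dict[str, int], TruthRecord]:
    """Plant a marker complement with known completeness and redundancy.

    Samples round(completeness_frac * size) present genes and duplicates
    round(redundancy_frac * size) of them (each duplicated gene gains one
    extra copy), so QC recovers the planted fractions exactly.
    """
    if not (0 <= completeness_frac <= 1 and 0 <= redundancy_frac <= 1):
        raise ValueError("fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_present = round(completeness_frac * markers.size)
    n_dup = min(round(redundancy_frac * markers.size), n_present)
    present = list(rng.choice(markers.genes, size=n_present, replace=False))
    dups = set(rng.choice(present, size=n_dup, replace=False)) if n_dup else set()
    copies = {g: (2 if g in dups else 1) for g in present}
    truth = TruthRecord("sim_genome_complement", seed, {
        "completeness": 100.0 * n_present / markers.size,
        "redundancy": 100.0 * n_dup / markers.size,
    })
    return copies, truth


def sim_coverage(n_genomes: int, n_samples: int,
                 linked_pairs: list[tuple[int, int, float]], seed: int,
                 log_mean: float = 1.0, log_sd: float = 1.0,
                 dropout_rate: float = 0.1,
                 ) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Lognormal coverage matrix with planted correlated organelle pairs.

    Per-genome log-coverage across samples is Gaussian with sd ``log_sd``;
    each linked pair (i, j, rho) shares a latent factor giving correlation
    rho on the log scale. Detection rises with coverage (saturating with
    mild noise) and a ``dropout_rate`` fraction of entries is forced below
    the 0.25 detection cutoff. Returns (coverage, detection, truth), both
    genome x sample frames.
    """
    rng = np.random.default_rng(seed)
    genomes = [f"G{i:03d}" for i in range(n_genomes)]
    samples = [f"S{j:03d}" for j in range(n_samples)]
    Z = rng.normal(size=(n_genomes, n_samples))
    for i, j, rho in linked_pairs:
        if not -1.0 <= rho <= 1.0:
            raise ValueError("rho must be in [-1, 1]")
        shared = rng.normal(size=n_samples)
        a = np.sqrt(abs(rho))
        b = np.sqrt(1.0 - abs(rho))
        Z[i] = a * shared + b * rng.normal(size=n_samples)
        Z[j] = np.sign(rho) * a * shared + b * rng.normal(size=n_samples)
    logcov = log_mean + log_sd * Z
    cov = np.exp(logcov)
    # detection saturates with coverage: 1 - exp(-cov) with noise
    det = 1.0 - np.exp(-cov)
    det = np.clip(det + rng.normal(0, 0.05, det.shape), 0.0, 1.0)
    drop = rng.random(det.shape) < dropout_rate
    det[drop] = rng.uniform(0.0, 0.25, drop.sum())
    coverage = pd.DataFrame(cov, index=genomes, columns=samples)
    detection = pd.DataFrame(det, index=genomes, columns=samples)
    truth = TruthRecord("sim_coverage", seed, {
        "linked_pairs": [(genomes[i], genomes[j], rho)
                         for i, j, rho in linked_pairs],
        "log_mean": log_mean, "log_sd": log_sd,
        "dropout_rate": dropout_rate,
    })
    return coverage, detection, truth


# ---------------------------------------------------------------------------
# Dollo gene content

def sim_dollo(host_tree: dendropy.Tree, n_genes: int, loss_rate: float,
              seed: int) -> tuple[GeneMatrix, TruthRecord]:
    """Evolve binary gene presence by Dollo loss on a rooted tree.

    Every gene is present at the root; losses arrive as Poisson events with
    mean ``loss_rate`` per branch (branch lengths ignored: rate is per edge),
    and descendants of a loss lack the gene. The truth records the number of
    effective loss events per gene (events on branches where the gene was
    still present).
    """
    if loss_rate < 0:
        raise ValueError("loss rate must be >= 0")
    rng = np.random.default_rng(seed)
    taxa = leaf_labels(host_tree)
    nodes = list(host_tree.preorder_node_iter())
    data = np.ones((len(taxa), n_genes), dtype=int)
    row = {t: i for i, t in enumerate(taxa)}
    true_events = np.zeros(n_genes, dtype=int)
    for g in range(n_genes):
        present = {nodes[0]: True}
        for node in nodes[1:]:
            state = present[node.parent_node]
            if state and rng.poisson(loss_rate) > 0:
                state = False
                true_events[g] += 1
            present[node] = state
            if node.is_leaf():
                data[row[node.taxon.label], g] = int(state)
    matrix = GeneMatrix(pd.DataFrame(data, index=taxa,
                                     columns=[f"gene{g:03d}" for g in range(n_genes)]))
    truth = TruthRecord("sim_dollo", seed, {
        "loss_rate": loss_rate,
        "true_events": list(map(int, true_events)),
        "total_events": int(true_events.sum()),
    })
    return matrix, truth
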