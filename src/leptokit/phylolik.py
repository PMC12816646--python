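"""Fixed-topology phylogenetic likelihood engine.

Felsenstein pruning under time-reversible empirical amino-acid models (LG,
cpREV, or user-supplied exchangeabilities) with discrete-Gamma rate variation
and optional fixed per-site frequency profiles, plus coordinate-wise branch
length optimization and I/O for per-site log-likelihood tables.

The engine is deliberately small: no topology search, no mixture-weight
estimation — it exists to evaluate and optimize candidate topologies so the
topology-test battery is runnable end to end.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import gamma as gamma_dist

from .align import Alignment
from .treeops import leaf_labels

MIN_BRANCH, MAX_BRANCH = 0.0, 10.0


class LikelihoodError(ValueError):
    pass


@dataclass
class SubstModel:
    """Time-reversible substitution model with discrete-Gamma rates.

    Q = S diag(pi), scaled so the expected rate at equilibrium is 1
    substitution per unit branch length. Discrete Gamma uses ``n_cats``
    equal-probability categories whose rates are the within-bin means
    (mean rate exactly 1).
    """

    alphabet: str
    exchangeabilities: np.ndarray   # (k, k) symmetric, zero diagonal
    frequencies: np.ndarray         # (k,) simplex
    gamma_shape: float | None = None
    n_cats: int = 1
    name: str = "custom"
    # eigendecomposition cache of the symmetrized rate matrix
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        k = len(self.alphabet)
        S = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if S.shape != (k, k) or not np.allclose(S, S.T):
            raise LikelihoodError("exchangeabilities must be k x k symmetric")
        if pi.shape != (k,) or abs(pi.sum() - 1) > 1e-6 or (pi <= 0).any():
            raise LikelihoodError("frequencies must be a positive simplex")
        pi = pi / pi.sum()
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        Q /= mu
        self.Q = Q
        self.frequencies = pi
        # symmetric form diag(pi)^(1/2) Q diag(pi)^(-1/2) for stable expm
        sq = np.sqrt(pi)
        A = Q * sq[:, None] / sq[None, :]   # = S_ij sqrt(pi_i pi_j), symmetric
        A = (A + A.T) / 2.0
        w, U = np.linalg.eigh(A)
        self._eig = (w, U, sq)

    @property
    def k(self) -> int:
        return len(self.alphabet)

    def category_rates(self) -> np.ndarray:
        if not hasattr(self, "_rates_cache"):
            self._rates_cache = discrete_gamma_rates(self.gamma_shape,
                                                     self.n_cats)
        return self._rates_cache

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(rate * t) = exp(Q rate t), rows summing to 1."""
        if t < 0:
            raise LikelihoodError("negative branch length")
        if t * rate == 0.0:
            return np.eye(self.k)
        w, U, sq = self._eig
        e = np.exp(w * (t * rate))
        P = (U * e[None, :]) @ U.T
        P = (P / sq[:, None]) * sq[None, :]
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_matrices(self, t: float) -> np.ndarray:
        """(n_cats, k, k) transition matrices, one per Gamma category."""
        return np.stack([self.transition_matrix(t, r)
                         for r in self.category_rates()])


def discrete_gamma_rates(shape: float | None, n_cats: int) -> np.ndarray:
    """Mean-of-bin discrete Gamma rates for ``n_cats`` equal-weight categories."""
    if n_cats < 1:
        raise LikelihoodError("need at least one rate category")
    if n_cats == 1 or shape is None:
        return np.ones(n_cats if n_cats >= 1 else 1)
    a = float(shape)
    if a <= 0:
        raise LikelihoodError("gamma shape must be positive")
    edges = gamma_dist.ppf(np.linspace(0, 1, n_cats + 1), a, scale=1.0 / a)
    # E[X; X in bin] / P(bin) using the Gamma(a+1, 1/a) upper-tail identity
    upper = gamma_dist.cdf(edges, a + 1, scale=1.0 / a)
    rates = (upper[1:] - upper[:-1]) * n_cats
    return rates / rates.mean()


def _load_builtin(name: str) -> tuple[str, np.ndarray, np.ndarray]:
    text = (resources.files("leptokit.data") / f"{name}.txt").read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    alphabet = "".join(lines[0].split())
    k = len(alphabet)
    S = np.array([[float(x) for x in lines[1 + i].split()] for i in range(k)])
    pi = np.array([float(x) for x in lines[1 + k].split()])
    return alphabet, S, pi


def load_model(name: str, gamma_shape: float | None = None,
               n_cats: int = 1, frequencies: np.ndarray | None = None) -> SubstModel:
    """Load a named model. ``"LG"``, ``"cpREV"``, ``"POISSON"`` are built in.

    ``frequencies`` overrides the model's equilibrium frequencies (the "+F"
    treatment when observed frequencies are passed).
    """
    key = name.upper()
    if key == "POISSON":
        alphabet = "ARNDCQEGHILKMFPSTWYV"
        S = np.ones((20, 20)) - np.eye(20)
        pi = np.full(20, 1 / 20)
    elif key in ("LG", "CPREV"):
        alphabet, S, pi = _load_builtin("lg" if key == "LG" else "cprev")
    else:
        raise LikelihoodError(f"unknown model {name!r}")
    if frequencies is not None:
        pi = np.asarray(frequencies, float)
    return SubstModel(alphabet, S, pi, gamma_shape, n_cats, name=key)


@dataclass
class SiteProfileSet:
    """Fixed per-site amino-acid frequency profiles (PMSF-style).

    ``profiles`` is (n_profiles, k) on the simplex; ``assignment`` maps each
    site to a profile row.
    """

    profiles: np.ndarray
    assignment: np.ndarray

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, float)
        self.assignment = np.asarray(self.assignment, int)
        if np.any(np.abs(self.profiles.sum(axis=1) - 1.0) > 1e-9):
            raise LikelihoodError("profiles must sum to 1")


# ---------------------------------------------------------------------------
# Pruning

def _encode_leaves(aln: Alignment, model: SubstModel) -> np.ndarray:
    """Leaf partial likelihoods (n_taxa, n_sites, k); missing data = all ones."""
    k = model.k
    idx = {c: i for i, c in enumerate(model.alphabet)}
    out = np.ones((aln.n_taxa, aln.n_sites, k))
    for c, i in idx.items():
        hit = aln.matrix == c
        if hit.any():
            rows, cols = np.nonzero(hit)
            out[rows, cols, :] = 0.0
            out[rows, cols, i] = 1.0
    return out


class TreeLikelihood:
    """Likelihood of one alignment on one fixed topology.

    Caches the tree structure and leaf encodings; branch lengths live on the
    dendropy tree's edges and can be re-optimized in place.
    """

    def __init__(self, aln: Alignment, tree: dendropy.Tree, model: SubstModel,
                 profiles: SiteProfileSet | None = None):
        if set(leaf_labels(tree)) != set(aln.taxa):
            raise LikelihoodError("tree leaves do not match alignment taxa")
        if profiles is not None and len(profiles.assignment) != aln.n_sites:
            raise LikelihoodError("profile assignment length != n_sites")
        self.aln = aln
        self.tree = tree
        self.model = model
        self.profiles = profiles
        self.nodes = list(tree.postorder_node_iter())
        self._leaf_partials = _encode_leaves(aln, model)
        self._taxon_row = {t: i for i, t in enumerate(aln.taxa)}
        self._rates = model.category_rates()

    # -- core recursion ----------------------------------------------------
    def _node_partials(self) -> dict:
        """Post-order conditional likelihoods per node: (n_sites, m, k)."""
        m, k = len(self._rates), self.model.k
        partials: dict = {}
        for node in self.nodes:
            if node.is_leaf():
                base = self._leaf_partials[self._taxon_row[node.taxon.label]]
                partials[node] = np.broadcast_to(base[:, None, :],
                                                 (self.aln.n_sites, m, k))
            else:
                acc = None
                for child in node.child_nodes():
                    P = self.model.transition_matrices(child.edge.length or 0.0)
                    contrib = np.einsum("smk,mjk->smj", partials[child], P)
                    acc = contrib if acc is None else acc * contrib
                partials[node] = acc
        return partials

    def _site_freqs(self) -> np.ndarray:
        """(n_sites, k) root frequencies, honoring fixed site profiles."""
        if self.profiles is None:
            return np.broadcast_to(self.model.frequencies,
                                   (self.aln.n_sites, self.model.k))
        return self.profiles.profiles[self.profiles.assignment]

    def site_log_likelihoods(self) -> np.ndarray:
        partials = self._node_partials()
        root = self.nodes[-1]
        pi = self._site_freqs()
        site_lik = np.einsum("smk,sk->s", partials[root], pi) / len(self._rates)
        with np.errstate(divide="ignore"):
            return np.log(site_lik)

    def log_likelihood(self) -> float:
        return float(self.site_log_likelihoods().sum())

    # -- branch-length optimization ---------------------------------------
    def _edge_flanks(self):
        """Per edge, the two conditional-likelihood arrays flanking it.

        For the edge above ``node``: ``down`` is node's post-order partial and
        ``up`` is the pre-order partial of the rest of the tree at the parent,
        with root frequencies folded in. The edge likelihood is then
        mean_cats sum_ij up_i P_ij(t) down_j per site.
        """
        partials = self._node_partials()
        root = self.nodes[-1]
        m, k = len(self._rates), self.model.k
        pi = self._site_freqs()
        uppers: dict = {root: np.broadcast_to(pi[:, None, :],
                                              (self.aln.n_sites, m, k))}
        flanks = []
        for node in reversed(self.nodes):  # preorder
            if node is root:
                continue
            parent = node.parent_node
            flank_up = uppers[parent].copy()
            for sib in parent.child_nodes():
                if sib is node:
                    continue
                P = self.model.transition_matrices(sib.edge.length or 0.0)
                flank_up *= np.einsum("smk,mjk->smj", partials[sib], P)
            # outside partial at the node itself: propagate through its edge
            P_own = self.model.transition_matrices(node.edge.length or 0.0)
            uppers[node] = np.einsum("smi,mij->smj", flank_up, P_own)
            flanks.append((node, flank_up, partials[node]))
        return flanks

    def _edge_lnl(self, up: np.ndarray, down: np.ndarray, t: float) -> float:
        P = self.model.transition_matrices(t)
        lik = np.einsum("smi,mij,smj->s", up, P, down) / len(self._rates)
        with np.errstate(divide="ignore"):
            return float(np.log(lik).sum())

    def _edge_lnl_factory(self, up: np.ndarray, down: np.ndarray):
        """Fast per-edge lnL(t) via the model's eigenbasis.

        Sum_ij up_i P_ij(t) down_j = Sum_k (up D^-1/2 V)_k (down D^1/2 V)_k
        e^(w_k r t), so each evaluation costs O(sites * cats * k) after a
        one-off projection per edge.
        """
        w, V, sq = self.model._eig
        ab = np.einsum("smi,ik->smk", up / sq, V) \
            * np.einsum("smj,jk->smk", down * sq, V)
        rates = self._rates
        m = len(rates)

        def lnl(t: float) -> float:
            e = np.exp(np.outer(rates, w) * t)
            lik = np.einsum("smk,mk->s", ab, e) / m
            return float(np.log(np.maximum(lik, 1e-300)).sum())

        return lnl

    def optimize_branch_lengths(self, init: float = 0.1, lnl_tol: float = 1e-4,
                                brent_tol: float = 1e-6, max_sweeps: int = 100,
                                ) -> float:
        """Coordinate-wise branch length optimization at fixed topology.

        Each sweep walks the tree depth-first: every edge is optimized with a
        bounded scalar search against partials that are exact at the moment of
        the update (ancestor edges already carry their new lengths; a
        subtree's post-order partial is refreshed when the walk backtracks
        through it), so each single-edge move cannot decrease the likelihood
        and lnL is non-decreasing across sweeps. Stops when a sweep improves
        lnL by less than ``lnl_tol`` or after ``max_sweeps``.
        """
        for node in self.nodes:
            if node.parent_node is not None and node.edge.length is None:
                node.edge.length = init
        current = self.log_likelihood()
        if not np.isfinite(current):
            # zero-length initialization conflicts; nudge and retry once
            for node in self.nodes:
                if node.parent_node is not None and node.edge.length == 0.0:
                    node.edge.length = init
            current = self.log_likelihood()
            if not np.isfinite(current):
                raise LikelihoodError("non-finite log-likelihood at start")
        m, k = len(self._rates), self.model.k
        for _ in range(max_sweeps):
            partials = self._node_partials()
            root = self.nodes[-1]
            pi = self._site_freqs()
            uppers = {root: np.broadcast_to(pi[:, None, :],
                                            (self.aln.n_sites, m, k))}

            def towards(child):
                P = self.model.transition_matrices(child.edge.length or 0.0)
                return np.einsum("smk,mjk->smj", partials[child], P)

            def visit(node):
                for child in node.child_nodes():
                    flank_up = uppers[node].copy()
                    for sib in node.child_nodes():
                        if sib is not child:
                            flank_up *= towards(sib)
                    f = self._edge_lnl_factory(flank_up, partials[child])
                    res = minimize_scalar(
                        lambda t: -f(t), bounds=(MIN_BRANCH, MAX_BRANCH),
                        method="bounded", options={"xatol": brent_tol})
                    if -res.fun >= f(child.edge.length or 0.0):
                        child.edge.length = float(res.x)
                    P_own = self.model.transition_matrices(child.edge.length)
                    uppers[child] = np.einsum("smi,mij->smj", flank_up, P_own)
                    visit(child)
                    if not child.is_leaf():
                        # refresh so later siblings/ancestors see new lengths
                        acc = None
                        for gc in child.child_nodes():
                            contrib = towards(gc)
                            acc = contrib if acc is None else acc * contrib
                        partials[child] = acc

            visit(root)
            new = self.log_likelihood()
            if new - current < lnl_tol:
                current = max(new, current)
                break
            current = new
        return current


def site_log_likelihoods(aln: Alignment, tree: dendropy.Tree, model: SubstModel,
                         profiles: SiteProfileSet | None = None) -> np.ndarray:
    """Per-site log-likelihoods of ``aln`` on ``tree`` (branch lengths fixed)."""
    return TreeLikelihood(aln, tree, model, profiles).site_log_likelihoods()


def total_log_likelihood(aln: Alignment, tree: dendropy.Tree, model: SubstModel,
                         profiles: SiteProfileSet | None = None) -> float:
    return float(site_log_likelihoods(aln, tree, model, profiles).sum())


def optimize_branch_lengths(aln: Alignment, topology: dendropy.Tree,
                            model: SubstModel,
                            profiles: SiteProfileSet | None = None,
                            init: float = 0.1) -> tuple[dendropy.Tree, float]:
    """Optimize branch lengths on a copy of ``topology``; returns (tree, lnL)."""
    tree = topology.clone(depth=1)
    for edge in tree.preorder_edge_iter():
        edge.length = init if edge.head_node.parent_node is not None else None
    engine = TreeLikelihood(aln, tree, model, profiles)
    lnl = engine.optimize_branch_lengths(init=init)
    return tree, lnl


# ---------------------------------------------------------------------------
# Site log-likelihood tables

@dataclass
class SiteLikelihoodMatrix:
    """Per-topology vectors of per-site log-likelihoods."""

    labels: list[str]
    values: np.ndarray  # (n_topologies, n_sites)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, float))
        if len(self.labels) != self.values.shape[0]:
            raise LikelihoodError("label/row count mismatch")
        if not np.all(np.isfinite(self.values)):
            raise LikelihoodError("non-finite site log-likelihoods")

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]


def read_sitelh(path) -> SiteLikelihoodMatrix:
    """Read a site-lnL table: header "<K> <N>", then K lines "label v1..vN"."""
    with open(path) as fh:
        tokens = fh.readline().split()
        if len(tokens) != 2:
            raise LikelihoodError("header must be '<n_topologies> <n_sites>'")
        n_topo, n_sites = int(tokens[0]), int(tokens[1])
        labels, rows = [], []
        for line in fh:
            if not line.strip():
                continue
            parts = line.split()
            labels.append(parts[0])
            vals = [float(x) for x in parts[1:]]
            if len(vals) != n_sites:
                raise LikelihoodError(
                    f"row {parts[0]!r} has {len(vals)} values, expected {n_sites}")
            rows.append(vals)
    if len(rows) != n_topo:
        raise LikelihoodError(f"expected {n_topo} rows, found {len(rows)}")
    return SiteLikelihoodMatrix(labels, np.array(rows))


def write_sitelh(matrix: SiteLikelihoodMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.labels)} {matrix.n_sites}\n")
        for lab, row in zip(matrix.labels, matrix.values):
            fh.write(lab + " " + " ".join(f"{v:.10g}" for v in row) + "\n")
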