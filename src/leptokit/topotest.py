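"""Topology-test battery for constrained maximum-likelihood trees.

Implements the likelihood-ratio chi-squared test whose degrees of freedom are
the branches collapsed in the strict consensus of the two competing trees,
the Bonferroni-style correction 1 - (1-p)^A over the A fully binary trees
compatible with that consensus, and the approximately unbiased (AU) test via
RELL multiscale bootstrap with probit regression on the bootstrap scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .phylolik import SiteLikelihoodMatrix
from .treeops import count_binary_resolutions, strict_consensus

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 2))


class TopoTestError(ValueError):
    pass


def lrs_chisq_test(lnl_a: float, lnl_b: float, tree_a: dendropy.Tree,
                   tree_b: dendropy.Tree) -> dict:
    """Likelihood-ratio chi-squared test between two maximized topologies.

    LRS = 2 |lnL_a - lnL_b|; df = number of branches collapsed in the strict
    consensus of the two trees; p = upper-tail chi-squared(df) at LRS.
    """
    cons = strict_consensus(tree_a, tree_b)
    lrs = 2.0 * abs(float(lnl_a) - float(lnl_b))
    df = cons.collapsed_count
    if df == 0:
        if lrs > 1e-9:
            raise TopoTestError(
                "identical topologies cannot differ in maximized lnL")
        return {"LRS": 0.0, "df": 0, "p": 1.0, "consensus": cons}
    p = float(chi2.sf(lrs, df))
    return {"LRS": lrs, "df": df, "p": p, "consensus": cons}


def bonferroni_correct(p: float, A: int) -> float:
    """Correct p over the A binary trees compatible with the consensus:
    1 - (1 - p)^A."""
    if A < 1:
        raise TopoTestError("A must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise TopoTestError("p must be in [0, 1]")
    return float(1.0 - (1.0 - p) ** A)


@dataclass
class AuResult:
    """AU test result for one candidate topology."""

    label: str
    scales: np.ndarray
    B: int
    bp: np.ndarray           # bootstrap proportion per scale
    d: float                 # signed distance
    c: float                 # curvature
    p_au: float
    degenerate: bool
    seed: int


def _rell_bp(values: np.ndarray, scales, B: int, rng: np.random.Generator,
             chunk: int = 2000) -> np.ndarray:
    """Bootstrap proportions (n_scales, n_topologies) by RELL resampling.

    For each scale r, draws B multinomial site-weight vectors of size
    round(r*N) and records which topology attains the maximal resampled lnL
    sum; exact ties are split uniformly at random.
    """
    K, N = values.shape
    bp = np.zeros((len(scales), K))
    for si, r in enumerate(scales):
        size = max(1, int(round(r * N)))
        wins = np.zeros(K)
        done = 0
        while done < B:
            b = min(chunk, B - done)
            weights = rng.multinomial(size, np.full(N, 1.0 / N), size=b)
            sums = weights @ values.T           # (b, K)
            best = sums.max(axis=1, keepdims=True)
            is_best = np.isclose(sums, best, rtol=0, atol=1e-9)
            # exact ties credited fractionally: unbiased and exactly uniform
            wins += (is_best / is_best.sum(axis=1, keepdims=True)).sum(axis=0)
            done += b
        bp[si] = wins / B
    return bp


def au_test(sitelh: SiteLikelihoodMatrix, scales=DEFAULT_SCALES,
            B: int = 10_000, seed: int = 0) -> list[AuResult]:
    """Approximately unbiased test for every topology in a site-lnL matrix.

    Multiscale RELL bootstrap proportions BP_r are fitted by weighted least
    squares to probit(1 - BP_r) = d sqrt(r) + c / sqrt(r); the AU p-value is
    1 - Phi(d - c). Scales with degenerate BP (0 or 1) are excluded from the
    fit; a topology degenerate at every scale gets p 0 or 1 with a flag.
    """
    values = sitelh.values
    if values.shape[0] < 1:
        raise TopoTestError("need at least one topology")
    scales = np.asarray(scales, float)
    rng = np.random.default_rng(seed)
    if values.shape[0] == 1:
        return [AuResult(sitelh.labels[0], scales, B,
                         np.ones(len(scales)), -np.inf, 0.0, 1.0, True, seed)]
    bp_all = _rell_bp(values, scales, B, rng)
    out = []
    for ti, label in enumerate(sitelh.labels):
        bp = bp_all[:, ti]
        usable = (bp > 0.0) & (bp < 1.0)
        if usable.sum() < 2:
            p = 1.0 if bp.mean() > 0.5 else 0.0
            d = -np.inf if p == 1.0 else np.inf
            out.append(AuResult(label, scales, B, bp, d, 0.0, p, True, seed))
            continue
        r = scales[usable]
        z = norm.ppf(1.0 - bp[usable])
        X = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
        # delta-method weights: Var(z) ~ BP(1-BP) / (B phi(z)^2)
        phi = norm.pdf(z)
        w = B * phi ** 2 / (bp[usable] * (1.0 - bp[usable]))
        WX = X * w[:, None]
        beta = np.linalg.solve(X.T @ WX, WX.T @ z)
        d_hat, c_hat = float(beta[0]), float(beta[1])
        p = float(1.0 - norm.cdf(d_hat - c_hat))
        out.append(AuResult(label, scales, B, bp, d_hat, c_hat, p, False, seed))
    return out


@dataclass
class TopologyTestResult:
    table: pd.DataFrame
    best: str

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_battery(sitelh: SiteLikelihoodMatrix,
                trees: dict[str, dendropy.Tree],
                alpha: float = 0.05, scales=DEFAULT_SCALES,
                B: int = 10_000, seed: int = 0) -> TopologyTestResult:
    """Full test battery over candidate topologies.

    ``sitelh`` holds the per-site log-likelihoods of every candidate under its
    maximized branch lengths; ``trees`` maps each label to its (branch-length
    optimized or bare) topology so consensus degrees of freedom and the
    Bonferroni A can be derived. The best topology (highest total lnL) is
    compared against every alternative; flags mark rejections at ``alpha``.
    """
    labels = sitelh.labels
    if len(labels) < 2:
        raise TopoTestError("battery needs at least two topologies")
    missing = [l for l in labels if l not in trees]
    if missing:
        raise TopoTestError(f"no tree supplied for: {missing}")
    totals = sitelh.values.sum(axis=1)
    best_i = int(np.argmax(totals))
    best = labels[best_i]
    au = {res.label: res for res in au_test(sitelh, scales, B, seed)}
    rows = []
    for i, label in enumerate(labels):
        delta = float(totals[best_i] - totals[i])
        if i == best_i:
            rows.append({"topology": label, "lnL": totals[i], "delta_lnL": 0.0,
                         "LRS": 0.0, "df": 0, "A": 1, "p_chisq": 1.0,
                         "p_bonferroni": 1.0, "p_AU": au[label].p_au,
                         "rejected_chisq": False, "rejected_AU": False})
            continue
        res = lrs_chisq_test(totals[best_i], totals[i],
                             trees[best], trees[label])
        A = count_binary_resolutions(res["consensus"].tree)
        p_bonf = bonferroni_correct(res["p"], A)
        rows.append({"topology": label, "lnL": totals[i], "delta_lnL": delta,
                     "LRS": res["LRS"], "df": res["df"], "A": A,
                     "p_chisq": res["p"], "p_bonferroni": p_bonf,
                     "p_AU": au[label].p_au,
                     "rejected_chisq": p_bonf < alpha,
                     "rejected_AU": au[label].p_au < alpha})
    table = pd.DataFrame(rows).sort_values("delta_lnL").reset_index(drop=True)
    return TopologyTestResult(table, best)


def run_battery_from_alignment(aln, topologies: dict, model,
                               alpha: float = 0.05, scales=DEFAULT_SCALES,
                               B: int = 10_000, seed: int = 0,
                               ) -> TopologyTestResult:
    """Convenience wrapper: optimize branch lengths for every candidate
    topology, collect per-site log-likelihoods, and run the battery."""
    from . import phylolik as _pl
    rows, fitted = [], {}
    for label, topo in topologies.items():
        tree, _ = _pl.optimize_branch_lengths(aln, topo, model)
        rows.append(_pl.site_log_likelihoods(aln, tree, model))
        fitted[label] = tree
    mat = SiteLikelihoodMatrix(list(topologies), np.vstack(rows))
    return run_battery(mat, fitted, alpha=alpha, scales=scales, B=B,
                       seed=seed)
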