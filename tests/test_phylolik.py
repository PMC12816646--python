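import itertools

import numpy as np
import pytest

from leptokit import phylolik, synthdata, treeops
from leptokit.align import Alignment
from leptokit.phylolik import (LikelihoodError, SiteLikelihoodMatrix,
                               SiteProfileSet, discrete_gamma_rates,
                               load_model, optimize_branch_lengths,
                               read_sitelh, site_log_likelihoods,
                               total_log_likelihood, write_sitelh)


class TestSubstModel:
    @pytest.mark.parametrize("name", ["LG", "cpREV", "POISSON"])
    def test_rows_sum_to_one(self, name):
        m = load_model(name)
        for t in (0.01, 0.5, 3.0):
            P = m.transition_matrix(t)
            assert np.abs(P.sum(axis=1) - 1).max() < 1e-10

    def test_zero_time_is_identity(self):
        assert np.array_equal(load_model("LG").transition_matrix(0.0),
                              np.eye(20))

    @pytest.mark.parametrize("name", ["LG", "cpREV"])
    def test_time_reversibility(self, name):
        m = load_model(name)
        P = m.transition_matrix(0.7)
        F = m.frequencies[:, None] * P
        assert np.abs(F - F.T).max() < 1e-10

    def test_rate_matrix_scaled_to_one_substitution(self):
        m = load_model("LG")
        assert -(m.frequencies * np.diag(m.Q)).sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("alpha,m", [(0.2, 4), (1.0, 4), (5.0, 8), (0.8, 1)])
    def test_discrete_gamma_mean_one(self, alpha, m):
        rates = discrete_gamma_rates(alpha, m)
        assert rates.mean() == pytest.approx(1.0, abs=1e-12)
        assert (np.diff(rates) >= 0).all()


class TestSiteLikelihoods:
    def test_identical_pair_zero_length(self, poisson):
        aln = Alignment.from_sequences({"A": "AR", "B": "AR"})
        tree = treeops.read_newick("(A:0.0,B:0.0);")
        v = site_log_likelihoods(aln, tree, poisson)
        assert np.allclose(v, -np.log(20))

    def test_impossible_pattern_minus_inf(self, poisson):
        aln = Alignment.from_sequences({"A": "A", "B": "R"})
        tree = treeops.read_newick("(A:0.0,B:0.0);")
        assert site_log_likelihoods(aln, tree, poisson)[0] == -np.inf

    def test_gaps_are_missing_data(self, poisson):
        # a taxon of all gaps contributes nothing: lnL equals the 2-taxon value
        a2 = Alignment.from_sequences({"A": "AR", "B": "AN"})
        t2 = treeops.read_newick("(A:0.1,B:0.2);")
        a3 = Alignment.from_sequences({"A": "AR", "B": "AN", "C": "--"})
        t3 = treeops.read_newick("((A:0.1,B:0.2):0.3,C:0.5);")
        v2 = site_log_likelihoods(a2, t2, poisson)
        v3 = site_log_likelihoods(a3, t3, poisson)
        assert np.allclose(v2, v3, atol=1e-10)

    def test_pruning_matches_exhaustive_state_sum(self, lg_g4):
        tree = treeops.read_newick("((A:0.2,B:0.3):0.1,C:0.4);")
        aln = Alignment.from_sequences({"A": "AR", "B": "AN", "C": "RN"})
        got = site_log_likelihoods(aln, tree, lg_g4)
        idx = {c: i for i, c in enumerate(lg_g4.alphabet)}
        pi = lg_g4.frequencies
        for s in range(aln.n_sites):
            states = [idx[aln.matrix[t, s]] for t in range(3)]
            tot = 0.0
            for r in lg_g4.category_rates():
                Pa = lg_g4.transition_matrix(0.2, r)
                Pb = lg_g4.transition_matrix(0.3, r)
                Pr = lg_g4.transition_matrix(0.1, r)
                Pc = lg_g4.transition_matrix(0.4, r)
                for x in range(20):          # root state
                    for y in range(20):      # internal node state
                        tot += (pi[x] * Pr[x, y] * Pa[y, states[0]]
                                * Pb[y, states[1]] * Pc[x, states[2]]
                                ) / len(lg_g4.category_rates())
            assert got[s] == pytest.approx(np.log(tot), rel=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_pruning_matches_brute_force_random_trees(self, seed):
        """Exhaustive internal-state summation oracle on 4-5 leaf trees,
        using a small alphabet so the sum is cheap."""
        rng = np.random.default_rng(seed)
        k = 4
        S = np.zeros((k, k))
        iu = np.triu_indices(k, 1)
        vals = rng.uniform(0.2, 2.0, len(iu[0]))
        S[iu] = vals
        S += S.T
        pi = rng.dirichlet(np.ones(k))
        model = phylolik.SubstModel("ABCD", S, pi, gamma_shape=0.5, n_cats=2)
        n_leaves = rng.integers(4, 6)
        labels = [f"L{i}" for i in range(n_leaves)]
        nwk = _random_binary_newick(labels, rng)
        tree = treeops.read_newick(nwk)
        seqs = {lab: "".join(rng.choice(list("ABCD"), 3)) for lab in labels}
        aln = Alignment.from_sequences(seqs, alphabet="ABCD")
        got = site_log_likelihoods(aln, tree, model)
        want = _brute_force_lnl(aln, tree, model)
        assert np.allclose(got, want, rtol=1e-9)

    def test_rerooting_invariance(self, lg_g4, six_taxon_tree):
        aln, _ = synthdata.sim_alignment(six_taxon_tree, lg_g4, 50, seed=2)
        base = total_log_likelihood(aln, six_taxon_tree, lg_g4)
        rerooted = six_taxon_tree.clone(depth=1)
        edge = [e for e in rerooted.preorder_edge_iter()
                if e.length is not None][3]
        rerooted.reroot_at_edge(edge, length1=edge.length / 2,
                                length2=edge.length / 2)
        assert total_log_likelihood(aln, rerooted, lg_g4) == pytest.approx(
            base, abs=1e-8)

    def test_site_profiles_override_frequencies(self, poisson):
        aln = Alignment.from_sequences({"A": "AA", "B": "AA"})
        tree = treeops.read_newick("(A:0.0,B:0.0);")
        prof = np.zeros((1, 20))
        prof[0, 0] = 1.0  # all mass on 'A'
        sps = SiteProfileSet(prof, np.zeros(2, dtype=int))
        v = site_log_likelihoods(aln, tree, poisson, profiles=sps)
        assert np.allclose(v, 0.0)  # likelihood 1 at both sites

    def test_taxon_mismatch_rejected(self, poisson):
        aln = Alignment.from_sequences({"A": "A", "B": "R"})
        tree = treeops.read_newick("(A:0.1,C:0.1);")
        with pytest.raises(LikelihoodError, match="match"):
            site_log_likelihoods(aln, tree, poisson)


class TestTotals:
    def test_total_is_sum_of_sites(self, lg_g4, six_taxon_tree):
        aln, _ = synthdata.sim_alignment(six_taxon_tree, lg_g4, 30, seed=9)
        v = site_log_likelihoods(aln, six_taxon_tree, lg_g4)
        assert total_log_likelihood(aln, six_taxon_tree, lg_g4) == \
            pytest.approx(v.sum())


class TestBranchOptimization:
    def test_identical_sequences_shrink_to_zero(self, poisson):
        aln = Alignment.from_sequences({"A": "ARNDC" * 10, "B": "ARNDC" * 10})
        tree = treeops.read_newick("(A:0.1,B:0.1);")
        fit, _ = optimize_branch_lengths(aln, tree, poisson)
        total = sum(lf.edge.length for lf in fit.leaf_node_iter())
        assert total < 1e-4

    def test_lnl_not_below_init(self, lg_g4, six_taxon_tree):
        aln, _ = synthdata.sim_alignment(six_taxon_tree, lg_g4, 200, seed=4)
        init = six_taxon_tree.clone(depth=1)
        for e in init.preorder_edge_iter():
            if e.length is not None:
                e.length = 0.1
        lnl0 = total_log_likelihood(aln, init, lg_g4)
        _, lnl = optimize_branch_lengths(aln, six_taxon_tree, lg_g4)
        assert lnl >= lnl0

    def test_simulation_recovery(self, lg_g4, six_taxon_tree):
        aln, _ = synthdata.sim_alignment(six_taxon_tree, lg_g4, 5000, seed=42)
        fit, _ = optimize_branch_lengths(aln, six_taxon_tree, lg_g4)
        true = _edge_lengths_by_clade(six_taxon_tree)
        est = _edge_lengths_by_clade(fit)
        rel = [abs(est[k] - true[k]) / true[k] for k in true]
        assert np.median(rel) < 0.15


class TestSitelhIO:
    def test_round_trip(self, tmp_path):
        mat = SiteLikelihoodMatrix(["t1", "t2"],
                                   [[-1.5, -2.25e-3, -30.1, -4],
                                    [-1.0, -2.0, -3.0, -4.123456789]])
        p = tmp_path / "x.sitelh"
        write_sitelh(mat, p)
        back = read_sitelh(p)
        assert back.labels == mat.labels
        assert np.allclose(back.values, mat.values, rtol=1e-10)

    def test_header_row_shape(self, tmp_path):
        p = tmp_path / "x.sitelh"
        p.write_text("2 4\nt1 -1 -2 -3 -4\nt2 -1 -2 -3 -4\n")
        mat = read_sitelh(p)
        assert mat.values.shape == (2, 4)

    def test_short_row_rejected(self, tmp_path):
        p = tmp_path / "x.sitelh"
        p.write_text("2 4\nt1 -1 -2 -3\nt2 -1 -2 -3 -4\n")
        with pytest.raises(LikelihoodError, match="values"):
            read_sitelh(p)


def _random_binary_newick(labels, rng):
    items = [lab for lab in labels]
    rng.shuffle(items)
    while len(items) > 3:
        a, b = items.pop(), items.pop()
        t = rng.uniform(0.05, 0.5)
        items.insert(0, f"({a}:{rng.uniform(0.05, 0.5):.3f},"
                        f"{b}:{rng.uniform(0.05, 0.5):.3f}):{t:.3f}")
        rng.shuffle(items)
    branches = ",".join(f"{x}:{rng.uniform(0.05, 0.5):.3f}"
                        if "(" not in x else x for x in items)
    return f"({branches});"


def _brute_force_lnl(aln, tree, model):
    """Sum over all internal-node state assignments — independent oracle."""
    nodes = list(tree.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    idx = {c: i for i, c in enumerate(model.alphabet)}
    k = model.k
    rates = model.category_rates()
    out = np.zeros(aln.n_sites)
    for s in range(aln.n_sites):
        site_lik = 0.0
        for r in rates:
            P = {n: model.transition_matrix(n.edge.length or 0.0, r)
                 for n in nodes if n.parent_node is not None}
            for assign in itertools.product(range(k), repeat=len(internals)):
                state = dict(zip(internals, assign))
                for n in nodes:
                    if n.is_leaf():
                        state[n] = idx[aln.matrix[
                            aln.taxa.index(n.taxon.label), s]]
                lik = model.frequencies[state[nodes[-1]]]
                for n in nodes:
                    if n.parent_node is not None:
                        lik *= P[n][state[n.parent_node], state[n]]
                site_lik += lik / len(rates)
        out[s] = np.log(site_lik)
    return out


def _edge_lengths_by_clade(tree):
    return {frozenset(l.taxon.label for l in nd.leaf_iter()): nd.edge.length
            for nd in tree.postorder_node_iter()
            if nd.parent_node is not None}
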