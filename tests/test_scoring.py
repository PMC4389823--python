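"""Network scoring: quadrature oracles for the family marginal, score
equivalence across Markov classes, decomposability, conjugate posteriors."""

from itertools import product

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from apoptonet.dags import make_dag
from apoptonet.scoring import (
    FamilyScorer,
    GaussianPrior,
    ScoredNetwork,
    family_log_marginal,
    fit_local_params,
    log_posterior_odds,
    network_score,
)


def quadrature_log_marginal(y, P, prior):
    """Independent oracle: integrate coefficients via the Gaussian-marginal
    identity y | s2 ~ N(Z m0, s2 (I + Z V0 Z')), then 1-D quadrature over
    the Inverse-Gamma noise-variance prior."""
    y = np.asarray(y, dtype=float)
    k = 0 if P is None else np.atleast_2d(P).shape[0]
    Z = np.column_stack([np.ones(y.size)] + ([] if k == 0 else [np.atleast_2d(P).T]))
    m0, lam0, a, b = prior.family_nig(k)
    V0 = np.diag(1.0 / lam0)
    shape = np.eye(y.size) + Z @ V0 @ Z.T

    def integrand(s2):
        return stats.multivariate_normal.pdf(y, mean=Z @ m0, cov=s2 * shape) * \
            stats.invgamma.pdf(s2, a, scale=b)

    val, _ = integrate.quad(integrand, 0, np.inf, limit=400)
    return np.log(val)


def dblquad_log_marginal_no_parents(y, prior):
    """Fully numerical 2-D oracle over (intercept, variance), no identities."""
    y = np.asarray(y, dtype=float)
    m0, lam0, a, b = prior.family_nig(0)

    def integrand(alpha, s2):
        lik = np.prod(stats.norm.pdf(y, loc=alpha, scale=np.sqrt(s2)))
        pri_alpha = stats.norm.pdf(alpha, loc=m0[0], scale=np.sqrt(s2 / lam0[0]))
        return lik * pri_alpha * stats.invgamma.pdf(s2, a, scale=b)

    val, _ = integrate.dblquad(integrand, 1e-6, 60, -30, 30, epsabs=1e-12, epsrel=1e-10)
    return np.log(val)


def all_dags(nodes):
    """Brute-force enumeration of every labeled DAG on the given nodes."""
    pairs = [(u, v) for u in nodes for v in nodes if u != v]
    out = []
    for mask in product([0, 1], repeat=len(pairs)):
        edges = [p for p, m in zip(pairs, mask) if m]
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        if nx.is_directed_acyclic_graph(g):
            out.append(g)
    return out


def equivalence_key(g):
    """Brute-force Markov-class key: skeleton + immoralities."""
    skel = frozenset(frozenset(e) for e in g.edges)
    vs = set()
    for c in g.nodes:
        pa = sorted(g.predecessors(c))
        for i in range(len(pa)):
            for j in range(i + 1, len(pa)):
                a, b = pa[i], pa[j]
                if not (g.has_edge(a, b) or g.has_edge(b, a)):
                    vs.add((a, c, b))
    return (skel, frozenset(vs))


class TestFamilyLogMarginal:
    @pytest.mark.parametrize("k", [0, 1, 2, 3])
    def test_matches_quadrature_oracle(self, k):
        rng = np.random.default_rng(10 + k)
        prior = GaussianPrior(nu=1.3, a0=1.7, b0=0.8)
        y = rng.standard_normal(6)
        P = None if k == 0 else rng.standard_normal((k, 6))
        got = family_log_marginal(y, P, prior)
        want = quadrature_log_marginal(y, P, prior)
        assert got == pytest.approx(want, rel=1e-6)

    def test_no_parent_case_against_full_2d_quadrature(self):
        rng = np.random.default_rng(1)
        prior = GaussianPrior()
        y = rng.standard_normal(5)
        got = family_log_marginal(y, None, prior)
        want = dblquad_log_marginal_no_parents(y, prior)
        assert got == pytest.approx(want, rel=1e-6)

    def test_single_observation_at_prior_mean(self):
        prior = GaussianPrior(mean=0.0)
        y = np.array([0.0])
        got = family_log_marginal(y, None, prior)
        want = quadrature_log_marginal(y, None, prior)
        assert got == pytest.approx(want, rel=1e-8)

    def test_duplicating_rows_decreases_log_density(self):
        rng = np.random.default_rng(2)
        prior = GaussianPrior()
        y = rng.standard_normal(8)
        P = rng.standard_normal((1, 8))
        once = family_log_marginal(y, P, prior)
        twice = family_log_marginal(np.tile(y, 2), np.tile(P, 2), prior)
        assert twice < once

    def test_rejects_non_finite_and_empty(self):
        prior = GaussianPrior()
        with pytest.raises(ValueError, match="non-finite"):
            family_log_marginal(np.array([1.0, np.nan]), None, prior)
        with pytest.raises(ValueError):
            family_log_marginal(np.array([]), None, prior)
        with pytest.raises(ValueError, match="samples"):
            family_log_marginal(np.ones(4), np.ones((1, 3)), prior)


class TestNetworkScore:
    def test_empty_dag_sums_univariate_marginals(self, independent_data):
        prior = GaussianPrior()
        g = make_dag(["A", "B"])
        net = network_score(g, independent_data, prior, center=False)
        for node in "AB":
            direct = family_log_marginal(
                independent_data.loc[node].to_numpy(), None, prior
            )
            assert net.family_scores[node] == pytest.approx(direct, rel=1e-12)
        assert net.score == pytest.approx(sum(net.family_scores.values()))

    def test_likelihood_equivalence_two_nodes(self, independent_data):
        g1 = make_dag("AB", [("A", "B")])
        g2 = make_dag("AB", [("B", "A")])
        s1 = network_score(g1, independent_data).score
        s2 = network_score(g2, independent_data).score
        assert s1 == pytest.approx(s2, rel=1e-8)

    def test_equivalence_classes_on_all_three_node_dags(self, chain_data):
        dags = all_dags(["X", "Y", "Z"])
        assert len(dags) == 25
        scores = {}
        for g in dags:
            key = equivalence_key(g)
            s = network_score(g, chain_data).score
            scores.setdefault(key, []).append(s)
        assert len(scores) == 11  # Markov classes on 3 nodes
        for vals in scores.values():
            assert max(vals) - min(vals) <= 1e-8 * max(1.0, abs(vals[0]))

    def test_decomposability_exact(self, chain_data):
        prior = GaussianPrior()
        g1 = make_dag("XYZ", [("X", "Y")])
        g2 = make_dag("XYZ", [("X", "Y"), ("Y", "Z")])
        n1 = network_score(g1, chain_data, prior)
        n2 = network_score(g2, chain_data, prior)
        # only Z's family changed
        assert n1.family_scores["X"] == n2.family_scores["X"]
        assert n1.family_scores["Y"] == n2.family_scores["Y"]
        assert n2.score - n1.score == pytest.approx(
            n2.family_scores["Z"] - n1.family_scores["Z"], rel=1e-12
        )

    def test_missing_node_named_in_error(self, independent_data):
        g = make_dag(["A", "QQ"])
        with pytest.raises(KeyError, match="QQ"):
            network_score(g, independent_data)

    def test_total_invariant_enforced(self):
        g = make_dag("A")
        with pytest.raises(ValueError, match="sum of family scores"):
            ScoredNetwork(dag=g, family_scores={"A": -1.0}, score=5.0)


class TestLogPosteriorOdds:
    def test_identical_structures_give_zero(self, chain_data):
        g = make_dag("XYZ", [("X", "Y")])
        assert log_posterior_odds(g, g.copy(), chain_data) == 0.0

    def test_markov_equivalent_pair_gives_zero(self, chain_data):
        g1 = make_dag("XYZ", [("X", "Y"), ("Y", "Z")])
        g2 = make_dag("XYZ", [("Y", "X"), ("Y", "Z")])
        assert log_posterior_odds(g1, g2, chain_data) == pytest.approx(0.0, abs=1e-7)

    def test_true_skeleton_beats_empty_on_chain_data(self, chain_data):
        g1 = make_dag("XYZ", [("X", "Y"), ("Y", "Z")])
        g0 = make_dag("XYZ")
        assert log_posterior_odds(g1, g0, chain_data) > 0

    def test_node_set_mismatch(self, chain_data):
        with pytest.raises(ValueError, match="node sets"):
            log_posterior_odds(make_dag("XY"), make_dag("XZ"), chain_data)


class TestFitLocalParams:
    def test_zero_observations_return_prior(self):
        prior = GaussianPrior(nu=2.0, a0=3.0, b0=4.0)
        model = fit_local_params(np.array([]), None, prior)
        assert model.intercept == 0.0
        assert model.a_n == 3.0 and model.b_n == 4.0
        assert model.sigma2 == pytest.approx(4.0 / 2.0)
        assert model.log_marginal == 0.0

    def test_consistency_on_noiseless_linear_child(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(5000)
        y = 2.0 * x
        model = fit_local_params(y, x[None, :], GaussianPrior(), parent_names=("x",))
        assert model.coefficients["x"] == pytest.approx(2.0, abs=1e-3)
        assert model.sigma2 < 1e-2

    def test_sampling_mode_agrees_with_closed_form(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(20)
        y = 1.5 * x + rng.standard_normal(20)
        n_draws = 20_000
        model, theta, sigma2 = fit_local_params(
            y, x[None, :], GaussianPrior(), n_draws=n_draws, seed=0
        )
        for j in range(2):
            mc_se = theta[:, j].std() / np.sqrt(n_draws)
            assert abs(theta[:, j].mean() - model.posterior_mean[j]) < 3 * mc_se
        mc_se = sigma2.std() / np.sqrt(n_draws)
        assert abs(sigma2.mean() - model.sigma2) < 3 * mc_se


def test_family_scorer_caches_and_counts(chain_data):
    scorer = FamilyScorer(chain_data, GaussianPrior())
    a = scorer.family_score("Y", frozenset({"X"}))
    b = scorer.family_score("Y", frozenset({"X"}))
    assert a == b and scorer.n_family_evals == 1


def test_prior_validation():
    with pytest.raises(ValueError):
        GaussianPrior(nu=0.0)
    with pytest.raises(ValueError):
        GaussianPrior(a0=-1.0)
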