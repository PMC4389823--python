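"""Bayesian scoring of Gaussian networks.

Each node of a directed acyclic graph follows a conditional linear Gaussian
model: given its parents, the node is normal with mean linear in the parent
values and homoscedastic noise.  With a conjugate Normal-Inverse-Gamma (NIG)
prior on the regression parameters of every family the marginal likelihood
of the data given a structure integrates in closed form, and the network
score is the sum of per-family log marginal likelihoods.

Score (likelihood) equivalence -- Markov-equivalent DAGs receiving identical
scores -- does *not* hold for an arbitrary NIG prior repeated across
families.  Here the family priors are derived as conditionals of a single
global Normal-Inverse-Wishart prior over all variables (mean 0, equivalent
sample size ``nu``, scale ``2*b0`` times the identity):  a family with ``k``
parents receives intercept precision ``nu``, slope precision ``2*b0``,
noise-variance shape ``a0 + k/2`` and scale ``b0``.  Every family score is
then still an ordinary NIG regression marginal, while the total score
depends on the structure only through its Markov equivalence class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import gammaln

from .dags import check_dag

__all__ = [
    "GaussianPrior",
    "LocalGaussianModel",
    "ScoredNetwork",
    "FamilyScorer",
    "family_log_marginal",
    "network_score",
    "log_posterior_odds",
    "fit_local_params",
]


@dataclass(frozen=True)
class GaussianPrior:
    """Hyperparameters of the conjugate prior shared by all families.

    Parameters
    ----------
    mean
        Prior mean for the intercept and every regression coefficient.
        Values other than 0 break exact score equivalence and should only
        be used for sensitivity analyses.
    nu
        Equivalent sample size: prior precision of the intercept relative
        to the noise variance.
    a0, b0
        Shape and scale of the Inverse-Gamma prior on the noise variance of
        a parentless node.  A family with ``k`` parents uses shape
        ``a0 + k/2`` and the same scale (the consistency adjustment coming
        from the global Normal-Inverse-Wishart construction); its slope
        precision is ``2*b0``.
    """

    mean: float = 0.0
    nu: float = 1.0
    a0: float = 1.0
    b0: float = 1.0

    def __post_init__(self):
        for name in ("nu", "a0", "b0"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")

    def family_nig(self, k: int) -> tuple[np.ndarray, np.ndarray, float, float]:
        """Derived NIG hyperparameters for a family with ``k`` parents.

        Returns ``(m0, lam0, a, b)`` where ``m0`` is the prior mean vector
        for (intercept, k slopes), ``lam0`` the diagonal of the prior
        precision matrix (relative to the noise variance), and ``(a, b)``
        the Inverse-Gamma shape and scale of the noise variance.
        """
        if k < 0:
            raise ValueError("parent count must be >= 0")
        m0 = np.full(k + 1, float(self.mean))
        lam0 = np.concatenate(([self.nu], np.full(k, 2.0 * self.b0)))
        return m0, lam0, self.a0 + 0.5 * k, self.b0


@dataclass
class LocalGaussianModel:
    """Posterior summary of one node's conditional linear Gaussian model."""

    node: str
    parents: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]
    sigma2: float
    log_marginal: float
    # full conjugate posterior, for the optional sampling mode
    posterior_mean: np.ndarray = field(repr=False, default=None)
    posterior_precision: np.ndarray = field(repr=False, default=None)
    a_n: float = 0.0
    b_n: float = 0.0


@dataclass
class ScoredNetwork:
    """A DAG with its per-family and total log marginal likelihood."""

    dag: nx.DiGraph
    family_scores: dict[str, float]
    score: float

    def __post_init__(self):
        total = sum(self.family_scores.values())
        scale = max(1.0, abs(total))
        if abs(total - self.score) > 1e-9 * scale:
            raise ValueError("total score does not equal the sum of family scores")


def _nig_posterior(y: np.ndarray, Z: np.ndarray, m0, lam0, a, b):
    """Conjugate update for y = Z @ theta + noise; lam0 is a diagonal."""
    n = y.shape[0]
    Lam0 = np.diag(lam0)
    Lam_n = Lam0 + Z.T @ Z
    rhs = lam0 * m0 + Z.T @ y
    chol = cho_factor(Lam_n, lower=True)
    m_n = cho_solve(chol, rhs)
    a_n = a + 0.5 * n
    b_n = b + 0.5 * (y @ y + m0 @ (lam0 * m0) - m_n @ (Lam_n @ m_n))
    logdet0 = float(np.sum(np.log(lam0)))
    logdet_n = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
    return m_n, Lam_n, a_n, b_n, logdet0, logdet_n


def _nig_log_marginal(y: np.ndarray, Z: np.ndarray, m0, lam0, a, b) -> float:
    n = y.shape[0]
    _, _, a_n, b_n, logdet0, logdet_n = _nig_posterior(y, Z, m0, lam0, a, b)
    return (
        -0.5 * n * math.log(2.0 * math.pi)
        + 0.5 * (logdet0 - logdet_n)
        + a * math.log(b)
        - a_n * math.log(b_n)
        + gammaln(a_n)
        - gammaln(a)
    )


def family_log_marginal(
    child: np.ndarray, parents: np.ndarray | None, prior: GaussianPrior
) -> float:
    """Log marginal likelihood of one family's linear regression.

    Parameters
    ----------
    child
        Observations of the child node, shape ``(n,)``.
    parents
        Parent observations, shape ``(k, n)`` (one row per parent), or
        ``None`` / empty for a parentless node.
    prior
        Shared prior; the family's NIG hyperparameters are derived from it
        via :meth:`GaussianPrior.family_nig`.
    """
    y = np.asarray(child, dtype=float).ravel()
    if y.size < 1:
        raise ValueError("need at least one observation")
    if parents is None:
        P = np.empty((0, y.size))
    else:
        P = np.atleast_2d(np.asarray(parents, dtype=float))
    if P.shape[0] and P.shape[1] != y.size:
        raise ValueError(
            f"parent matrix has {P.shape[1]} samples but child has {y.size}"
        )
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(P))):
        raise ValueError("data contain non-finite values")
    k = P.shape[0]
    Z = np.column_stack([np.ones(y.size), P.T])
    m0, lam0, a, b = prior.family_nig(k)
    return _nig_log_marginal(y, Z, m0, lam0, a, b)


class FamilyScorer:
    """Cached family scores over one dataset via Gram-matrix statistics.

    Precomputes the cross-product matrix of (intercept, all genes) once;
    any family's NIG marginal then needs only a small submatrix.  Scores
    are cached by ``(node, parent frozenset)``, which together with score
    decomposability makes hill climbing and bootstrapping tractable.
    """

    def __init__(self, data: pd.DataFrame, prior: GaussianPrior, center: bool = True):
        if not isinstance(data, pd.DataFrame):
            raise TypeError("data must be a DataFrame (genes x samples)")
        if data.shape[1] < 1:
            raise ValueError("need at least one sample")
        X = data.to_numpy(dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("data contain non-finite values")
        if center:
            X = X - X.mean(axis=1, keepdims=True)
        self.nodes: tuple[str, ...] = tuple(str(i) for i in data.index)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("row ids must be unique")
        self._index = {g: i + 1 for i, g in enumerate(self.nodes)}
        self.n = X.shape[1]
        A = np.vstack([np.ones((1, self.n)), X])
        self._gram = A @ A.T
        self.prior = prior
        self._cache: dict[tuple[str, frozenset], float] = {}
        self.n_family_evals = 0

    def family_score(self, node: str, parent_set: frozenset) -> float:
        key = (node, parent_set)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        if node not in self._index:
            raise KeyError(f"node {node!r} is missing from the data")
        pa = sorted(parent_set)
        for p in pa:
            if p not in self._index:
                raise KeyError(f"node {p!r} is missing from the data")
        idx = [0] + [self._index[p] for p in pa]
        c = self._index[node]
        M = self._gram
        k = len(pa)
        m0, lam0, a, b = self.prior.family_nig(k)
        ZtZ = M[np.ix_(idx, idx)]
        Zty = M[idx, c]
        yty = M[c, c]
        Lam_n = ZtZ + np.diag(lam0)
        rhs = lam0 * m0 + Zty
        chol = cho_factor(Lam_n, lower=True)
        m_n = cho_solve(chol, rhs)
        a_n = a + 0.5 * self.n
        b_n = b + 0.5 * (yty + m0 @ (lam0 * m0) - m_n @ (Lam_n @ m_n))
        score = (
            -0.5 * self.n * math.log(2.0 * math.pi)
            + 0.5 * (float(np.sum(np.log(lam0))) - 2.0 * float(np.sum(np.log(np.diag(chol[0])))))
            + a * math.log(b)
            - a_n * math.log(b_n)
            + gammaln(a_n)
            - gammaln(a)
        )
        self._cache[key] = score
        self.n_family_evals += 1
        return score

    def score_dag(self, dag: nx.DiGraph) -> ScoredNetwork:
        fam = {
            node: self.family_score(node, frozenset(dag.predecessors(node)))
            for node in dag.nodes
        }
        return ScoredNetwork(dag=dag, family_scores=fam, score=sum(fam.values()))


def network_score(
    dag: nx.DiGraph,
    data: pd.DataFrame,
    prior: GaussianPrior | None = None,
    center: bool = True,
) -> ScoredNetwork:
    """Total Bayesian score of *dag* on *data* (genes x samples).

    The score decomposes over families: changing the parents of one node
    changes only that node's term.  Rows of *data* are mean-centered per
    gene by default before scoring.
    """
    prior = prior or GaussianPrior()
    check_dag(dag)
    missing = [n for n in dag.nodes if n not in data.index]
    if missing:
        raise KeyError(f"dag nodes missing from the data: {missing}")
    if data.shape[1] < 3:
        raise ValueError("need at least 3 samples to score a network")
    scorer = FamilyScorer(data.loc[list(dag.nodes)], prior, center=center)
    return scorer.score_dag(dag)


def log_posterior_odds(
    g1: nx.DiGraph,
    g2: nx.DiGraph,
    data: pd.DataFrame,
    prior: GaussianPrior | None = None,
    center: bool = True,
) -> float:
    """Log posterior odds of g1 over g2 under a uniform structure prior.

    With equal structure priors the odds reduce to the Bayes factor, i.e.
    the difference of network scores.
    """
    if set(g1.nodes) != set(g2.nodes):
        raise ValueError("the two DAGs are over different node sets")
    s1 = network_score(g1, data, prior, center=center)
    s2 = network_score(g2, data, prior, center=center)
    return s1.score - s2.score


def fit_local_params(
    child: np.ndarray,
    parents: np.ndarray | None,
    prior: GaussianPrior | None = None,
    parent_names: tuple[str, ...] = (),
    node: str = "child",
    n_draws: int = 0,
    seed: int | None = None,
) -> LocalGaussianModel | tuple[LocalGaussianModel, np.ndarray, np.ndarray]:
    """Conjugate posterior of one family's regression parameters.

    With ``n_draws > 0`` also returns Monte-Carlo draws from the exact
    Normal-Inverse-Gamma posterior (an MCMC-free sampling mode kept for
    cross-checking the closed form): ``(model, theta_draws, sigma2_draws)``
    where ``theta_draws`` has one row per draw, columns (intercept, slopes).
    Zero observations are allowed and return the prior itself.
    """
    prior = prior or GaussianPrior()
    y = np.asarray(child, dtype=float).ravel()
    if parents is None:
        P = np.empty((0, y.size))
    else:
        P = np.atleast_2d(np.asarray(parents, dtype=float))
        if P.size == 0:
            P = np.empty((0, y.size))
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(P))):
        raise ValueError("data contain non-finite values")
    k = P.shape[0]
    if parent_names and len(parent_names) != k:
        raise ValueError("parent_names length does not match the parent matrix")
    names = tuple(parent_names) if parent_names else tuple(f"parent{i}" for i in range(k))
    Z = np.column_stack([np.ones(y.size), P.T]) if y.size else np.empty((0, k + 1))
    m0, lam0, a, b = prior.family_nig(k)
    if y.size == 0:
        m_n, Lam_n, a_n, b_n = m0, np.diag(lam0), a, b
        logml = 0.0
    else:
        m_n, Lam_n, a_n, b_n, _, _ = _nig_posterior(y, Z, m0, lam0, a, b)
        logml = _nig_log_marginal(y, Z, m0, lam0, a, b)
    sigma2 = b_n / (a_n - 1.0) if a_n > 1.0 else float("nan")
    model = LocalGaussianModel(
        node=node,
        parents=names,
        intercept=float(m_n[0]),
        coefficients={nm: float(c) for nm, c in zip(names, m_n[1:])},
        sigma2=float(sigma2),
        log_marginal=float(logml),
        posterior_mean=m_n,
        posterior_precision=Lam_n,
        a_n=float(a_n),
        b_n=float(b_n),
    )
    if n_draws <= 0:
        return model
    rng = np.random.default_rng(seed)
    sigma2_draws = b_n / rng.gamma(shape=a_n, scale=1.0, size=n_draws)
    cov_unit = np.linalg.inv(Lam_n)
    L = np.linalg.cholesky(cov_unit)
    z = rng.standard_normal((n_draws, k + 1))
    theta_draws = m_n + (z @ L.T) * np.sqrt(sigma2_draws)[:, None]
    return model, theta_draws, sigma2_draws
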