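"""Scikit-learn-style estimators over the package's core machinery.

These follow the sklearn contract -- constructor parameters stored
verbatim, ``fit`` returning ``self``, fitted attributes with a trailing
underscore, ``get_params``/``set_params`` inherited from
:class:`~sklearn.base.BaseEstimator` -- so they compose with pipelines and
model selection.  Input ``X`` uses the sklearn orientation (samples x
genes); DataFrames keep their column names as gene labels.

- :class:`ModeratedTTest`: pooled two-group differential expression with
  empirical-Bayes variance moderation and Bonferroni adjustment.
- :class:`GaussianBayesianNetwork`: single best DAG by Bayesian-score hill
  climbing with random restarts.
- :class:`BootstrapConsensus`: bootstrap model averaging of
  :class:`GaussianBayesianNetwork` fits with edge-confidence thresholding.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import consensus as _consensus
from . import diffexpr as _diffexpr
from .datasets import SampleDesign
from .scoring import GaussianPrior
from .search import hill_climb

__all__ = ["ModeratedTTest", "GaussianBayesianNetwork", "BootstrapConsensus"]


def _as_frame(X, transpose: bool = True) -> pd.DataFrame:
    """samples x genes input -> genes x samples DataFrame with labels."""
    if isinstance(X, pd.DataFrame):
        df = X.T if transpose else X.copy()
        df.index = [str(i) for i in df.index]
        return df
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    arr = X.T if transpose else X
    genes = [f"g{i}" for i in range(arr.shape[0])]
    cols = [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=genes, columns=cols)


class ModeratedTTest(BaseEstimator):
    """Empirical-Bayes moderated two-group t-test as a feature scorer.

    Parameters
    ----------
    alpha : float, default 0.05
        Adjusted-p threshold used by :meth:`get_support` and
        :meth:`signature`.
    m : int or None
        Bonferroni multiplier; defaults to the number of tested features.

    Attributes
    ----------
    logfc_, s2_, s2_post_, t_, pvalue_, adjusted_pvalue_ : ndarray per gene
    df_residual_ : float
    df_prior_, s2_prior_ : float
        The estimated moderation hyperparameters (d0, s0^2).
    feature_names_in_ : ndarray of gene labels
    """

    def __init__(self, alpha: float = 0.05, m: int | None = None):
        self.alpha = alpha
        self.m = m

    def fit(self, X, y):
        """Fit on X (samples x genes) and group labels y.

        ``y`` may be the strings {"control", "perturbed"} or {0, 1}
        (1 = perturbed).
        """
        expr = _as_frame(X)
        y = np.asarray(y)
        if y.shape[0] != expr.shape[1]:
            raise ValueError("y length does not match the number of samples")
        labels = np.where(
            np.isin(y, ["control", "perturbed"]), y,
            np.where(y.astype(str) == "1", "perturbed", "control"),
        )
        design = SampleDesign(tuple(expr.columns), tuple(labels))
        fit = _diffexpr.fit_group_model(expr, design)
        hyper = _diffexpr.estimate_eb_hyperparams(
            fit["s2"].to_numpy(), float(fit["df"].iloc[0])
        )
        tab = _diffexpr.moderated_t(
            fit, hyper, len(design.control_ids), len(design.perturbed_ids)
        )
        tab["adjusted_p"] = _diffexpr.bonferroni(tab["p"].to_numpy(), self.m)
        self.feature_names_in_ = np.asarray(expr.index)
        self.n_features_in_ = expr.shape[0]
        self.logfc_ = tab["logfc"].to_numpy()
        self.s2_ = tab["s2"].to_numpy()
        self.s2_post_ = tab["s2_post"].to_numpy()
        self.t_ = tab["t"].to_numpy()
        self.pvalue_ = tab["p"].to_numpy()
        self.adjusted_pvalue_ = tab["adjusted_p"].to_numpy()
        self.df_residual_ = float(tab["df"].iloc[0])
        self.df_prior_ = hyper.d0
        self.s2_prior_ = hyper.s02
        self._table = tab
        return self

    def get_support(self) -> np.ndarray:
        """Boolean mask of genes with adjusted p below ``alpha``."""
        check_is_fitted(self, "adjusted_pvalue_")
        return self.adjusted_pvalue_ < self.alpha

    def signature(self) -> tuple[list[str], list[str]]:
        """(upregulated, downregulated) gene lists at ``alpha``."""
        check_is_fitted(self, "adjusted_pvalue_")
        return _diffexpr.select_signature(self._table, self.alpha)

    def to_frame(self) -> pd.DataFrame:
        """The full differential-expression table, indexed by gene."""
        check_is_fitted(self, "adjusted_pvalue_")
        return self._table.copy()


class GaussianBayesianNetwork(BaseEstimator):
    """Best-scoring DAG by hill climbing over a Bayesian network score.

    Parameters mirror :func:`apoptonet.search.hill_climb` and the scoring
    prior; see :mod:`apoptonet.scoring` for the model.

    Attributes
    ----------
    dag_ : networkx.DiGraph
    score_ : float
    family_scores_ : dict node -> float
    trace_ : SearchTrace
    n_structures_ : int
    """

    def __init__(
        self,
        nu: float = 1.0,
        a0: float = 1.0,
        b0: float = 1.0,
        n_restarts: int = 2,
        edge_prob: float = 0.2,
        center: bool = True,
        random_state: int | None = 0,
    ):
        self.nu = nu
        self.a0 = a0
        self.b0 = b0
        self.n_restarts = n_restarts
        self.edge_prob = edge_prob
        self.center = center
        self.random_state = random_state

    def _prior(self) -> GaussianPrior:
        return GaussianPrior(nu=self.nu, a0=self.a0, b0=self.b0)

    def fit(self, X, y=None):
        data = _as_frame(X)
        trace = hill_climb(
            data,
            self._prior(),
            n_restarts=self.n_restarts,
            seed=self.random_state,
            center=self.center,
            edge_prob=self.edge_prob,
        )
        self.feature_names_in_ = np.asarray(data.index)
        self.n_features_in_ = data.shape[0]
        self.trace_ = trace
        self.dag_ = trace.best.dag
        self.score_ = trace.best.score
        self.family_scores_ = dict(trace.best.family_scores)
        self.n_structures_ = trace.structures_evaluated
        return self


class BootstrapConsensus(BaseEstimator):
    """Bootstrap-averaged network with confidence-thresholded edges.

    Parameters
    ----------
    n_bootstrap : int, default 200
        Number of bootstrap replicates (B).
    score_interval : float, default 0.95
        Central score interval used to filter replicates before averaging.
    edge_threshold : float, default 0.75
        Directed-confidence threshold for consensus edges (strict >).
    n_restarts, nu, a0, b0, edge_prob, center
        Passed through to the per-replicate structure search / score.

    Attributes
    ----------
    ensemble_ : BootstrapEnsemble  (all replicates)
    retained_ : BootstrapEnsemble  (after the score-interval filter)
    edge_confidence_ : EdgeConfidenceTable
    consensus_ : networkx.DiGraph with ``confidence`` edge attributes
    """

    def __init__(
        self,
        n_bootstrap: int = 200,
        score_interval: float = 0.95,
        edge_threshold: float = 0.75,
        n_restarts: int = 2,
        nu: float = 1.0,
        a0: float = 1.0,
        b0: float = 1.0,
        edge_prob: float = 0.2,
        center: bool = True,
        random_state: int | None = 0,
    ):
        self.n_bootstrap = n_bootstrap
        self.score_interval = score_interval
        self.edge_threshold = edge_threshold
        self.n_restarts = n_restarts
        self.nu = nu
        self.a0 = a0
        self.b0 = b0
        self.edge_prob = edge_prob
        self.center = center
        self.random_state = random_state

    def fit(self, X, y=None):
        data = _as_frame(X)
        prior = GaussianPrior(nu=self.nu, a0=self.a0, b0=self.b0)
        ensemble = _consensus.bootstrap_learn(
            data,
            prior,
            B=self.n_bootstrap,
            seed=self.random_state,
            n_restarts=self.n_restarts,
            center=self.center,
            edge_prob=self.edge_prob,
        )
        retained = _consensus.filter_score_interval(ensemble, self.score_interval)
        table = _consensus.edge_confidence(retained)
        self.feature_names_in_ = np.asarray(data.index)
        self.n_features_in_ = data.shape[0]
        self.ensemble_ = ensemble
        self.retained_ = retained
        self.edge_confidence_ = table
        self.consensus_ = _consensus.build_consensus(table, self.edge_threshold)
        return self
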