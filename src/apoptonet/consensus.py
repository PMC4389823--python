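"""Bootstrap model averaging of learned network structures.

A single best-scoring DAG can be unstable: small changes to the data may
change the structure substantially.  Resampling the samples with
replacement, learning one structure per replicate, filtering replicates to
a central score interval and keeping edges that appear in more than a
confidence threshold of the retained structures gives a consensus network
whose edges carry bootstrap confidence values.  Because structure learning
only identifies DAGs up to Markov equivalence, direction flips across
replicates are expected; a direction-ignoring (skeleton) confidence is
therefore reported alongside the directed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .scoring import GaussianPrior, ScoredNetwork
from .search import hill_climb

__all__ = [
    "BootstrapEnsemble",
    "EdgeConfidenceTable",
    "bootstrap_learn",
    "filter_score_interval",
    "edge_confidence",
    "build_consensus",
    "skeleton_precision_recall",
]


@dataclass
class BootstrapEnsemble:
    """Replicate networks learned on resampled datasets."""

    replicates: list[tuple[int, int, ScoredNetwork]]  # (id, search seed, network)
    n_samples: int
    nodes: tuple[str, ...]

    @property
    def scores(self) -> np.ndarray:
        return np.array([net.score for _, _, net in self.replicates])

    def __len__(self) -> int:
        return len(self.replicates)


@dataclass
class EdgeConfidenceTable:
    """Directed and skeleton (direction-ignoring) bootstrap edge frequencies."""

    directed: dict[tuple[str, str], float]
    skeleton: dict[frozenset, float]
    n_retained: int
    nodes: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "source": u,
                "target": v,
                "directed_conf": c,
                "skeleton_conf": self.skeleton[frozenset((u, v))],
            }
            for (u, v), c in sorted(self.directed.items())
        ]
        return pd.DataFrame(rows, columns=["source", "target", "directed_conf", "skeleton_conf"])


def bootstrap_learn(
    data: pd.DataFrame,
    prior: GaussianPrior | None = None,
    B: int = 200,
    seed: int | None = 0,
    n_restarts: int = 2,
    center: bool = True,
    edge_prob: float = 0.2,
) -> BootstrapEnsemble:
    """Learn one best network per bootstrap resample of the samples.

    Each replicate draws ``n`` columns of *data* with replacement and runs
    hill climbing with its own search seed; both streams derive from the
    master ``seed``, so the whole ensemble is reproducible.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if data.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    prior = prior or GaussianPrior()
    n = data.shape[1]
    values = data.to_numpy(dtype=float)
    streams = np.random.SeedSequence(seed).spawn(B)
    replicates = []
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        cols = rng.integers(0, n, size=n)
        resample = pd.DataFrame(
            values[:, cols], index=data.index,
            columns=[f"b{j}" for j in range(n)],
        )
        search_seed = int(rng.integers(2**31))
        trace = hill_climb(
            resample, prior, n_restarts=n_restarts, seed=search_seed,
            center=center, edge_prob=edge_prob,
        )
        replicates.append((r, search_seed, trace.best))
    return BootstrapEnsemble(replicates=replicates, n_samples=n, nodes=tuple(data.index))


def filter_score_interval(ensemble: BootstrapEnsemble, level: float = 0.95) -> BootstrapEnsemble:
    """Keep replicates whose score lies in the central ``level`` interval.

    The interval is the closed range between the ``(1-level)/2`` and
    ``1-(1-level)/2`` empirical quantiles (linear interpolation) of the
    replicate scores.
    """
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    if not len(ensemble):
        raise ValueError("ensemble is empty")
    scores = ensemble.scores
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(scores, [tail, 1.0 - tail])
    kept = [
        rep for rep, s in zip(ensemble.replicates, scores) if lo <= s <= hi
    ]
    return BootstrapEnsemble(replicates=kept, n_samples=ensemble.n_samples, nodes=ensemble.nodes)


def edge_confidence(ensemble: BootstrapEnsemble) -> EdgeConfidenceTable:
    """Directed and skeleton edge frequencies over the (retained) ensemble."""
    if not len(ensemble):
        raise ValueError("ensemble is empty")
    directed: dict[tuple[str, str], int] = {}
    skeleton: dict[frozenset, int] = {}
    for _, _, net in ensemble.replicates:
        for e in net.dag.edges:
            directed[e] = directed.get(e, 0) + 1
        for e in {frozenset(e) for e in net.dag.edges}:
            skeleton[e] = skeleton.get(e, 0) + 1
    B = len(ensemble)
    return EdgeConfidenceTable(
        directed={e: c / B for e, c in directed.items()},
        skeleton={e: c / B for e, c in skeleton.items()},
        n_retained=B,
        nodes=ensemble.nodes,
    )


def build_consensus(
    table: EdgeConfidenceTable,
    threshold: float = 0.75,
    strict: bool = True,
    level: str = "skeleton",
) -> nx.DiGraph:
    """Directed consensus network of edges above the confidence threshold.

    With ``level="skeleton"`` (default) a node pair enters the consensus
    when its direction-ignoring confidence exceeds ``threshold``; the kept
    edge is oriented along the higher directed confidence.  This is the
    appropriate default because structure learning only identifies DAGs up
    to Markov equivalence, so bootstrap replicates flip orientations
    within a class and split the directed frequency of a stable pair.
    With ``level="directed"`` the directed confidence itself must pass.

    In both modes the comparison is strict unless ``strict=False`` (>=),
    orientation ties go to the lexicographically smaller direction and the
    surviving edge is flagged ``tie=True``.  The result is a plain directed
    graph over the full analysis node set -- model averaging does not
    guarantee acyclicity.  Edge attributes carry both confidences.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    if level not in ("skeleton", "directed"):
        raise ValueError("level must be 'skeleton' or 'directed'")
    g = nx.DiGraph()
    g.add_nodes_from(table.nodes)

    def _passes(c: float) -> bool:
        return c > threshold if strict else c >= threshold

    if level == "skeleton":
        for pair, sk in sorted(table.skeleton.items(), key=lambda kv: sorted(kv[0])):
            if not _passes(sk):
                continue
            a, b = sorted(pair)
            c_ab = table.directed.get((a, b), 0.0)
            c_ba = table.directed.get((b, a), 0.0)
            u, v = (a, b) if c_ab >= c_ba else (b, a)
            g.add_edge(u, v, confidence=table.directed.get((u, v), 0.0),
                       skeleton_confidence=sk, tie=(c_ab == c_ba))
        return g

    passing = {e: c for e, c in table.directed.items() if _passes(c)}
    for (u, v), c in sorted(passing.items()):
        rev = passing.get((v, u))
        if rev is not None and (rev > c or (rev == c and (v, u) < (u, v))):
            continue
        g.add_edge(u, v, confidence=c,
                   skeleton_confidence=table.skeleton[frozenset((u, v))],
                   tie=(rev == c if rev is not None else False))
    return g


def skeleton_precision_recall(predicted: nx.DiGraph | nx.Graph, true_dag: nx.DiGraph) -> tuple[float, float]:
    """Precision and recall of the predicted skeleton against a true DAG's.

    Both graphs are reduced to unordered node pairs; precision is the
    fraction of predicted pairs that are true, recall the fraction of true
    pairs predicted.  An empty prediction has precision 1 by convention.
    """
    pred = {frozenset(e) for e in predicted.edges}
    true = {frozenset(e) for e in true_dag.edges}
    tp = len(pred & true)
    precision = tp / len(pred) if pred else 1.0
    recall = tp / len(true) if true else 1.0
    return precision, recall
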