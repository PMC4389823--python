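"""Hill climbing over DAG space with random restarts, and DAG counting.

The move set is the classical one: single-edge addition, deletion and
reversal, restricted to moves that keep the graph acyclic.  The search is
greedy: from the current structure every legal move is scored (score
decomposability means only one or two families change per move) and the
best strictly improving move is taken; it stops at a local optimum.  The
first restart starts from the empty graph so a baseline run is fully
reproducible; further restarts start from random DAGs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
import numpy as np
import pandas as pd

from .dags import check_dag, make_dag
from .scoring import FamilyScorer, GaussianPrior, ScoredNetwork

__all__ = [
    "SearchTrace",
    "neighbor_moves",
    "random_dag",
    "random_dag_init",
    "hill_climb",
    "count_dags",
]

_MOVE_ORDER = {"add": 0, "delete": 1, "reverse": 2}


@dataclass
class SearchTrace:
    """Record of one hill-climbing run."""

    structures_evaluated: int
    n_restarts: int
    restart_best_scores: list[float]
    moves: list[tuple[int, int, str, str, str, float]] = field(repr=False)
    best: ScoredNetwork = None

    @property
    def best_score(self) -> float:
        return self.best.score


def _legal_moves(g: nx.DiGraph) -> list[tuple[str, str, str]]:
    """All acyclicity-preserving single-edge moves, lexicographically ordered.

    Moves are ``(kind, u, v)`` with kind in {add, delete, reverse}; the
    ordering (move kind, then source, then target label) is the
    deterministic tie-break used by the climber.
    """
    nodes = sorted(g.nodes)
    moves: list[tuple[str, str, str]] = []
    for u in nodes:
        for v in nodes:
            if u == v:
                continue
            if g.has_edge(u, v):
                moves.append(("delete", u, v))
                g.remove_edge(u, v)
                ok = not nx.has_path(g, u, v)
                g.add_edge(u, v)
                if ok:
                    moves.append(("reverse", u, v))
            elif not g.has_edge(v, u):
                if not nx.has_path(g, v, u):
                    moves.append(("add", u, v))
    moves.sort(key=lambda m: (_MOVE_ORDER[m[0]], m[1], m[2]))
    return moves


def _apply_move(g: nx.DiGraph, move: tuple[str, str, str]) -> None:
    kind, u, v = move
    if kind == "add":
        g.add_edge(u, v)
    elif kind == "delete":
        g.remove_edge(u, v)
    elif kind == "reverse":
        g.remove_edge(u, v)
        g.add_edge(v, u)
    else:  # pragma: no cover
        raise ValueError(f"unknown move kind {kind!r}")


def neighbor_moves(dag: nx.DiGraph) -> list[nx.DiGraph]:
    """All DAGs one legal edge addition, deletion or reversal away."""
    check_dag(dag)
    out = []
    for move in _legal_moves(dag.copy()):
        h = dag.copy()
        _apply_move(h, move)
        out.append(h)
    return out


def random_dag(nodes, edge_prob: float, rng: np.random.Generator) -> nx.DiGraph:
    """Random DAG: random topological order + independent edge coin flips.

    Edges only run from earlier to later positions in a random permutation
    of the nodes, so acyclicity holds by construction.
    """
    nodes = list(nodes)
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError("edge_prob must be in [0, 1]")
    order = [nodes[i] for i in rng.permutation(len(nodes))]
    edges = []
    for i in range(len(order)):
        for j in range(i + 1, len(order)):
            if rng.random() < edge_prob:
                edges.append((order[i], order[j]))
    return make_dag(nodes, edges)


def random_dag_init(nodes, seed, edge_prob: float = 0.2) -> nx.DiGraph:
    """Random restart point for the climber (delegates to :func:`random_dag`)."""
    return random_dag(nodes, edge_prob, np.random.default_rng(seed))


def hill_climb(
    data: pd.DataFrame,
    prior: GaussianPrior | None = None,
    n_restarts: int = 2,
    seed: int | None = 0,
    center: bool = True,
    edge_prob: float = 0.2,
    scorer: FamilyScorer | None = None,
) -> SearchTrace:
    """Greedy DAG search maximizing the Bayesian network score.

    Parameters
    ----------
    data
        Expression matrix, genes x samples; every row becomes a node.
    prior
        Scoring prior (default :class:`GaussianPrior`).
    n_restarts
        Number of climbs; the first starts from the empty graph, the rest
        from random DAGs drawn with ``edge_prob``.
    seed
        Seeds the random restarts; the result is deterministic per seed.
    scorer
        Optional pre-built :class:`FamilyScorer` (shares its cache); used
        internally by the bootstrap loop.

    Returns
    -------
    SearchTrace
        Includes every accepted move, the number of structures scored
        (every evaluated neighbor counts, accepted or not) and the best
        :class:`ScoredNetwork` over restarts.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    prior = prior or GaussianPrior()
    if scorer is None:
        scorer = FamilyScorer(data, prior, center=center)
    nodes = list(scorer.nodes)
    rng = np.random.default_rng(seed)

    structures_evaluated = 0
    restart_best: list[float] = []
    moves_log: list[tuple[int, int, str, str, str, float]] = []
    best: ScoredNetwork | None = None

    for r in range(n_restarts):
        if r == 0:
            g = make_dag(nodes)
        else:
            g = random_dag(nodes, edge_prob, rng)
        fam = {v: scorer.family_score(v, frozenset(g.predecessors(v))) for v in nodes}
        current = sum(fam.values())
        step = 0
        while True:
            best_delta = 0.0
            best_move = None
            for move in _legal_moves(g):
                kind, u, v = move
                if kind == "reverse":
                    # both endpoint families change
                    d = (
                        scorer.family_score(v, frozenset(g.predecessors(v)) - {u})
                        - fam[v]
                        + scorer.family_score(u, frozenset(g.predecessors(u)) | {v})
                        - fam[u]
                    )
                else:
                    pa = frozenset(g.predecessors(v))
                    pa = pa | {u} if kind == "add" else pa - {u}
                    d = scorer.family_score(v, pa) - fam[v]
                structures_evaluated += 1
                if d > best_delta:
                    best_delta = d
                    best_move = move
            if best_move is None:
                break
            kind, u, v = best_move
            _apply_move(g, best_move)
            fam[v] = scorer.family_score(v, frozenset(g.predecessors(v)))
            if kind == "reverse":
                fam[u] = scorer.family_score(u, frozenset(g.predecessors(u)))
            current = sum(fam.values())
            step += 1
            moves_log.append((r, step, kind, u, v, best_delta))
        restart_best.append(current)
        if best is None or current > best.score:
            best = ScoredNetwork(dag=g, family_scores=dict(fam), score=current)

    return SearchTrace(
        structures_evaluated=structures_evaluated,
        n_restarts=n_restarts,
        restart_best_scores=restart_best,
        moves=moves_log,
        best=best,
    )


@lru_cache(maxsize=None)
def count_dags(n: int) -> int:
    """Number of labeled DAGs on ``n`` nodes (exact integer).

    Robinson's recurrence:
    ``a(n) = sum_{k=1..n} (-1)^(k+1) C(n,k) 2^(k(n-k)) a(n-k)``, ``a(0)=1``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return 1
    total = 0
    for k in range(1, n + 1):
        total += (-1) ** (k + 1) * math.comb(n, k) * 2 ** (k * (n - k)) * count_dags(n - k)
    return total
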