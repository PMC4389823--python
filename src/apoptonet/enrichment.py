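"""Gene-set over-representation and a mean-|score| permutation GSEA variant.

Two complementary tests of whether a gene set (e.g. apoptosis annotations)
is enriched in a drug-response analysis:

- an upper-tail hypergeometric (Fisher) test of the overlap between a
  selected signature and the set within a fixed gene universe;
- a threshold-free permutation test whose enrichment score is the mean of
  the absolute differential-expression statistic over set members
  (absolute value because set genes may move in either direction), with
  the null built by repeatedly drawing same-sized random gene sets.

Gene symbols are matched case-insensitively (uppercased); no alias
resolution is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "hypergeom_overlap_test",
    "abs_mean_enrichment",
    "partition_counts",
]


def _norm(genes: Iterable[str]) -> frozenset[str]:
    return frozenset(str(g).upper() for g in genes)


@dataclass(frozen=True)
class GeneSet:
    """A named gene set; symbols are stored uppercased."""

    name: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "genes", _norm(self.genes))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentResult:
    """Overlap bookkeeping plus the two p-values (either may be absent)."""

    set_name: str
    k: int = 0  # overlap
    n: int = 0  # signature size
    K: int = 0  # set size within the universe
    N: int = 0  # universe size
    p_hypergeom: float | None = None
    es: float | None = None
    p_perm: float | None = None
    n_perm: int = 0


def hypergeom_overlap_test(
    signature: Iterable[str],
    gene_set: GeneSet | Iterable[str],
    universe: Iterable[str],
    name: str = "set",
) -> EnrichmentResult:
    """Upper-tail hypergeometric test of signature / set overlap.

    ``p = P(X >= k)`` for ``X ~ Hypergeom(N, K, n)`` with ``N`` the
    universe size, ``K`` the set size after restriction to the universe,
    ``n`` the signature size and ``k`` the observed overlap.  The observed
    count is included in the tail (the standard over-representation form).
    """
    uni = _norm(universe)
    sig = _norm(signature)
    if not uni:
        raise ValueError("universe is empty")
    if not sig:
        raise ValueError("signature is empty")
    outside = sig - uni
    if outside:
        raise ValueError(
            f"signature genes outside the universe: {sorted(outside)[:5]}"
        )
    if isinstance(gene_set, GeneSet):
        name, members = gene_set.name, gene_set.genes
    else:
        members = _norm(gene_set)
    K_set = members & uni
    k = len(sig & K_set)
    N, K, n = len(uni), len(K_set), len(sig)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(set_name=name, k=k, n=n, K=K, N=N, p_hypergeom=p)


def abs_mean_enrichment(
    scores: pd.Series,
    set_genes: Iterable[str],
    n_perm: int = 10_000,
    seed: int | None = 0,
    name: str = "set",
) -> EnrichmentResult:
    """Permutation GSEA with ES = mean |score| of set members.

    The null distribution draws ``|set|`` genes uniformly without
    replacement from all scored genes, ``n_perm`` times; the permutation
    p-value is ``(1 + #{null ES >= observed ES}) / (1 + n_perm)``, so it is
    never zero and never below ``1/(n_perm+1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if isinstance(set_genes, GeneSet):
        name, members = set_genes.name, set(set_genes.genes)
    else:
        members = set(_norm(set_genes))
    idx = pd.Index([str(g).upper() for g in scores.index])
    if idx.has_duplicates:
        raise ValueError("scores index contains duplicate gene symbols")
    values = np.abs(np.asarray(scores.to_numpy(), dtype=float))
    pos = {g: i for i, g in enumerate(idx)}
    missing = sorted(g for g in members if g not in pos)
    if missing:
        raise KeyError(f"set genes missing from the score vector: {missing[:10]}")
    member_idx = np.fromiter((pos[g] for g in sorted(members)), dtype=int)
    es = float(values[member_idx].mean())
    rng = np.random.default_rng(seed)
    m, N = member_idx.size, values.size
    null = np.empty(n_perm)
    for r in range(n_perm):
        null[r] = values[rng.choice(N, size=m, replace=False)].mean()
    # >= with a tiny tolerance so exact ties (identical |scores|) count
    hits = int(np.sum(null >= es - 1e-12))
    p = (1 + hits) / (1 + n_perm)
    return EnrichmentResult(
        set_name=name, k=m, n=m, K=m, N=N, es=es, p_perm=float(p), n_perm=n_perm
    )


def partition_counts(pro: Iterable[str], anti: Iterable[str]) -> tuple[int, int, int, int]:
    """(n_pro, n_anti, n_both, n_total) for a pro/anti gene-set partition.

    ``n_both`` counts genes annotated on both sides;
    ``n_total = n_pro + n_anti - n_both`` (the union).
    """
    p, a = _norm(pro), _norm(anti)
    n_both = len(p & a)
    return len(p), len(a), n_both, len(p) + len(a) - n_both
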