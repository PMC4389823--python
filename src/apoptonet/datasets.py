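"""Synthetic drug-perturbation expression data with known ground truth.

Emulates, at desk scale, a pooled compendium of control and drug-perturbed
expression profiles from a single cell line: a background of null genes, a
set of signature genes whose mean shifts under perturbation, and a small
gene module whose joint distribution follows a known linear-Gaussian
structural equation model (SEM) over a DAG.  Matching apoptosis-style gene
sets (pro / anti, with overlap) and a reference interaction network with
decoy nodes are generated alongside, so that differential expression,
enrichment, network recovery and validation can all be tested against the
generating truth without any download.

Default scale mirrors the real study's proportions: ~1,000 background
genes, 178 shifted signature genes, a 13-gene / 15-edge SEM module, 100
control and 400 perturbed samples, perturbation shifts |delta| in
[0.06, 0.32] log2 units (the magnitude range of the study's reported
signature fold changes) on top of gene-level noise with sd 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .dags import check_dag, make_dag
from .search import random_dag

__all__ = [
    "SemParams",
    "SampleDesign",
    "SyntheticTruth",
    "sample_random_dag",
    "random_dag_with_n_edges",
    "random_sem",
    "default_apoptosis_sem",
    "simulate_sem",
    "implied_covariance",
    "simulate_cmap_like",
    "save_truth",
    "load_truth",
    "APOPTOSIS_MODULE_GENES",
]

#: Node labels of the default 13-gene module (drug-responsive apoptotic genes).
APOPTOSIS_MODULE_GENES = (
    "PMAIP1", "VEGFA", "SERINC3", "TNFAIP3", "BNIP3L", "GCLC", "BCL2L11",
    "TAX1BP1", "SON", "NUP62", "NOL3", "TUBB", "MSH6",
)


@dataclass(frozen=True)
class SemParams:
    """A linear-Gaussian structural equation model over a DAG.

    Each node ``g`` is ``alpha[g] + sum_p beta[(p, g)] * value(p) + noise``
    with Gaussian noise of variance ``sigma2[g]``.
    """

    dag: nx.DiGraph
    beta: dict[tuple[str, str], float]
    alpha: dict[str, float]
    sigma2: dict[str, float]

    def __post_init__(self):
        check_dag(self.dag)
        edges = set(self.dag.edges)
        for key in self.beta:
            if key not in edges:
                raise ValueError(f"beta key {key} is not an edge of the DAG")
        for u, v in edges:
            if (u, v) not in self.beta:
                raise ValueError(f"edge ({u}, {v}) has no beta coefficient")
        for g in self.dag.nodes:
            if g not in self.alpha:
                raise ValueError(f"node {g} has no intercept")
            if self.sigma2.get(g, 0.0) <= 0:
                raise ValueError(f"node {g} needs a positive noise variance")

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self.dag.nodes)


@dataclass(frozen=True)
class SampleDesign:
    """Sample ids with a {control, perturbed} label per sample."""

    sample_ids: tuple[str, ...]
    groups: tuple[str, ...]

    def __post_init__(self):
        if len(self.sample_ids) != len(self.groups):
            raise ValueError("sample_ids and groups differ in length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        bad = set(self.groups) - {"control", "perturbed"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for grp in ("control", "perturbed"):
            if self.groups.count(grp) < 2:
                raise ValueError(f"need >= 2 {grp} samples")

    def ids_for(self, group: str) -> list[str]:
        return [s for s, g in zip(self.sample_ids, self.groups) if g == group]

    @property
    def control_ids(self) -> list[str]:
        return self.ids_for("control")

    @property
    def perturbed_ids(self) -> list[str]:
        return self.ids_for("perturbed")


@dataclass
class SyntheticTruth:
    """Everything the generator knows: the recovery target for every stage."""

    sem: SemParams
    signature_shifts: dict[str, float]  # gene -> true delta (log2 units)
    null_genes: tuple[str, ...]
    design: SampleDesign
    manifest: dict = field(default_factory=dict)

    def __post_init__(self):
        sem_nodes = set(self.sem.nodes)
        if sem_nodes & set(self.signature_shifts):
            raise ValueError("signature genes must be disjoint from SEM nodes")
        if sem_nodes & set(self.null_genes):
            raise ValueError("null genes must be disjoint from SEM nodes")
        if set(self.null_genes) & set(self.signature_shifts):
            raise ValueError("null and signature gene lists overlap")
        if any(d == 0 for d in self.signature_shifts.values()):
            raise ValueError("every signature gene needs a nonzero shift")

    @property
    def signature_genes(self) -> tuple[str, ...]:
        return tuple(self.signature_shifts)


def sample_random_dag(n_nodes: int, edge_prob: float, seed: int | None = None) -> nx.DiGraph:
    """Random DAG on nodes ``g01..gNN`` via a random topological order.

    Edges run only from lower to higher position in a random permutation of
    the nodes, each present independently with probability ``edge_prob``.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    nodes = [f"g{i + 1:02d}" for i in range(n_nodes)]
    return random_dag(nodes, edge_prob, np.random.default_rng(seed))


def random_dag_with_n_edges(nodes: Sequence[str], n_edges: int, rng: np.random.Generator) -> nx.DiGraph:
    """Random DAG with exactly ``n_edges`` edges (uniform over a random order)."""
    nodes = list(nodes)
    m = len(nodes)
    pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
    if n_edges > len(pairs):
        raise ValueError(f"cannot place {n_edges} edges on {m} nodes")
    order = [nodes[i] for i in rng.permutation(m)]
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    edges = [(order[pairs[c][0]], order[pairs[c][1]]) for c in chosen]
    return make_dag(nodes, edges)


def random_sem(
    dag: nx.DiGraph,
    beta_range: tuple[float, float] = (0.5, 1.5),
    sigma2: float = 1.0,
    alpha_loc: float = 0.0,
    alpha_scale: float = 0.0,
    seed: int | None = None,
) -> SemParams:
    """SEM on *dag* with |beta| ~ Uniform(beta_range), random sign.

    Intercepts are ``alpha_loc`` plus N(0, alpha_scale^2) jitter; noise
    variance is ``sigma2`` for every node.
    """
    rng = np.random.default_rng(seed)
    beta = {}
    for u, v in sorted(dag.edges):
        mag = rng.uniform(*beta_range)
        beta[(u, v)] = float(mag * rng.choice([-1.0, 1.0]))
    alpha = {
        g: float(alpha_loc + (alpha_scale * rng.standard_normal() if alpha_scale else 0.0))
        for g in dag.nodes
    }
    return SemParams(dag=dag, beta=beta, alpha=alpha, sigma2={g: float(sigma2) for g in dag.nodes})


def default_apoptosis_sem(seed: int = 0, n_edges: int = 15) -> SemParams:
    """The default 13-gene, 15-edge module used throughout the package.

    Node labels are the 13 drug-responsive apoptotic genes; the wiring is a
    random DAG (deterministic per seed), coefficients |beta| in [0.5, 1.5]
    with random sign, unit noise variance, and intercepts around 7 to mimic
    log2 expression levels.
    """
    rng = np.random.default_rng(seed)
    dag = random_dag_with_n_edges(APOPTOSIS_MODULE_GENES, n_edges, rng)
    return random_sem(dag, alpha_loc=7.0, alpha_scale=1.0, seed=rng.integers(2**31))


def simulate_sem(sem: SemParams, n_samples: int, seed: int | None = None) -> pd.DataFrame:
    """Draw i.i.d. samples from the SEM; returns a nodes x samples matrix.

    Nodes are generated in topological order:
    ``value = alpha + sum(beta * parent) + N(0, sigma2)``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    order = list(nx.topological_sort(sem.dag))
    values: dict[str, np.ndarray] = {}
    for g in order:
        x = sem.alpha[g] + np.sqrt(sem.sigma2[g]) * rng.standard_normal(n_samples)
        for p in sem.dag.predecessors(g):
            x = x + sem.beta[(p, g)] * values[p]
        values[g] = x
    cols = [f"s{i + 1:05d}" for i in range(n_samples)]
    return pd.DataFrame({g: values[g] for g in sem.nodes}, index=cols).T


def implied_covariance(sem: SemParams) -> pd.DataFrame:
    """Population covariance of the SEM: (I - C)^-1 D (I - C)^-T.

    ``C[child, parent] = beta`` and ``D`` is the diagonal of noise
    variances; rows/columns follow the SEM node order.
    """
    nodes = list(sem.nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    m = len(nodes)
    C = np.zeros((m, m))
    for (u, v), b in sem.beta.items():
        C[idx[v], idx[u]] = b
    D = np.diag([sem.sigma2[g] for g in nodes])
    inv = np.linalg.inv(np.eye(m) - C)
    cov = inv @ D @ inv.T
    return pd.DataFrame(cov, index=nodes, columns=nodes)


def _partition_gene_set(genes: list[str], rng: np.random.Generator,
                        pro_frac: float, both_frac: float) -> dict[str, list[str]]:
    """Split a set into pro / anti with an overlap, mimicking GO annotation."""
    genes = list(genes)
    rng.shuffle(genes)
    n = len(genes)
    n_both = max(1, round(both_frac * n)) if n >= 3 else 0
    n_pro_only = round(pro_frac * (n - n_both))
    both = genes[:n_both]
    pro_only = genes[n_both:n_both + n_pro_only]
    anti_only = genes[n_both + n_pro_only:]
    return {
        "apoptosis": sorted(genes),
        "pro": sorted(pro_only + both),
        "anti": sorted(anti_only + both),
    }


def simulate_cmap_like(
    n_background: int = 1000,
    n_signature: int = 178,
    sem: SemParams | None = None,
    n_control: int = 100,
    n_perturbed: int = 400,
    delta_range: tuple[float, float] = (0.06, 0.32),
    noise_sd: float = 0.5,
    seed: int | None = 0,
    probes_per_gene: int = 1,
    shift_sem: bool = True,
    n_set_background: int = 30,
    set_signature_frac: float = 0.05,
    pro_frac: float = 0.55,
    both_frac: float = 0.07,
    ref_direct_frac: float = 0.8,
    n_decoy_nodes: int = 10,
    n_decoy_paths: int = 6,
    n_decoy_edges: int = 8,
):
    """Generate a full synthetic study: expression, design, truth, sets, reference.

    Returns ``(expr, design, truth, gene_sets, reference)``:

    - ``expr``: genes x samples log2-scale matrix.  Background genes are
      i.i.d. Gaussian with no group effect; signature genes additionally
      receive a shift ``delta`` (|delta| ~ Uniform(delta_range), random
      sign) in perturbed samples; SEM module genes are drawn jointly from
      the SEM for all samples.
    - ``design``: control / perturbed labels.
    - ``truth``: :class:`SyntheticTruth` with the SEM, per-gene shifts and
      a manifest of counts.
    - ``gene_sets``: GMT-ready dict with keys ``apoptosis``, ``pro`` and
      ``anti``; the apoptosis set holds the SEM module, a fraction of the
      signature genes and background fillers, so over-representation is
      real but not trivial.
    - ``reference``: undirected interaction network containing a fraction
      of the SEM skeleton (direct evidence), decoy intermediates creating
      two-hop paths between non-adjacent module genes (indirect evidence)
      and decoy-decoy edges.

    With ``probes_per_gene > 1`` each gene is expanded into that many probe
    rows (id ``GENE_pK``) with independent probe-level noise; the
    probe-to-gene map is stored in ``truth.manifest["probe2gene"]``.
    """
    for name, v in (("n_background", n_background), ("n_control", n_control),
                    ("n_perturbed", n_perturbed)):
        if v < 1:
            raise ValueError(f"{name} must be >= 1")
    if n_signature < 0:
        raise ValueError("n_signature must be >= 0")
    if not (0 < delta_range[0] <= delta_range[1]):
        raise ValueError("delta_range must be a positive interval")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")

    # named substreams off a single master seed
    ss = np.random.SeedSequence(seed)
    (ss_base, ss_delta, ss_noise, ss_sem, ss_sets, ss_ref) = ss.spawn(6)
    rng_base = np.random.default_rng(ss_base)
    rng_delta = np.random.default_rng(ss_delta)
    rng_noise = np.random.default_rng(ss_noise)
    rng_sets = np.random.default_rng(ss_sets)
    rng_ref = np.random.default_rng(ss_ref)

    sem = sem if sem is not None else default_apoptosis_sem(seed=0)
    sem_genes = list(sem.nodes)
    bg_genes = [f"BG{i + 1:04d}" for i in range(n_background)]
    sig_genes = [f"SIG{i + 1:04d}" for i in range(n_signature)]
    overlap = (set(bg_genes) | set(sig_genes)) & set(sem_genes)
    if overlap:
        raise ValueError(f"gene-id namespaces overlap: {sorted(overlap)}")

    n = n_control + n_perturbed
    sample_ids = tuple(f"s{i + 1:05d}" for i in range(n))
    groups = ("control",) * n_control + ("perturbed",) * n_perturbed
    design = SampleDesign(sample_ids, groups)
    pert_mask = np.array([g == "perturbed" for g in groups])

    # background + signature: baseline ~ N(7, 1) per gene, noise sd per sample
    genes = bg_genes + sig_genes
    baseline = 7.0 + rng_base.standard_normal(len(genes))
    X = baseline[:, None] + noise_sd * rng_noise.standard_normal((len(genes), n))
    deltas = {}
    for i, g in enumerate(sig_genes):
        d = float(rng_delta.uniform(*delta_range) * rng_delta.choice([-1.0, 1.0]))
        deltas[g] = d
        X[n_background + i, pert_mask] += d
    expr = pd.DataFrame(X, index=genes, columns=sample_ids)

    sem_expr = simulate_sem(sem, n, seed=np.random.default_rng(ss_sem).integers(2**31))
    sem_expr.columns = sample_ids
    # module genes are themselves drug-responsive: a mean shift under
    # perturbation on top of their joint SEM structure (the shift is a
    # constant per gene, so the within-group dependence is untouched)
    sem_shifts = {}
    if shift_sem:
        for g in sem_expr.index:
            d = float(rng_delta.uniform(*delta_range) * rng_delta.choice([-1.0, 1.0]))
            sem_shifts[g] = d
            sem_expr.loc[g, pert_mask] += d
    expr = pd.concat([expr, sem_expr])

    # apoptosis gene set: SEM module + some signature genes + background filler
    n_sig_in_set = round(set_signature_frac * n_signature)
    sig_in_set = list(rng_sets.choice(sig_genes, size=n_sig_in_set, replace=False)) if n_sig_in_set else []
    n_bg_in_set = min(n_set_background, n_background)
    bg_in_set = list(rng_sets.choice(bg_genes, size=n_bg_in_set, replace=False))
    gene_sets = _partition_gene_set(sem_genes + sig_in_set + bg_in_set,
                                    rng_sets, pro_frac, both_frac)

    reference, ref_manifest = _build_reference(sem, rng_ref, ref_direct_frac,
                                               n_decoy_nodes, n_decoy_paths, n_decoy_edges)

    manifest = {
        "n_background": n_background,
        "n_signature": n_signature,
        "n_sem": len(sem_genes),
        "n_sem_edges": sem.dag.number_of_edges(),
        "n_control": n_control,
        "n_perturbed": n_perturbed,
        "apoptosis_set_size": len(gene_sets["apoptosis"]),
        "set_signature_members": sorted(sig_in_set),
        "sem_shifts": sem_shifts,
        **ref_manifest,
    }

    if probes_per_gene > 1:
        probe2gene = {}
        rows, ids = [], []
        for g in expr.index:
            for j in range(probes_per_gene):
                pid = f"{g}_p{j + 1}"
                probe2gene[pid] = g
                rows.append(expr.loc[g].to_numpy() + 0.1 * rng_noise.standard_normal(n))
                ids.append(pid)
        expr = pd.DataFrame(np.vstack(rows), index=ids, columns=sample_ids)
        manifest["probe2gene"] = probe2gene

    truth = SyntheticTruth(
        sem=sem,
        signature_shifts=deltas,
        null_genes=tuple(bg_genes),
        design=design,
        manifest=manifest,
    )
    return expr, design, truth, gene_sets, reference


def _build_reference(sem: SemParams, rng: np.random.Generator, direct_frac: float,
                     n_decoy_nodes: int, n_decoy_paths: int, n_decoy_edges: int):
    """Reference network: partial SEM skeleton + decoy paths and edges."""
    ref = nx.Graph()
    ref.add_nodes_from(sem.nodes)
    skel = sorted({tuple(sorted(e)) for e in sem.dag.edges})
    n_direct = round(direct_frac * len(skel))
    keep = rng.choice(len(skel), size=n_direct, replace=False) if n_direct else []
    for i in sorted(keep):
        ref.add_edge(*skel[i])

    decoys = [f"D{i + 1:02d}" for i in range(n_decoy_nodes)]
    ref.add_nodes_from(decoys)
    # two-hop decoy paths between non-adjacent module genes
    nodes = list(sem.nodes)
    non_adjacent = [
        (u, v)
        for i, u in enumerate(nodes)
        for v in nodes[i + 1:]
        if not (sem.dag.has_edge(u, v) or sem.dag.has_edge(v, u))
    ]
    n_paths = min(n_decoy_paths, len(non_adjacent), len(decoys))
    picked = rng.choice(len(non_adjacent), size=n_paths, replace=False) if n_paths else []
    for k, i in enumerate(sorted(picked)):
        u, v = non_adjacent[i]
        ref.add_edge(u, decoys[k])
        ref.add_edge(decoys[k], v)
    for _ in range(n_decoy_edges):
        a, b = rng.choice(len(decoys), size=2, replace=False)
        ref.add_edge(decoys[a], decoys[b])
    manifest = {
        "reference_nodes": ref.number_of_nodes(),
        "reference_edges": ref.number_of_edges(),
        "reference_direct_skeleton_edges": int(len(keep)),
        "reference_decoy_paths": int(n_paths),
    }
    return ref, manifest


def save_truth(truth: SyntheticTruth, path) -> None:
    """Serialize a SyntheticTruth to JSON (a structured sidecar for tests)."""
    payload = {
        "sem": {
            "nodes": list(truth.sem.nodes),
            "edges": [[u, v] for u, v in truth.sem.dag.edges],
            "beta": {f"{u}->{v}": b for (u, v), b in truth.sem.beta.items()},
            "alpha": truth.sem.alpha,
            "sigma2": truth.sem.sigma2,
        },
        "signature_shifts": truth.signature_shifts,
        "null_genes": list(truth.null_genes),
        "design": {
            "sample_ids": list(truth.design.sample_ids),
            "groups": list(truth.design.groups),
        },
        "manifest": truth.manifest,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_truth(path) -> SyntheticTruth:
    with open(path) as fh:
        payload = json.load(fh)
    s = payload["sem"]
    dag = make_dag(s["nodes"], [tuple(e) for e in s["edges"]])
    beta = {}
    for key, b in s["beta"].items():
        u, v = key.split("->")
        beta[(u, v)] = float(b)
    sem = SemParams(dag=dag, beta=beta, alpha=s["alpha"], sigma2=s["sigma2"])
    d = payload["design"]
    return SyntheticTruth(
        sem=sem,
        signature_shifts=payload["signature_shifts"],
        null_genes=tuple(payload["null_genes"]),
        design=SampleDesign(tuple(d["sample_ids"]), tuple(d["groups"])),
        manifest=payload.get("manifest", {}),
    )
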