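"""End-to-end orchestration: configuration, stages, artifacts, provenance.

Stages (each reads the previous stage's artifacts from ``outdir``):

``simulate`` -> expression.tsv, design.tsv, gene_sets.gmt, reference.tsv,
truth.json; ``diffexpr`` -> diffexpr.tsv, signature_up.txt,
signature_down.txt; ``enrich`` -> enrichment.tsv; ``learn`` ->
ensemble_scores.tsv, ensemble_edges.tsv, best_dag.tsv; ``consensus`` ->
edge_confidence.tsv, consensus.sif, consensus_confidence.tsv;
``validate`` -> validation.tsv, evidence_subnetwork.tsv.

Every artifact carries a provenance header (stage, seed, config hash) and
the resolved configuration is echoed to ``config_used.yaml``.  All
randomness derives from the single master seed, so a rerun with the same
configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import consensus as cns
from . import datasets, diffexpr, enrichment, io, validation
from .scoring import GaussianPrior
from .search import hill_climb

logger = logging.getLogger(__name__)

STAGES = ("simulate", "diffexpr", "enrich", "learn", "consensus", "validate")

#: artifact -> producing stage, for actionable missing-input errors
_PRODUCERS = {
    "expression.tsv": "simulate",
    "design.tsv": "simulate",
    "gene_sets.gmt": "simulate",
    "reference.tsv": "simulate",
    "truth.json": "simulate",
    "diffexpr.tsv": "diffexpr",
    "signature_up.txt": "diffexpr",
    "signature_down.txt": "diffexpr",
    "ensemble_edges.tsv": "learn",
    "ensemble_scores.tsv": "learn",
    "edge_confidence.tsv": "consensus",
    "consensus.sif": "consensus",
}


@dataclass
class PipelineConfig:
    """Resolved configuration; defaults follow the reference workflow."""

    outdir: str = "apoptonet_run"
    seed: int = 0
    # synthetic data scale
    n_background: int = 1000
    n_signature: int = 178
    n_control: int = 100
    n_perturbed: int = 400
    delta_low: float = 0.06
    delta_high: float = 0.32
    noise_sd: float = 0.5
    probes_per_gene: int = 1
    sem_seed: int = 0
    # differential expression
    alpha: float = 0.05
    bonferroni_m: int | None = None
    # enrichment
    n_perm: int = 10_000
    # scoring prior
    nu: float = 1.0
    a0: float = 1.0
    b0: float = 1.0
    # search / consensus
    n_restarts: int = 2
    n_bootstrap: int = 200
    score_interval: float = 0.95
    edge_threshold: float = 0.75
    analysis_genes: list[str] = field(default_factory=list)  # default: SEM module

    def __post_init__(self):
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not 0 < self.score_interval <= 1:
            raise ValueError("score_interval must be in (0, 1]")
        if not 0 <= self.edge_threshold <= 1:
            raise ValueError("edge_threshold must be in [0, 1]")
        if self.n_perm < 1 or self.n_restarts < 1 or self.n_bootstrap < 1:
            raise ValueError("n_perm, n_restarts and n_bootstrap must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        # outdir is a location, not a parameter: identical analyses written
        # to different directories must hash (and byte-compare) the same
        payload = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def provenance(self, stage: str) -> dict:
        return {
            "stage": stage,
            "stage_version": __version__,
            "seed": self.seed,
            "config_hash": self.config_hash(),
        }


def _require(outdir: Path, filename: str) -> Path:
    path = outdir / filename
    if not path.exists():
        stage = _PRODUCERS.get(filename, "an earlier stage")
        raise FileNotFoundError(
            f"missing artifact {path}; run the '{stage}' stage first"
        )
    return path


def _echo_config(cfg: PipelineConfig, outdir: Path) -> None:
    with open(outdir / "config_used.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def _stage_seed(cfg: PipelineConfig, stage: str) -> int:
    """Independent per-stage substream of the master seed."""
    offset = {"simulate": 0, "enrich": 1, "learn": 2}.get(stage, 0)
    child = np.random.SeedSequence(cfg.seed).spawn(3)[offset]
    return int(np.random.default_rng(child).integers(2**31))


def run_stage(name: str, cfg: PipelineConfig) -> dict:
    """Run one pipeline stage; returns a small summary dict."""
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}; choose from {STAGES}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _echo_config(cfg, outdir)
    logger.info("stage %s -> %s", name, outdir)
    return _STAGE_FUNCS[name](cfg, outdir)


def run_all(cfg: PipelineConfig) -> dict:
    summary = {}
    for stage in STAGES:
        summary[stage] = run_stage(stage, cfg)
    return summary


def _stage_simulate(cfg: PipelineConfig, outdir: Path) -> dict:
    sem = datasets.default_apoptosis_sem(seed=cfg.sem_seed)
    expr, design, truth, gene_sets, reference = datasets.simulate_cmap_like(
        n_background=cfg.n_background,
        n_signature=cfg.n_signature,
        sem=sem,
        n_control=cfg.n_control,
        n_perturbed=cfg.n_perturbed,
        delta_range=(cfg.delta_low, cfg.delta_high),
        noise_sd=cfg.noise_sd,
        seed=_stage_seed(cfg, "simulate"),
        probes_per_gene=cfg.probes_per_gene,
    )
    prov = cfg.provenance("simulate")
    io.write_expression_tsv(expr, outdir / "expression.tsv", prov)
    io.write_design_tsv(design, outdir / "design.tsv", prov)
    io.write_gmt(gene_sets, outdir / "gene_sets.gmt")
    io.write_network_tsv(reference, outdir / "reference.tsv", prov)
    datasets.save_truth(truth, outdir / "truth.json")
    return {"genes": expr.shape[0], "samples": expr.shape[1]}


def _stage_diffexpr(cfg: PipelineConfig, outdir: Path) -> dict:
    expr = io.read_expression_tsv(_require(outdir, "expression.tsv"))
    design = io.read_design_tsv(_require(outdir, "design.tsv"))
    probe2gene = None
    truth_path = outdir / "truth.json"
    if cfg.probes_per_gene > 1 and truth_path.exists():
        probe2gene = datasets.load_truth(truth_path).manifest.get("probe2gene")
    table = diffexpr.run_diffexpr(expr, design, m=cfg.bonferroni_m, probe2gene=probe2gene)
    up, down = diffexpr.select_signature(table, cfg.alpha)
    prov = cfg.provenance("diffexpr")
    cols = ["probe", "logfc", "s2", "df", "s2_post", "t", "p", "adjusted_p", "direction"]
    with open(outdir / "diffexpr.tsv", "w") as fh:
        for k, v in prov.items():
            fh.write(f"# {k}={v}\n")
        table[cols].to_csv(fh, sep="\t", index_label="gene")
    (outdir / "signature_up.txt").write_text("".join(g + "\n" for g in up))
    (outdir / "signature_down.txt").write_text("".join(g + "\n" for g in down))
    return {"n_up": len(up), "n_down": len(down)}


def _read_de_table(outdir: Path) -> pd.DataFrame:
    return pd.read_csv(_require(outdir, "diffexpr.tsv"), sep="\t", comment="#", index_col=0)


def _stage_enrich(cfg: PipelineConfig, outdir: Path) -> dict:
    table = _read_de_table(outdir)
    gene_sets = io.read_gmt(_require(outdir, "gene_sets.gmt"))
    up = [g for g in _require(outdir, "signature_up.txt").read_text().split() if g]
    down = [g for g in _require(outdir, "signature_down.txt").read_text().split() if g]
    signature = up + down
    universe = list(table.index)
    scores = pd.Series(table["t"].to_numpy(), index=universe)
    seed = _stage_seed(cfg, "enrich")
    rows = []
    for i, (name, members) in enumerate(sorted(gene_sets.items())):
        if signature:
            hg = enrichment.hypergeom_overlap_test(signature, members, universe, name=name)
            hg_fields = {"k": hg.k, "n": hg.n, "K": hg.K, "N": hg.N,
                         "p_hypergeom": hg.p_hypergeom}
        else:
            logger.warning("empty signature; skipping the over-representation test")
            hg_fields = {"k": 0, "n": 0, "K": np.nan, "N": len(universe),
                         "p_hypergeom": np.nan}
        gsea = enrichment.abs_mean_enrichment(
            scores, set(members) & {g.upper() for g in universe},
            n_perm=cfg.n_perm, seed=seed + i, name=name,
        )
        rows.append({
            "set": name, **hg_fields, "es": gsea.es,
            "p_perm": gsea.p_perm, "n_perm": gsea.n_perm,
        })
    report = pd.DataFrame(rows)
    with open(outdir / "enrichment.tsv", "w") as fh:
        for k, v in cfg.provenance("enrich").items():
            fh.write(f"# {k}={v}\n")
        report.to_csv(fh, sep="\t", index=False)
    return {"sets": len(rows)}


def _analysis_matrix(cfg: PipelineConfig, outdir: Path) -> pd.DataFrame:
    expr = io.read_expression_tsv(_require(outdir, "expression.tsv"))
    genes = cfg.analysis_genes or list(datasets.APOPTOSIS_MODULE_GENES)
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise KeyError(f"analysis genes missing from the expression matrix: {missing}")
    return expr.loc[genes]


def _stage_learn(cfg: PipelineConfig, outdir: Path) -> dict:
    data = _analysis_matrix(cfg, outdir)
    prior = GaussianPrior(nu=cfg.nu, a0=cfg.a0, b0=cfg.b0)
    seed = _stage_seed(cfg, "learn")
    trace = hill_climb(data, prior, n_restarts=cfg.n_restarts, seed=seed)
    ensemble = cns.bootstrap_learn(
        data, prior, B=cfg.n_bootstrap, seed=seed, n_restarts=cfg.n_restarts
    )
    prov = cfg.provenance("learn")
    from .dags import write_edge_list

    write_edge_list(trace.best.dag, outdir / "best_dag.tsv")
    with open(outdir / "ensemble_scores.tsv", "w") as fh:
        for k, v in prov.items():
            fh.write(f"# {k}={v}\n")
        fh.write("replicate\tscore\n")
        for (r, _, net) in ensemble.replicates:
            fh.write(f"{r}\t{net.score:.10g}\n")
    with open(outdir / "ensemble_edges.tsv", "w") as fh:
        for k, v in prov.items():
            fh.write(f"# {k}={v}\n")
        fh.write("replicate\tsource\ttarget\n")
        for (r, _, net) in ensemble.replicates:
            for u, v in sorted(net.dag.edges):
                fh.write(f"{r}\t{u}\t{v}\n")
    return {
        "best_score": trace.best.score,
        "structures_evaluated": trace.structures_evaluated,
        "B": len(ensemble),
    }


def _load_ensemble(cfg: PipelineConfig, outdir: Path) -> cns.BootstrapEnsemble:
    from .dags import make_dag
    from .scoring import ScoredNetwork

    scores = pd.read_csv(_require(outdir, "ensemble_scores.tsv"), sep="\t", comment="#")
    edges = pd.read_csv(_require(outdir, "ensemble_edges.tsv"), sep="\t", comment="#")
    genes = cfg.analysis_genes or list(datasets.APOPTOSIS_MODULE_GENES)
    replicates = []
    by_rep = dict(tuple(edges.groupby("replicate"))) if len(edges) else {}
    for _, row in scores.iterrows():
        r = int(row["replicate"])
        e = by_rep.get(r)
        pairs = list(zip(e["source"], e["target"])) if e is not None else []
        dag = make_dag(genes, pairs)
        fam = {g: 0.0 for g in genes}
        fam[genes[0]] = float(row["score"])
        replicates.append((r, 0, ScoredNetwork(dag=dag, family_scores=fam, score=float(row["score"]))))
    return cns.BootstrapEnsemble(replicates=replicates, n_samples=0, nodes=tuple(genes))


def _stage_consensus(cfg: PipelineConfig, outdir: Path) -> dict:
    ensemble = _load_ensemble(cfg, outdir)
    retained = cns.filter_score_interval(ensemble, cfg.score_interval)
    table = cns.edge_confidence(retained)
    graph = cns.build_consensus(table, cfg.edge_threshold)
    prov = cfg.provenance("consensus")
    with open(outdir / "edge_confidence.tsv", "w") as fh:
        for k, v in prov.items():
            fh.write(f"# {k}={v}\n")
        table.to_frame().to_csv(fh, sep="\t", index=False)
    io.write_sif(graph, outdir / "consensus.sif", provenance=prov)
    with open(outdir / "consensus_confidence.tsv", "w") as fh:
        for k, v in prov.items():
            fh.write(f"# {k}={v}\n")
        fh.write("source\ttarget\tconfidence\tskeleton_confidence\n")
        for u, v, d in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d['confidence']:.6g}\t{d['skeleton_confidence']:.6g}\n")
    return {"retained": len(retained), "consensus_edges": graph.number_of_edges()}


def _stage_validate(cfg: PipelineConfig, outdir: Path) -> dict:
    reference = validation.load_reference(_require(outdir, "reference.tsv"))
    conf = pd.read_csv(_require(outdir, "consensus.sif"), sep="\t", comment="#", header=None,
                       names=["source", "interaction", "target"])
    predicted = nx.DiGraph()
    predicted.add_edges_from(zip(conf["source"], conf["target"]))
    report = validation.classify_edges(predicted, reference)
    evidence = validation.evidence_subnetwork(report, reference)
    prov = cfg.provenance("validate")
    with open(outdir / "validation.tsv", "w") as fh:
        for k, v in prov.items():
            fh.write(f"# {k}={v}\n")
        fh.write("source\ttarget\tstatus\tshortest_path_length\tn_shortest_paths\tpaths\n")
        for ev in report.edges:
            paths = ";".join("-".join(p) for p in ev.shortest_paths)
            fh.write(
                f"{ev.source}\t{ev.target}\t{ev.status}\t"
                f"{ev.path_length if ev.path_length is not None else ''}\t"
                f"{len(ev.shortest_paths)}\t{paths}\n"
            )
    io.write_network_tsv(evidence, outdir / "evidence_subnetwork.tsv", prov)
    return {
        **report.counts,
        "evidence_nodes": evidence.number_of_nodes(),
        "evidence_edges": evidence.number_of_edges(),
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "diffexpr": _stage_diffexpr,
    "enrich": _stage_enrich,
    "learn": _stage_learn,
    "consensus": _stage_consensus,
    "validate": _stage_validate,
}
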