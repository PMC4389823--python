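# apoptonet

Tools for asking what a large compendium of drug-perturbed cancer-cell
expression profiles says about programmed cell death: which genes respond
to chemical perturbation, whether apoptosis annotations are enriched among
the responders, and how a small module of apoptotic genes is wired.  The
package is aimed at computational biologists who have a normalized
expression matrix (hundreds of pooled control and compound-treated
samples from one cell line), a control/perturbed sample annotation, gene
sets in GMT format and a curated interaction network — and who want the
whole analysis to be reproducible and testable, so it ships a synthetic
data generator with a known ground-truth network in place of any download.

## What it computes

**Differential expression.**  All perturbed samples are pooled against all
controls ("complete pooling" across compounds).  Per gene `g`, a two-group
linear model gives the log-fold-change and residual variance `s²_g` with
`d = n − 2` degrees of freedom; variances are shrunk with the standard
empirical-Bayes hierarchy

    s̃²_g = (d₀·s₀² + d·s²_g) / (d₀ + d),
    t_g = logFC_g / sqrt(s̃²_g (1/n_c + 1/n_p))  ~  t(d + d₀),

with `(d₀, s₀²)` estimated by moment-matching `log s²` across genes.
Multiple testing is Bonferroni-controlled (`p_adj = min(1, p·m)`).

**Enrichment.**  An upper-tail hypergeometric test of the
signature-versus-set overlap within the gene universe, and a
threshold-free permutation test whose enrichment score is the mean |t|
over set members (absolute value because apoptotic genes move in both
directions), with `p = (1 + #{null ES ≥ ES}) / (1 + n_perm)`.

**Network inference.**  Each gene is modeled conditional on its parents in
a DAG `G` as a linear Gaussian family,
`g_i | pa(g_i) ~ N(Σ_j β_ij·pa_j + α_i, σ_i²)`.  With a conjugate
Normal–Inverse-Gamma prior per family, derived from a single global
Normal–Inverse-Wishart so that Markov-equivalent DAGs score identically,
the structure score is the log marginal likelihood
`score(G : D) = log p(D | G) = Σ_i log ∫ p(d_i | θ_i, pa_i) p(θ_i) dθ_i`,
and structures are compared by Bayes factors (uniform structure prior).
The 13-node space holds ≈ 1.87 × 10³¹ DAGs, so the best structure is found
by hill climbing (add/delete/reverse moves) with random restarts.
Stability comes from bootstrap model averaging: one structure per
resample, replicates filtered to the central 95% score interval, and a
consensus of node pairs whose bootstrap confidence exceeds 75%.

**Validation.**  Predicted edges are compared with a curated interaction
network: *direct* (the pair is a reference edge), *indirect* (a path via
intermediates; all shortest paths recorded) or *unsupported*, plus the
evidence subnetwork spanned by those paths.

## Worked example

```python
import numpy as np
import pandas as pd
from apoptonet import simulate_cmap_like, ModeratedTTest, BootstrapConsensus
from apoptonet.enrichment import hypergeom_overlap_test, abs_mean_enrichment
from apoptonet.consensus import skeleton_precision_recall
from apoptonet.validation import classify_edges

expr, design, truth, gene_sets, reference = simulate_cmap_like(
    n_background=300, n_signature=60, n_control=100, n_perturbed=200,
    delta_range=(0.2, 0.4), set_signature_frac=0.3, seed=7)

de = ModeratedTTest().fit(expr.T, np.asarray(design.groups))
up, down = de.signature()

res = hypergeom_overlap_test(up + down, gene_sets["apoptosis"], list(expr.index))
gsea = abs_mean_enrichment(pd.Series(de.t_, index=expr.index),
                           gene_sets["apoptosis"], n_perm=10_000, seed=7)

module = expr.loc[list(truth.sem.nodes)]
net = BootstrapConsensus(n_bootstrap=100, random_state=7).fit(module.T)
precision, recall = skeleton_precision_recall(net.consensus_, truth.sem.dag)
report = classify_edges(net.consensus_, reference)
```

prints (via the obvious f-strings):

```
signature: 22 up, 27 down (d0=9.21, s0^2=0.243)
apoptosis overlap: k=16 of n=49 signature genes (set K=61, universe N=373), hypergeometric p=0.00187
GSEA: ES=2.159, permutation p=0.0004 (10000 permutations)
consensus: 13 edges from 94 retained replicates; skeleton precision=0.92, recall=0.80
validation: 9 direct, 3 indirect, 1 unsupported
```

Reading this: 49 of the 60 planted responder genes cleared the Bonferroni
bar at α = 0.05 with no false positives; the apoptosis set is
over-represented in the signature (p ≈ 0.002) and enriched in the
threshold-free test (p = 4 × 10⁻⁴); the bootstrap consensus over the
13-gene module recovered 12 of the 15 true undirected interactions with
one false pair; and 12 of the 13 consensus edges have direct or
shortest-path support in the reference network.

The same workflow is available from the shell:

```sh
apoptonet run-all --outdir run1 --seed 7          # or per stage:
apoptonet simulate --outdir run1 --seed 7
apoptonet diffexpr --outdir run1 --seed 7
...
```

with a YAML config (`--config`) exposing every threshold (α = 0.05,
10,000 permutations, 2 restarts, B = 200, 95% score interval, 75% edge
confidence).  Outputs are TSV/GMT/SIF with provenance headers; reruns
with the same seed are byte-identical.

## Layout

| module | contents |
| --- | --- |
| `apoptonet.datasets` | synthetic study generator, SEM simulation, implied covariance |
| `apoptonet.diffexpr` | two-group fits, moderated t, Bonferroni, probe collapsing |
| `apoptonet.enrichment` | hypergeometric overlap test, mean-\|t\| permutation GSEA |
| `apoptonet.scoring` | Gaussian-network marginal-likelihood score, conjugate posteriors |
| `apoptonet.search` | hill climbing with restarts, neighbor moves, DAG counting |
| `apoptonet.consensus` | bootstrap ensembles, score filtering, edge confidence |
| `apoptonet.validation` | direct/indirect/unsupported classification, evidence subnetwork |
| `apoptonet.estimators` | sklearn-style `ModeratedTTest`, `GaussianBayesianNetwork`, `BootstrapConsensus` |
| `apoptonet.pipeline` / `apoptonet.cli` | staged pipeline, YAML config, `apoptonet` command |

See `docs/methods.md` for the model details, defaults and limitations.
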