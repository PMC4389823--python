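# Methods

This note records the models implemented in `apoptonet`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that matter for reproducing
results.

## Pooled differential expression

The design is an intercept plus a binary perturbation indicator: all
compound-treated samples are pooled into one group against all controls.
Pooling trades per-compound resolution for statistical power and is the
right model when the question is the *shared* transcriptional response to
chemical stress; per-compound effects, batch structure and
compound-cluster analyses are out of scope.

Per gene, ordinary least squares gives `logFC` (difference of group
means, log2 units) and the pooled residual variance `s²` on `d = n − 2`
degrees of freedom.  The empirical-Bayes hierarchy places a scaled
inverse-chi-square prior on the true variances, `1/σ² ~ χ²_{d₀}/(d₀ s₀²)`,
so the posterior variance is the precision-weighted blend
`s̃² = (d₀ s₀² + d s²)/(d₀ + d)` and the moderated t has `d + d₀` degrees
of freedom.  `(d₀, s₀²)` are estimated by matching the mean and variance
of `log s²` to the implied scaled-F distribution; the trigamma equation is
inverted by Newton iteration.  Two deliberate edge cases:

- **Under-dispersion** (`var(log s²)` below the pure chi-square noise
  level) yields `d₀ = ∞`: full shrinkage, normal reference distribution.
  Exactly constant variances shrink to that constant (the chi-square bias
  correction assumes sampling dispersion that is absent there).
- **Fewer than 10 positive variances**: estimation is refused and
  `d₀ = 0` (no moderation) is returned with a warning, because two or
  three points cannot identify a dispersion hyperparameter.

The implementation is cross-checked in the test suite against the
R/Bioconductor `limma` package on a simulated fixture (agreement to
~1e−8 for finite `d₀`).

Multiple testing uses Bonferroni, `p_adj = min(1, p·m)`, with `m`
defaulting to the number of tested rows; a caller analysing a platform
subset can pass the full platform count (22,268 probe sets on the array
this workflow targets).  Bonferroni rather than a false-discovery-rate
procedure is a deliberate match to the upstream workflow this package
reimplements; the column is named `adjusted_p` to avoid implying
Benjamini–Hochberg.  Probes collapse to genes by minimum raw p — the
most-significant probe represents the gene; alternatives (mean, median)
change little here and the rule is simple to audit.

## Enrichment

Over-representation is the upper-tail hypergeometric probability
`P(X ≥ k)` for an overlap of `k` set members among `n` signature genes in
a universe of `N` containing `K` set members; the set is intersected with
the universe before testing (genes absent from the platform cannot
enrich), and signature genes must lie inside the universe.  Symbols match
case-insensitively; no alias resolution is attempted.

The permutation variant avoids the selection threshold entirely: the
enrichment score is the mean of |t| over set members — absolute value
because a coherent apoptotic response contains both induced and repressed
genes, which a signed mean would cancel.  The null draws `|set|` genes
uniformly without replacement `n_perm` times (default 10,000) and
`p = (1 + #{ES_null ≥ ES}) / (1 + n_perm)`, which is never zero and is
exact-conservative at any `n_perm`.  The statistic fed to the test is the
moderated t by default (variance-stabilized); logFC can be supplied
instead by passing a different score vector.

## Gaussian network score

Each node is a conditional linear Gaussian family.  The score of a
structure is the sum over families of the log marginal likelihood of the
child regressed on (intercept, parents) under a conjugate
Normal–Inverse-Gamma prior, integrated exactly.

**Equivalence-consistent prior.**  Repeating one arbitrary NIG prior for
every family does *not* give likelihood equivalence (Markov-equivalent
DAGs would score differently, making edge directions an artifact of the
prior).  The family priors here are therefore derived as conditionals of
a single global Normal–Inverse-Wishart over all `p` analysed genes
(mean 0, equivalent sample size `nu`, scale `2·b0·I`): a family with `k`
parents receives

- intercept precision `nu` (relative to the noise variance),
- slope precision `2·b0` per parent,
- noise variance `σ² ~ Inv-Gamma(a0 + k/2, b0)`.

The `k/2` shape adjustment is the Inverse-Wishart marginalization
consistency condition.  With this construction the total score depends on
the DAG only through its Markov equivalence class — exactly, not
approximately — which the test suite verifies over every 3- and 4-node
DAG.  Each family score is still a plain NIG regression marginal, so it
is checked against numerical integration (coefficients via the Gaussian
marginal identity, variance by quadrature; plus a fully numerical 2-D
oracle for the no-parent case) to 1e−6 relative error.

Defaults `nu = a0 = b0 = 1` are weak and scale-free after the per-gene
mean centering that `network_score` applies by default (centering only;
scale is preserved).  A nonzero prior mean is accepted for sensitivity
analyses but breaks exact equivalence and is not the default.  Parameter
estimation uses the closed-form conjugate posterior (posterior mean
coefficients, `E[σ²] = b_n/(a_n − 1)`); an optional sampling mode draws
from the exact posterior and is verified against the closed form — no
Markov-chain approximation is needed because the conjugate model
integrates exactly.

## Structure search

Hill climbing over the classical move set (single-edge addition, deletion,
reversal, all acyclicity-checked) with strict-improvement steps, so every
climb is finite and monotone.  The first restart starts from the empty
graph (a reproducible baseline), later restarts from random DAGs (random
topological order, edge probability 0.2); the default is 2 restarts.
Ties among equally improving moves break lexicographically by (move kind,
source, target), making the search deterministic given the seed.  Score
decomposability is exploited twice: a move re-scores only the one or two
changed families, and family scores are cached by (node, parent set), so
repeated neighborhoods cost nothing.  `structures_evaluated` counts every
scored candidate, accepted or not.

The 13-variable space contains 1.86766 × 10³¹ DAGs (Robinson's
recurrence, computed exactly with integer arithmetic and verified against
brute-force enumeration for n ≤ 4), which is why greedy search plus
averaging replaces enumeration.

**Limitation.**  Greedy search finds local optima, and at finite sample
size the global optimum itself can differ from the generating DAG by an
edge or two.  Exact single-run recovery is therefore not a contract of
this package; stability comes from the bootstrap layer below.

## Bootstrap consensus

`B` bootstrap replicates (default 200; 100 in the heavier benchmarks)
resample the samples with replacement and learn one structure each, all
seeds derived from one master seed.  Replicates are filtered to the
central 95% interval of ensemble scores (closed interval between the
2.5% and 97.5% empirical quantiles, linear interpolation) to drop runs
trapped in poor optima.  Edge confidence is the frequency of an edge
among retained replicates, reported both directed and direction-ignoring
(skeleton).

The consensus keeps node pairs whose **skeleton** confidence strictly
exceeds the threshold (default 75%), oriented along the majority
direction.  Skeleton-level thresholding is the default because structure
learning identifies DAGs only up to Markov equivalence: replicates flip
orientations within a class, splitting a stable pair's directed frequency
(empirically ≈ 0.5/0.5) while its skeleton confidence stays near 1.  A
`level="directed"` mode applies the threshold to directed frequencies
instead.  The consensus graph is not forced acyclic — averaging DAGs does
not yield a DAG — and is reported as a directed interaction network with
both confidences per edge.

Under the benchmark conditions (13 genes, 15 edges, |β| ~ U(0.5, 1.5)
with random sign, σ² = 1, n = 1000, B = 100, threshold 0.75) the
consensus skeleton reaches mean precision/recall ≈ 0.96/0.97 over five
seeds, as recomputed by `scripts/acceptance.py`; shrinking β toward zero
empties the consensus.

## Validation

The reference interaction network is undirected (curated databases mix
directionality), simple (duplicates and self-loops dropped on load) and
matched case-insensitively.  A predicted edge, direction ignored, is
*direct* if the pair is a reference edge, *indirect* if any path connects
the endpoints — all *shortest* paths are recorded, and only those count
as evidence — and *unsupported* otherwise (including endpoints absent
from the reference).  No path-length bound is applied by default.  The
evidence subnetwork is the union of supported endpoints and every node
and edge on a recorded shortest path; it is verified against an
independent breadth-first-search oracle.

## Synthetic data

The generator emulates, at desk scale, a pooled drug-perturbation
compendium from one cell line:

- **Background genes** (default 1,000): i.i.d. Gaussian, baseline
  ~N(7, 1) per gene (log2-like levels), per-sample noise sd 0.5, no group
  effect.
- **Signature genes** (default 178): background plus a shift δ in
  perturbed samples, |δ| ~ U(0.06, 0.32) with random sign — the magnitude
  range of the reported responder fold-changes — so at default scale only
  the stronger ones are Bonferroni-recoverable, which is realistic.
- **A 13-gene module** wired as a random 15-edge DAG (node labels are the
  13 drug-responsive apoptotic genes), sampled jointly from the
  linear-Gaussian SEM for all samples; by default the module genes also
  receive a perturbation shift, since in the real workflow they were
  selected as responders.  The closed-form implied covariance
  `(I − C)⁻¹ D (I − C)⁻ᵀ` serves as the simulation oracle.
- **Gene sets**: an apoptosis set holding the module, a fraction of the
  signature and background fillers, split into pro/anti with overlap.
- **Reference network**: 80% of the module skeleton as direct evidence,
  decoy intermediates creating two-hop paths between non-adjacent module
  genes, and decoy-decoy edges — so direct, indirect and unsupported
  classifications all occur.
- Samples: 100 control + 400 perturbed by default (the real compendium's
  ≈1:6 imbalance at reduced size).

All randomness flows from one master seed through named substreams;
outputs are TSV/GMT plus a JSON truth sidecar.  Deliberately *not*
modeled: probe-level intensities and normalization, batch effects,
per-compound heterogeneity, and alias ambiguity in gene symbols.  Passing
tests on this generator demonstrate correctness of the statistics and
recoverability under the stated conditions; they do not certify
performance on real microarray data, where unmodeled structure (batch,
compound clusters, annotation noise) will lower enrichment and recovery.

## Problem sizes and runtime

The test suite runs the full stack at reduced scale (recovery benchmark:
five seeds × 100 bootstrap replicates × 2 restarts at n = 1000, about a
minute; everything else seconds).  `scripts/acceptance.py` uses the
default-scale synthetic study (1,191 genes × 500 samples, B = 100,
10,000 permutations) plus the recovery benchmark, finishing in a few
minutes on one CPU.  At this scale the synthetic enrichment p-values are
honest but underpowered relative to a compendium of thousands of samples;
the study-scale margins quantity (`fisher_p_study_margins`) is the
scale-faithful over-representation number.
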