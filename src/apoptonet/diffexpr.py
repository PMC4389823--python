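"""Pooled two-group differential expression with a moderated t-statistic.

All perturbed samples are pooled against all controls ("complete pooling"
across compounds): per gene, an ordinary least-squares fit of expression on
an intercept plus a binary perturbation indicator gives the log-fold-change
and a residual variance with ``n - 2`` degrees of freedom.  Residual
variances are then shrunk toward a common prior value with the standard
empirical-Bayes hierarchical model: ``s2 ~ s2_true * chi2_d / d`` and
``1/s2_true ~ chi2_d0 / (d0 * s0^2)``, giving the posterior variance
``s2_post = (d0*s0^2 + d*s2) / (d0 + d)`` and a t-statistic with ``d + d0``
degrees of freedom.  The hyperparameters ``(d0, s0^2)`` are estimated by
matching the first two moments of ``log s2`` to the implied scaled-F
distribution.  Multiple testing is controlled by Bonferroni (adjusted
p = min(1, p * m)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .datasets import SampleDesign

__all__ = [
    "EbHyperparams",
    "fit_group_model",
    "estimate_eb_hyperparams",
    "moderated_t",
    "bonferroni",
    "collapse_to_genes",
    "select_signature",
    "run_diffexpr",
]


@dataclass(frozen=True)
class EbHyperparams:
    """Prior degrees of freedom and variance of the variance hierarchy.

    ``d0 = 0`` means no moderation (ordinary t); ``d0 = inf`` means total
    shrinkage to ``s02`` (normal reference distribution).
    """

    d0: float
    s02: float

    def posterior_var(self, s2: np.ndarray, d: float) -> np.ndarray:
        s2 = np.asarray(s2, dtype=float)
        if np.isinf(self.d0):
            return np.full_like(s2, self.s02)
        if self.d0 == 0:
            return s2.copy()
        return (self.d0 * self.s02 + d * s2) / (self.d0 + d)


def fit_group_model(expr: pd.DataFrame, design: SampleDesign) -> pd.DataFrame:
    """Per-row two-group least squares: logFC, pooled residual variance, df.

    ``logfc = mean(perturbed) - mean(control)`` (log2 units when the input
    is log2 expression); ``s2`` is the pooled residual variance with
    ``d = n - 2`` degrees of freedom.
    """
    ctrl, pert = design.control_ids, design.perturbed_ids
    missing = [s for s in design.sample_ids if s not in expr.columns]
    if missing:
        raise ValueError(f"design samples missing from the matrix: {missing[:5]}")
    n = len(ctrl) + len(pert)
    d = n - 2
    if d <= 0:
        raise ValueError("zero residual degrees of freedom (need >= 3 samples)")
    Xc = expr[ctrl].to_numpy(dtype=float)
    Xp = expr[pert].to_numpy(dtype=float)
    if not (np.all(np.isfinite(Xc)) and np.all(np.isfinite(Xp))):
        raise ValueError("expression matrix contains non-finite values")
    mc, mp = Xc.mean(axis=1), Xp.mean(axis=1)
    ss = ((Xc - mc[:, None]) ** 2).sum(axis=1) + ((Xp - mp[:, None]) ** 2).sum(axis=1)
    return pd.DataFrame(
        {"logfc": mp - mc, "s2": ss / d, "df": float(d)}, index=expr.index
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        raise ValueError("trigamma inverse needs y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_eb_hyperparams(s2: np.ndarray, d: float) -> EbHyperparams:
    """Moment-match ``log s2`` against its scaled-F sampling distribution.

    Under the hierarchy, ``log s2`` has mean
    ``log s02 + psi(d/2) - log(d/2) - psi(d0/2) + log(d0/2)`` and variance
    ``psi'(d/2) + psi'(d0/2)``; solving the variance equation for ``d0``
    and back-substituting gives ``s02``.  When the observed variances are
    under-dispersed relative to pure chi-square noise the solution is
    ``d0 = +inf`` (all variances equal ``s02``).  With fewer than 10
    positive variances estimation is refused and ``d0 = 0`` (no
    moderation) is returned.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size < 10:
        warnings.warn(
            f"only {pos.size} positive variances; refusing to moderate (d0=0)",
            stacklevel=2,
        )
        return EbHyperparams(d0=0.0, s02=float(np.median(pos)) if pos.size else 0.0)
    z = np.log(pos)
    emean = float(z.mean())
    evar = float(z.var(ddof=1))
    if evar < 1e-12:
        # exactly constant variances: no sampling dispersion at all, so the
        # chi-square bias correction does not apply; shrink fully to the
        # common value
        return EbHyperparams(d0=np.inf, s02=float(np.exp(emean)))
    evar_resid = evar - float(special.polygamma(1, d / 2.0))
    base = emean - float(special.digamma(d / 2.0)) + np.log(d / 2.0)
    if evar_resid <= 0:
        return EbHyperparams(d0=np.inf, s02=float(np.exp(base)))
    half_d0 = _trigamma_inverse(evar_resid)
    d0 = 2.0 * half_d0
    s02 = float(np.exp(base + special.digamma(half_d0) - np.log(half_d0)))
    return EbHyperparams(d0=d0, s02=s02)


def moderated_t(
    table: pd.DataFrame,
    hyper: EbHyperparams,
    n_control: int,
    n_perturbed: int,
) -> pd.DataFrame:
    """Moderated t and two-sided p per row.

    ``t = logfc / sqrt(s2_post * (1/n_c + 1/n_p))`` referred to a t
    distribution with ``d + d0`` degrees of freedom (standard normal when
    ``d0`` is infinite).  Rows with ``s2_post = 0`` get infinite t, p = 0
    and are flagged in ``zero_variance``.
    """
    out = table.copy()
    d = float(table["df"].iloc[0])
    s2_post = hyper.posterior_var(table["s2"].to_numpy(), d)
    se2 = s2_post * (1.0 / n_control + 1.0 / n_perturbed)
    logfc = table["logfc"].to_numpy()
    zero = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / np.sqrt(se2)
    t[zero] = np.sign(logfc[zero]) * np.inf
    if np.isinf(hyper.d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=d + hyper.d0)
    p = np.where(zero, 0.0, p)
    out["s2_post"] = s2_post
    out["t"] = t
    out["p"] = p
    out["zero_variance"] = zero
    return out


def bonferroni(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``min(1, p * m)``; order-preserving.

    ``m`` defaults to the number of tested rows and may be larger (e.g.
    the full probe-set count of a platform when only a subset is passed).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"m={m} is smaller than the number of tests ({p.size})")
    return np.minimum(1.0, p * m)


def collapse_to_genes(table: pd.DataFrame, probe2gene: dict[str, str]) -> pd.DataFrame:
    """One row per gene: the probe with the smallest raw p represents it.

    Probes absent from the mapping are dropped with a warning.  The output
    keeps the probe id in a ``probe`` column and is indexed by gene.
    """
    unmapped = [pid for pid in table.index if pid not in probe2gene]
    if unmapped:
        warnings.warn(
            f"dropping {len(unmapped)} probes without a gene mapping "
            f"(e.g. {unmapped[:3]})",
            stacklevel=2,
        )
    kept = table.loc[[pid for pid in table.index if pid in probe2gene]].copy()
    kept["probe"] = kept.index
    kept["gene"] = [probe2gene[pid] for pid in kept.index]
    best = kept.sort_values("p", kind="stable").drop_duplicates("gene", keep="first")
    best = best.set_index("gene").sort_index()
    return best


def select_signature(table: pd.DataFrame, alpha: float = 0.05) -> tuple[list[str], list[str]]:
    """Rows with adjusted p < alpha, split into up- and downregulated lists."""
    if "adjusted_p" not in table.columns:
        raise KeyError("table has no 'adjusted_p' column; run bonferroni first")
    hits = table[table["adjusted_p"] < alpha]
    up = sorted(hits.index[hits["logfc"] > 0])
    down = sorted(hits.index[hits["logfc"] < 0])
    return up, down


def run_diffexpr(
    expr: pd.DataFrame,
    design: SampleDesign,
    m: int | None = None,
    probe2gene: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Full differential-expression table: fit, moderate, adjust, collapse.

    Returns a table indexed by gene (after probe collapsing when a
    mapping is given) with columns logfc, s2, df, s2_post, t, p,
    adjusted_p and direction.
    """
    fit = fit_group_model(expr, design)
    hyper = estimate_eb_hyperparams(fit["s2"].to_numpy(), float(fit["df"].iloc[0]))
    tab = moderated_t(fit, hyper, len(design.control_ids), len(design.perturbed_ids))
    tab["adjusted_p"] = bonferroni(tab["p"].to_numpy(), m)
    if probe2gene is not None:
        tab = collapse_to_genes(tab, probe2gene)
    else:
        tab = tab.copy()
        tab["probe"] = tab.index
    tab["direction"] = np.where(tab["logfc"] > 0, "up", np.where(tab["logfc"] < 0, "down", "flat"))
    tab.attrs["eb_hyperparams"] = hyper
    return tab
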