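"""Differential expression: OLS fits, variance moderation, adjustment.

The moderated-t stack is checked three ways: against closed-form oracles
coded independently in this file, against parameter-recovery simulations,
and against the R/Bioconductor limma implementation on a frozen fixture.
"""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from apoptonet.datasets import SampleDesign, simulate_cmap_like
from apoptonet.diffexpr import (
    EbHyperparams,
    bonferroni,
    collapse_to_genes,
    estimate_eb_hyperparams,
    fit_group_model,
    moderated_t,
    run_diffexpr,
    select_signature,
)


def _design(n_c, n_p):
    ids = tuple(f"s{i}" for i in range(n_c + n_p))
    return SampleDesign(ids, ("control",) * n_c + ("perturbed",) * n_p)


class TestFitGroupModel:
    def test_noiseless_separation(self):
        design = _design(2, 2)
        expr = pd.DataFrame([[0.0, 0.0, 1.0, 1.0]], index=["g"], columns=design.sample_ids)
        fit = fit_group_model(expr, design)
        assert fit.loc["g", "logfc"] == 1.0
        assert fit.loc["g", "s2"] == 0.0
        assert fit.loc["g", "df"] == 2.0

    def test_label_swap_negates_logfc(self):
        rng = np.random.default_rng(0)
        design = _design(4, 6)
        swapped = SampleDesign(
            design.sample_ids,
            tuple("perturbed" if g == "control" else "control" for g in design.groups),
        )
        expr = pd.DataFrame(rng.standard_normal((5, 10)), columns=design.sample_ids)
        a = fit_group_model(expr, design)
        b = fit_group_model(expr, swapped)
        np.testing.assert_allclose(a["logfc"], -b["logfc"])
        np.testing.assert_allclose(a["s2"], b["s2"])

    def test_matches_two_group_least_squares_oracle(self):
        # independent closed-form oracle: project onto (1, indicator)
        rng = np.random.default_rng(1)
        design = _design(8, 12)
        y = rng.standard_normal(20)
        expr = pd.DataFrame([y], index=["g"], columns=design.sample_ids)
        x = np.array([0.0] * 8 + [1.0] * 12)
        X = np.column_stack([np.ones(20), x])
        beta, rss, _, _ = np.linalg.lstsq(X, y, rcond=None)
        fit = fit_group_model(expr, design)
        assert fit.loc["g", "logfc"] == pytest.approx(beta[1], rel=1e-12)
        assert fit.loc["g", "s2"] == pytest.approx(float(rss[0]) / 18, rel=1e-12)

    def test_too_few_samples_rejected(self):
        design = SampleDesign(("a", "b", "c", "d"), ("control",) * 2 + ("perturbed",) * 2)
        expr = pd.DataFrame(np.zeros((1, 4)), columns=design.sample_ids)
        fit_group_model(expr, design)  # d = 2 fine
        with pytest.raises(ValueError, match="missing"):
            fit_group_model(expr.iloc[:, :3], design)


class TestEbHyperparams:
    def test_degenerate_equal_variances(self):
        hyper = estimate_eb_hyperparams(np.full(50, 0.25), d=10)
        assert np.isinf(hyper.d0)
        assert hyper.s02 == pytest.approx(0.25, rel=0.05)
        np.testing.assert_allclose(hyper.posterior_var(np.full(50, 0.25), 10), 0.25, rtol=0.05)

    def test_parameter_recovery_from_scaled_inv_chisquare(self):
        rng = np.random.default_rng(7)
        d0, s02, d = 4.0, 1.0, 10
        s2_true = s02 * d0 / rng.chisquare(d0, size=10_000)
        s2 = s2_true * rng.chisquare(d, size=10_000) / d
        hyper = estimate_eb_hyperparams(s2, d)
        assert hyper.d0 == pytest.approx(d0, rel=0.2)
        assert hyper.s02 == pytest.approx(s02, rel=0.05)

    def test_refuses_tiny_inputs(self):
        with pytest.warns(UserWarning, match="refusing"):
            hyper = estimate_eb_hyperparams(np.array([0.5, 0.7]), d=4)
        assert hyper.d0 == 0.0

    def test_posterior_var_between_observed_and_prior(self):
        hyper = EbHyperparams(d0=4.0, s02=1.0)
        s2 = np.array([0.2, 1.0, 5.0])
        post = hyper.posterior_var(s2, d=10)
        assert np.all(post >= np.minimum(s2, 1.0)) and np.all(post <= np.maximum(s2, 1.0))


class TestModeratedT:
    def test_no_shrinkage_equals_classical_pooled_t(self):
        rng = np.random.default_rng(2)
        design = _design(5, 7)
        expr = pd.DataFrame(rng.standard_normal((30, 12)), columns=design.sample_ids)
        fit = fit_group_model(expr, design)
        tab = moderated_t(fit, EbHyperparams(d0=0.0, s02=1.0), 5, 7)
        t_ref, p_ref = stats.ttest_ind(
            expr[design.perturbed_ids], expr[design.control_ids], axis=1, equal_var=True
        )
        np.testing.assert_allclose(tab["t"], t_ref, rtol=1e-12)
        np.testing.assert_allclose(tab["p"], p_ref, rtol=1e-12)

    def test_formula_oracle_row_by_row(self):
        rng = np.random.default_rng(3)
        design = _design(6, 6)
        expr = pd.DataFrame(rng.standard_normal((30, 12)) * 2 + 5, columns=design.sample_ids)
        fit = fit_group_model(expr, design)
        hyper = estimate_eb_hyperparams(fit["s2"].to_numpy(), 10)
        tab = moderated_t(fit, hyper, 6, 6)
        for g in expr.index:
            s2_post = (hyper.d0 * hyper.s02 + 10 * fit.loc[g, "s2"]) / (hyper.d0 + 10)
            t = fit.loc[g, "logfc"] / np.sqrt(s2_post * (1 / 6 + 1 / 6))
            p = 2 * stats.t.sf(abs(t), df=10 + hyper.d0)
            assert tab.loc[g, "t"] == pytest.approx(t, abs=1e-10)
            assert tab.loc[g, "p"] == pytest.approx(p, abs=1e-10)

    def test_zero_variance_flagged(self):
        design = _design(2, 2)
        expr = pd.DataFrame([[0.0, 0.0, 1.0, 1.0]], index=["g"], columns=design.sample_ids)
        fit = fit_group_model(expr, design)
        tab = moderated_t(fit, EbHyperparams(d0=0.0, s02=1.0), 2, 2)
        assert np.isinf(tab.loc["g", "t"]) and tab.loc["g", "p"] == 0.0
        assert tab.loc["g", "zero_variance"]


@pytest.mark.parametrize(
    "p,expected",
    [
        # printed platform multiplier 22,268 reproduces reported adjusted values
        (8.88e-10, 1.98e-05),
        (1.87e-10, 4.16e-06),
        (1.41e-06, 3.14e-02),
    ],
)
def test_bonferroni_platform_examples(p, expected):
    adj = bonferroni(np.array([p]), m=22_268)[0]
    assert float(f"{adj:.2e}") == pytest.approx(expected, rel=1e-9)


class TestBonferroni:
    def test_caps_at_one(self):
        assert bonferroni(np.array([0.5]), m=10)[0] == 1.0

    def test_rejects_invalid_p_and_small_m(self):
        with pytest.raises(ValueError):
            bonferroni(np.array([1.5]))
        with pytest.raises(ValueError):
            bonferroni(np.array([0.1, 0.2]), m=1)

    def test_monotone_and_never_smaller(self):
        rng = np.random.default_rng(4)
        p = np.sort(rng.uniform(size=50))
        adj = bonferroni(p, m=100)
        assert np.all(np.diff(adj) >= 0)
        assert np.all(adj >= p)


class TestCollapseToGenes:
    def test_min_raw_p_rule(self):
        tab = pd.DataFrame(
            {"p": [1e-8, 1e-3], "logfc": [1.0, 2.0]}, index=["pr1", "pr2"]
        )
        out = collapse_to_genes(tab, {"pr1": "G", "pr2": "G"})
        assert list(out.index) == ["G"]
        assert out.loc["G", "probe"] == "pr1"

    def test_identity_mapping_preserves_rows(self):
        tab = pd.DataFrame({"p": [0.1, 0.2], "logfc": [1, -1]}, index=["a", "b"])
        out = collapse_to_genes(tab, {"a": "a", "b": "b"})
        assert sorted(out.index) == ["a", "b"]

    def test_unmapped_probe_dropped_with_warning(self):
        tab = pd.DataFrame({"p": [0.1, 0.2]}, index=["a", "zz"])
        with pytest.warns(UserWarning, match="without a gene mapping"):
            out = collapse_to_genes(tab, {"a": "a"})
        assert list(out.index) == ["a"]

    def test_generated_probe_mode_collapses_exactly(self):
        expr, design, truth, _, _ = simulate_cmap_like(
            n_background=30, n_signature=10, n_control=10, n_perturbed=10,
            probes_per_gene=3, seed=8,
        )
        tab = run_diffexpr(expr, design, probe2gene=truth.manifest["probe2gene"])
        assert tab.shape[0] == 30 + 10 + 13


class TestSelectSignature:
    def test_alpha_extremes(self):
        tab = pd.DataFrame({"adjusted_p": [0.01, 0.5], "logfc": [1.0, -1.0]},
                           index=["u", "d"])
        assert select_signature(tab, 0.0) == ([], [])
        up, down = select_signature(tab, 1.0 + 1e-9)
        assert up == ["u"] and down == ["d"]

    def test_recovers_planted_signature(self):
        expr, design, truth, _, _ = simulate_cmap_like(
            n_background=300, n_signature=40, n_control=250, n_perturbed=250,
            delta_range=(0.2, 0.32), seed=9, shift_sem=False,
        )
        tab = run_diffexpr(expr, design)
        up, down = select_signature(tab, 0.05)
        hits = set(up) | set(down)
        true = set(truth.signature_genes)
        recall = len(hits & true) / len(true)
        false_hits = hits - true - set(truth.sem.nodes)
        assert recall >= 0.9
        assert not false_hits


def test_moderated_t_matches_limma_oracle(tmp_path):
    """Cross-check the full moderated-t stack against Bioconductor limma."""
    rng = np.random.default_rng(3)
    d0, s02, m, n = 4.0, 0.6, 400, 12
    s2_true = s02 * d0 / rng.chisquare(d0, size=m)
    X = rng.standard_normal((m, n)) * np.sqrt(s2_true)[:, None] + 7
    expr = pd.DataFrame(X, index=[f"g{i}" for i in range(m)],
                        columns=[f"s{i}" for i in range(n)])
    fix = tmp_path / "fix.tsv"
    out = tmp_path / "out.tsv"
    expr.to_csv(fix, sep="\t")
    r_code = f"""
    suppressMessages(library(limma))
    x <- as.matrix(read.delim("{fix}", row.names=1))
    fit <- eBayes(lmFit(x, cbind(1, c(rep(0,5), rep(1,7)))))
    out <- data.frame(t=fit$t[,2], p=fit$p.value[,2], d0=fit$df.prior, s02=fit$s2.prior)
    write.table(format(out, digits=15), "{out}", sep="\\t", quote=FALSE)
    """
    res = subprocess.run(["Rscript", "-e", r_code], capture_output=True, text=True)
    if res.returncode != 0:
        pytest.fail(f"Rscript failed: {res.stderr[-500:]}")
    ref = pd.read_csv(out, sep="\t")
    design = _design(5, 7)
    fit = fit_group_model(expr, design)
    hyper = estimate_eb_hyperparams(fit["s2"].to_numpy(), float(n - 2))
    tab = moderated_t(fit, hyper, 5, 7)
    assert hyper.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-8)
    assert hyper.s02 == pytest.approx(ref["s02"].iloc[0], rel=1e-8)
    np.testing.assert_allclose(tab["t"], ref["t"], rtol=1e-8)
    np.testing.assert_allclose(tab["p"], ref["p"], rtol=1e-6)
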