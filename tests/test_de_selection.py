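"""Moderated-t statistics (checked against the ordinary t, a null
calibration, and Bioconductor limma) and the selection-funnel arithmetic."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mgti.de_selection import (
    DEResult,
    ThresholdSet,
    apply_funnel,
    compute_frequencies,
    fit_moderated_t,
    merge_datasets,
    results_to_frame,
)
from mgti.errors import ConfigurationError, DomainError
from mgti.synthetic_data import ExpressionMatrix, SimulationConfig, simulate_expression


def _matrix(values, n1, n2):
    values = np.asarray(values, dtype=float)
    samples = [f"c{i}" for i in range(n1)] + [f"t{i}" for i in range(n2)]
    groups = {s: ("control" if s.startswith("c") else "case") for s in samples}
    genes = [f"g{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(genes, samples, values, groups)


class TestFitModeratedT:
    def test_identical_group_means_give_null_result(self):
        row = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        expr = _matrix([row, [0, 1, 0, 1, 0, 1]], 3, 3)
        res = fit_moderated_t(expr, ("control", "case"))
        assert res[0].t_mod == pytest.approx(0.0, abs=1e-12)
        assert res[0].p_value == pytest.approx(1.0)

    def test_zero_prior_df_recovers_ordinary_t(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(30, 12))
        values[:5, 6:] += 1.5
        expr = _matrix(values, 6, 6)
        res = fit_moderated_t(expr, ("control", "case"), prior_df=0.0)
        for i, r in enumerate(res):
            t_ref, p_ref = stats.ttest_ind(values[i, 6:], values[i, :6], equal_var=True)
            assert r.t_mod == pytest.approx(t_ref, rel=1e-10)
            assert r.p_value == pytest.approx(p_ref, rel=1e-10)
            assert r.df_total == 10

    def test_shrinkage_pulls_extreme_variances_together(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(200, 10))
        values[0] *= 0.05  # tiny-variance gene
        expr = _matrix(values, 5, 5)
        mod = fit_moderated_t(expr, ("control", "case"))
        plain = fit_moderated_t(expr, ("control", "case"), prior_df=0.0)
        # moderation damps the tiny-variance gene's |t|
        assert abs(mod[0].t_mod) < abs(plain[0].t_mod)
        assert mod[0].df_total > 8

    def test_constant_gene_flagged_p_one(self):
        values = np.vstack([np.full(8, 3.0), np.random.default_rng(2).normal(size=8)])
        expr = _matrix(values, 4, 4)
        res = fit_moderated_t(expr, ("control", "case"), prior_df=0.0)
        assert res[0].p_value == 1.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ConfigurationError):
            _matrix(np.zeros((3, 3)), 2, 1)

    def test_null_calibration_at_p1(self):
        # pure-null simulations: rejection fraction at 0.01 within MC noise
        fracs = []
        for seed in range(5):
            cfg = SimulationConfig(
                n_genes=2000, n_samples_per_group=5, frac_de=0.0, seed=seed
            )
            expr, _ = simulate_expression(cfg)
            res = fit_moderated_t(expr, ("group1", "group2"))
            fracs.append(np.mean([r.p_value < 0.01 for r in res]))
        assert np.mean(fracs) == pytest.approx(0.01, abs=0.005)

    def test_matches_limma_oracle(self, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not on PATH; limma cross-check cannot run")
        rng = np.random.default_rng(42)
        values = rng.normal(size=(60, 10))
        values[:8, 5:] += 2.0
        expr = _matrix(values, 5, 5)
        res = fit_moderated_t(expr, ("control", "case"))
        mat_path = tmp_path / "expr.tsv"
        expr.to_frame().to_csv(mat_path, sep="\t")
        script = textwrap.dedent(
            f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.delim("{mat_path}", row.names = 1))
            design <- cbind(Intercept = 1, case = rep(c(0, 1), each = 5))
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(t = fit$t[, "case"], p = fit$p.value[, "case"],
                              df0 = fit$df.prior, s02 = fit$s2.prior)
            write.csv(out, "{tmp_path}/limma.csv")
            """
        )
        (tmp_path / "run.R").write_text(script)
        subprocess.run(
            ["Rscript", str(tmp_path / "run.R")], check=True, capture_output=True
        )
        ref = pd.read_csv(tmp_path / "limma.csv", index_col=0)
        ours = results_to_frame(res).set_index("gene_id")
        np.testing.assert_allclose(ours["t"], ref["t"], rtol=1e-6)
        np.testing.assert_allclose(ours["p"], ref["p"], rtol=1e-6)


class TestThresholdSet:
    def test_default_ordering(self):
        t = ThresholdSet()
        assert t.as_tuple() == (0.01, 0.001, 0.0001)

    @pytest.mark.parametrize("args", [(0.001, 0.01, 0.0001), (0.5, 0.5, 0.1), (1.2, 0.1, 0.01)])
    def test_disordered_rejected(self, args):
        with pytest.raises(ConfigurationError):
            ThresholdSet(*args)


def _result(gene, p):
    return DEResult(gene_id=gene, log_fold_change=1.0, t_mod=3.0, p_value=p, df_total=10)


class TestApplyFunnel:
    def test_nothing_passes_gives_zero_rows(self):
        results = [_result("g1", 0.5), _result("g2", 0.9)]
        funnel = apply_funnel(results, ThresholdSet(), {"g1": 1})
        for lvl in funnel.levels.values():
            assert (lvl.total, lvl.not_duplicated, lvl.annotated, lvl.selected) == (0, 0, 0, 0)

    def test_duplicate_symbols_collapse_keeping_smallest_p(self):
        results = [_result(f"g{i}", 1e-5) for i in range(10)]
        symbols = {f"g{i}": f"s{i}" for i in range(10)}
        symbols["g9"] = "s0"  # g9 duplicates g0's symbol
        annot = {f"g{i}": 1 for i in range(10)}
        funnel = apply_funnel(results, ThresholdSet(), annot, symbols=symbols)
        lvl = funnel.levels[0.0001]
        assert lvl.total == 10
        assert lvl.not_duplicated == 9

    def test_rows_monotone_and_thresholds_nested(self, sim_bundle):
        expr = sim_bundle["expr"]
        res = fit_moderated_t(expr, ("group1", "group2"))
        funnel = apply_funnel(res, ThresholdSet(), sim_bundle["annot"])
        sel = {}
        for p_cut, lvl in funnel.levels.items():
            assert lvl.total >= lvl.not_duplicated >= lvl.annotated >= lvl.selected
            sel[p_cut] = set(lvl.selected_gene_ids)
        assert sel[0.0001] <= sel[0.001] <= sel[0.01]

    def test_empty_annotation_warns_not_errors(self, caplog):
        results = [_result("g1", 1e-6)]
        funnel = apply_funnel(results, ThresholdSet(), {})
        assert funnel.levels[0.01].annotated == 0

    def test_planted_de_total_within_binomial_bounds(self):
        cfg = SimulationConfig(
            n_genes=2000, n_samples_per_group=10, frac_de=0.05, effect_size=3.0,
            noise_sd=1.0, seed=21,
        )
        expr, truth = simulate_expression(cfg)
        res = fit_moderated_t(expr, ("group1", "group2"))
        funnel = apply_funnel(res, ThresholdSet(), {g: 1 for g in expr.gene_ids})
        total = funnel.levels[0.0001].total
        # power at delta=3, sd=1, n=10/group, alpha=1e-4 is essentially 1;
        # expected false positives 1900 * 1e-4
        n_de = len(truth.de_gene_ids)
        expected = n_de + (cfg.n_genes - n_de) * 1e-4
        assert abs(total - expected) < 3 * np.sqrt(n_de * 0.05 + 0.19) + 3


class TestMergeAndFrequencies:
    def _funnel_from(self, gene_lists):
        results = [_result(g, 1e-6) for g in gene_lists]
        annot = {g: 1 for g in gene_lists}
        return apply_funnel(results, ThresholdSet(), annot)

    def test_single_funnel_identity(self):
        f = self._funnel_from([f"g{i}" for i in range(5)])
        merged = merge_datasets([f])
        assert merged.levels[0.0001].selected_gene_ids == f.levels[0.0001].selected_gene_ids

    def test_disjoint_lists_union(self):
        f1 = self._funnel_from([f"a{i}" for i in range(5)])
        f2 = self._funnel_from([f"b{i}" for i in range(5)])
        merged = merge_datasets([f1, f2])
        lvl = merged.levels[0.0001]
        assert lvl.selected == 10
        assert all(c == 1 for c in lvl.occurrence.values())

    def test_shared_genes_counted(self):
        f1 = self._funnel_from(["g1", "g2", "g3", "x1", "x2"])
        f2 = self._funnel_from(["g1", "g2", "g3", "y1", "y2"])
        merged = merge_datasets([f1, f2])
        lvl = merged.levels[0.0001]
        assert lvl.selected == 7
        assert {g: c for g, c in lvl.occurrence.items() if c == 2} == {
            "g1": 2, "g2": 2, "g3": 2
        }

    def test_frequency_values_and_conservation(self):
        f1 = self._funnel_from(["g1", "g2"])
        f2 = self._funnel_from(["g1"])
        merged = merge_datasets([f1, f2])
        freq = compute_frequencies(merged, n_sources=5)
        assert freq["g1"] == pytest.approx(0.4)
        assert freq["g2"] == pytest.approx(0.2)
        occ = merged.levels[0.0001].occurrence
        assert sum(freq.values()) == pytest.approx(sum(occ.values()) / 5)

    def test_gene_in_all_sources_gets_one(self):
        funnels = [self._funnel_from(["g1"]) for _ in range(5)]
        merged = merge_datasets(funnels)
        assert compute_frequencies(merged, 5)["g1"] == pytest.approx(1.0)

    def test_empty_merge_rejected(self):
        with pytest.raises(DomainError):
            merge_datasets([])
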