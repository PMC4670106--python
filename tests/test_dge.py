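"""NB-Wald differential expression, BH adjustment, and DE calling."""

import numpy as np
import pandas as pd
import pytest

from hdbrain import dge, preprocess, simulate
from hdbrain.errors import InputError


def bh_bruteforce(p):
    """Independent BH oracle: padj_i = min over j with p_j >= p_i of m*p_(j)/j."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    out = np.empty(m)
    for i in range(m):
        out[i] = min(min(m * sorted_p[j] / (j + 1) for j in range(i, m)), 1.0)
    result = np.empty(m)
    result[order] = out
    return result


class TestBhAdjust:
    def test_single_value_identity(self):
        np.testing.assert_allclose(dge.bh_adjust([0.05]), [0.05])

    def test_analytic_step_up(self):
        np.testing.assert_allclose(dge.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        p = rng.random(100)
        np.testing.assert_allclose(dge.bh_adjust(p), bh_bruteforce(p),
                                   rtol=1e-12)

    def test_missing_values_propagate_and_shrink_m(self):
        p = np.array([0.01, np.nan, 0.02])
        out = dge.bh_adjust(p)
        assert np.isnan(out[1])
        # m=2, not 3: padj = [0.02, 0.02]
        np.testing.assert_allclose(out[[0, 2]], [0.02, 0.02])

    def test_monotone_on_sorted_input(self):
        rng = np.random.default_rng(1)
        p = np.sort(rng.random(50))
        out = dge.bh_adjust(p)
        assert (np.diff(out) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            dge.bh_adjust([0.5, 1.5])


class TestNbWaldTest:
    def test_doubled_counts_give_unit_lfc(self):
        rng = np.random.default_rng(2)
        base = rng.integers(50, 500, size=30)
        cols = [f"h{i}" for i in range(6)] + [f"c{i}" for i in range(6)]
        counts = pd.DataFrame(
            np.column_stack([np.tile(base * 2, (6, 1)).T,
                             np.tile(base, (6, 1)).T]),
            index=[f"g{i}" for i in range(30)], columns=cols)
        samples = pd.DataFrame({
            "condition": ["HD"] * 6 + ["control"] * 6,
            "age_of_death": 60, "rin": 8.0}, index=cols)
        factors = pd.Series(1.0, index=cols)
        table = dge.nb_wald_test(counts, samples, factors=factors,
                                 dispersion=0.05)
        np.testing.assert_allclose(table["lfc"], 1.0, atol=0.02)

    def test_lfc_sign_agrees_with_group_means(self, small_cohort):
        # with no covariate structure (constant age and RIN), the adjusted
        # fold change must point the same way as the raw group means
        _, counts, samples, _ = small_cohort
        balanced = samples.copy()
        balanced["age_of_death"] = 60
        balanced["rin"] = 8.0
        filtered, _ = preprocess.filter_low_signal(counts,
                                                   samples["condition"])
        table = dge.nb_wald_test(filtered, balanced)
        sel = (table["case_mean"] > 0) & (table["control_mean"] > 0) & \
            table["lfc"].notna() & (table["lfc"].abs() > 0.05)
        diff_sign = np.sign(table.loc[sel, "case_mean"]
                            - table.loc[sel, "control_mean"])
        agree = (np.sign(table.loc[sel, "lfc"]) == diff_sign).mean()
        assert agree > 0.98

    def test_de_calls_invariant_under_column_permutation(self, small_cohort):
        _, counts, samples, _ = small_cohort
        groups = samples["condition"]
        filtered, _ = preprocess.filter_low_signal(counts, groups)
        sub = filtered.iloc[:120]
        table = dge.nb_wald_test(sub, samples)
        perm = sub.sample(frac=1.0, axis=1, random_state=3)
        table_perm = dge.nb_wald_test(perm, samples.loc[perm.columns])
        assert dge.call_de(table) == dge.call_de(table_perm)

    def test_type_one_error_near_nominal_small(self):
        cfg = simulate.SimulationConfig(n_genes=300, n_cases=10, n_controls=12,
                                        de_fraction=0.0, seed=9)
        counts, samples, _ = simulate.simulate_counts(cfg)
        filtered, _ = preprocess.filter_low_signal(counts,
                                                   samples["condition"])
        table = dge.nb_wald_test(filtered, samples)
        frac = (table["p"].dropna() < 0.05).mean()
        assert frac < 0.12

    def test_power_regression_constant(self):
        # frozen by simulation: power ~ 1.0 at lfc=1, base_mean=100,
        # alpha=0.1, 20 vs 49 (500 replicates)
        rng = np.random.default_rng(42)
        n_case, n_ctrl, alpha = 20, 49, 0.1
        X = np.column_stack([np.ones(n_case + n_ctrl),
                             np.r_[np.ones(n_case), np.zeros(n_ctrl)]])
        offset = np.zeros(n_case + n_ctrl)
        hits = 0
        for _ in range(500):
            mu = np.r_[np.full(n_case, 200.0), np.full(n_ctrl, 100.0)]
            y = rng.poisson(rng.gamma(1 / alpha, alpha * mu))
            _, _, p = dge.nb_glm_wald(y, X, offset, alpha, 1)
            hits += p < 0.05
        assert hits / 500 >= 0.99


class TestCallDe:
    def test_no_significant_genes_gives_empty_list(self):
        table = pd.DataFrame({"p": [0.5, 0.9], "padj": [1.0, 1.0],
                              "lfc": [1.0, -1.0]},
                             index=pd.Index(["a", "b"], name="gene_id"))
        assert dge.call_de(table) == []

    def test_tie_break_by_abs_lfc_then_gene_id(self):
        table = pd.DataFrame({
            "p": [0.001, 0.001, 0.001, 0.002],
            "padj": [0.004] * 4,
            "lfc": [1.0, -2.0, 1.0, 3.0]},
            index=pd.Index(["gB", "gC", "gA", "gD"], name="gene_id"))
        assert dge.call_de(table) == ["gC", "gA", "gB", "gD"]

    def test_recall_of_planted_de_genes(self):
        cfg = simulate.SimulationConfig(n_genes=300, n_cases=20, n_controls=20,
                                        lfc_scale=1.5, exclusive_fraction=0.0,
                                        seed=5)
        counts, samples, truth = simulate.simulate_counts(cfg)
        groups = samples["condition"]
        filtered, _ = preprocess.filter_low_signal(counts, groups)
        trimmed = preprocess.trim_outlier_counts(filtered, groups)
        called = set(dge.call_de(dge.nb_wald_test(trimmed, samples)))
        planted = set(truth.index[truth["is_de"]]) & set(filtered.index)
        recall = len(called & planted) / len(planted)
        assert recall > 0.8


def test_lfc_agrees_with_independent_nb_implementation():
    """Cross-check fold changes against pydeseq2 on a small simulation."""
    pydeseq2 = pytest.importorskip("pydeseq2")
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    cfg = simulate.SimulationConfig(n_genes=150, n_cases=10, n_controls=10,
                                    lfc_scale=1.0, exclusive_fraction=0.0,
                                    seed=13)
    counts, samples, _ = simulate.simulate_counts(cfg)
    groups = samples["condition"]
    filtered, _ = preprocess.filter_low_signal(counts, groups)
    table = dge.nb_wald_test(filtered, samples)

    meta = samples[["condition"]].copy()
    dds = DeseqDataSet(counts=filtered.T, metadata=meta,
                       design="~condition", quiet=True)
    dds.deseq2()
    stats = DeseqStats(dds, contrast=["condition", "HD", "control"],
                       quiet=True)
    stats.summary()
    merged = table.join(stats.results_df["log2FoldChange"], how="inner").dropna(
        subset=["lfc", "log2FoldChange"])
    r = np.corrcoef(merged["lfc"], merged["log2FoldChange"])[0, 1]
    assert r > 0.95
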