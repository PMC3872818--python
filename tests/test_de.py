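"""Differential-expression statistics against hand-computed and independent
oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from heatnca import (AnnotationTable, annotate_genes, assemble_union,
                     interaction_anova, log2_fold_change, per_ecotype_t_test,
                     simulate_ecotype_experiment, summarize_counts)
from heatnca.de import de_records_all_ecotypes

from conftest import make_expression


class TestLog2FoldChange:
    def test_exact_mean_difference(self):
        expr = make_expression({("A", "heat"): [[4, 4, 4]],
                                ("A", "control"): [[2, 2, 2]]})
        assert log2_fold_change(expr, "A").iloc[0] == pytest.approx(2.0)

    def test_identical_arms_give_zero(self):
        expr = make_expression({("A", "heat"): [[1.3, 2.1]],
                                ("A", "control"): [[1.3, 2.1]]})
        assert log2_fold_change(expr, "A").iloc[0] == 0.0

    def test_recovers_planted_effect_within_sampling_bound(self):
        expr, truth = simulate_ecotype_experiment(
            400, ["A", "B"], 3, 0.5, 1.5, 0.3, seed=12)
        fc = log2_fold_change(expr, "A").to_numpy()
        bound = 3 * 0.3 * np.sqrt(2 / 3)
        assert np.all(np.abs(fc - truth.effect_sizes[:, 0]) <= bound)

    def test_unknown_ecotype_and_missing_arm(self):
        expr = make_expression({("A", "heat"): [[1, 2]],
                                ("A", "control"): [[1, 2]]})
        with pytest.raises(ValueError):
            log2_fold_change(expr, "Z")
        heat_only = make_expression({("A", "heat"): [[1, 2]]})
        with pytest.raises(ValueError):
            log2_fold_change(heat_only, "A")


class TestPerEcotypeTTest:
    def test_welch_textbook_example(self):
        # heat (4,5,6) vs control (1,2,3): t = 3/sqrt(2/3), Satterthwaite df 4
        expr = make_expression({("A", "heat"): np.array([[4, 5, 6.]]),
                                ("A", "control"): np.array([[1, 2, 3.]])})
        rec = per_ecotype_t_test(expr, "A", alpha=0.05, equal_var=False)
        t_manual = 3.0 / np.sqrt(1 / 3 + 1 / 3)
        p_manual = 2 * stats.t.sf(t_manual, 4.0)
        assert t_manual == pytest.approx(3.674234614)
        assert rec["t_pvalue"].iloc[0] == pytest.approx(p_manual, rel=1e-12)
        assert rec["t_pvalue"].iloc[0] == pytest.approx(0.021311641, rel=1e-6)
        assert rec.loc[0, "direction"] == "up"
        assert bool(rec.loc[0, "significant"])

    def test_constant_probes_get_p_one(self):
        expr = make_expression({("A", "heat"): [[5, 5, 5]],
                                ("A", "control"): [[5, 5, 5]]})
        rec = per_ecotype_t_test(expr, "A")
        assert rec["t_pvalue"].iloc[0] == 1.0
        assert not rec["significant"].any()
        assert rec["direction"].iloc[0] == ""

    def test_direction_matches_fold_change_sign(self):
        expr, _ = simulate_ecotype_experiment(300, ["A"], 3, 0.3, 2.0, 0.3, seed=3)
        rec = per_ecotype_t_test(expr, "A")
        up = rec["direction"] == "up"
        down = rec["direction"] == "down"
        assert (rec.loc[up, "log2fc"] > 0).all()
        assert (rec.loc[down, "log2fc"] < 0).all()

    @pytest.mark.parametrize("alpha_pair", [(0.001, 0.01), (0.01, 0.05)])
    def test_lowering_alpha_never_adds_genes(self, alpha_pair):
        lo, hi = alpha_pair
        expr, _ = simulate_ecotype_experiment(500, ["A"], 3, 0.2, 1.5, 0.3, seed=5)
        sig_lo = set(per_ecotype_t_test(expr, "A", lo).query("significant")["gene_id"])
        sig_hi = set(per_ecotype_t_test(expr, "A", hi).query("significant")["gene_id"])
        assert sig_lo <= sig_hi

    def test_requires_two_replicates(self):
        expr = make_expression({("A", "heat"): [[1, 2]], ("A", "control"): [[3]]})
        with pytest.raises(ValueError):
            per_ecotype_t_test(expr, "A")


class TestInteractionAnova:
    def test_planted_interaction_is_detected(self):
        rng = np.random.default_rng(0)
        base = rng.normal(7, 1, size=5)
        cells = {}
        for eco, effect in (("A", 2.0), ("B", 0.0)):
            cells[(eco, "control")] = base[:, None] + rng.normal(0, 0.1, (5, 3))
            cells[(eco, "heat")] = (base[:, None] + effect
                                    + rng.normal(0, 0.1, (5, 3)))
        expr = make_expression(cells)
        pv = interaction_anova(expr)
        assert (pv < 1e-4).all()

    def test_additive_truth_yields_uniform_pvalues(self):
        # same treatment effect in every ecotype -> interaction term null
        rng = np.random.default_rng(1)
        n = 4000
        base = rng.normal(7, 1, size=n)
        cells = {}
        for eco in ("A", "B", "C"):
            cells[(eco, "control")] = base[:, None] + rng.normal(0, 0.3, (n, 3))
            cells[(eco, "heat")] = base[:, None] + 1.0 + rng.normal(0, 0.3, (n, 3))
        expr = make_expression(cells)
        pv = interaction_anova(expr)
        frac = float((pv <= 0.01).mean())
        se = np.sqrt(0.01 * 0.99 / n)
        assert abs(frac - 0.01) <= 3 * se

    def test_agrees_with_statsmodels_ols(self):
        import statsmodels.formula.api as smf

        expr, _ = simulate_ecotype_experiment(12, ["A", "B", "C"], 3,
                                              0.5, 1.5, 0.3, seed=21)
        pv = interaction_anova(expr)
        import statsmodels.api as sm
        for g in range(12):
            df = expr.design.copy()
            df["y"] = expr.values[g]
            fit = smf.ols("y ~ C(ecotype) * C(treatment)", data=df).fit()
            table = sm.stats.anova_lm(fit, typ=2)
            p_ref = table.loc["C(ecotype):C(treatment)", "PR(>F)"]
            assert pv.iloc[g] == pytest.approx(p_ref, rel=1e-8)

    def test_preconditions(self):
        single = make_expression({("A", "heat"): [[1, 2]],
                                  ("A", "control"): [[1, 2]]})
        with pytest.raises(ValueError):
            interaction_anova(single)
        missing_cell = make_expression({("A", "heat"): [[1, 2]],
                                        ("A", "control"): [[1, 2]],
                                        ("B", "heat"): [[1, 2]]})
        with pytest.raises(ValueError, match="'B'.*'control'"):
            interaction_anova(missing_cell)
        unbalanced = make_expression({("A", "heat"): [[1, 2, 3]],
                                      ("A", "control"): [[1, 2]],
                                      ("B", "heat"): [[1, 2]],
                                      ("B", "control"): [[1, 2]]})
        with pytest.raises(ValueError, match="unbalanced"):
            interaction_anova(unbalanced)


def _brute_force_summary(records: pd.DataFrame):
    """Independent recount of the DE record list with plain loops."""
    sig = [(r.gene_id, r.ecotype, r.direction)
           for r in records.itertuples() if r.significant]
    genes = {}
    for g, e, _ in sig:
        genes.setdefault(g, set()).add(e)
    unique = {g for g, es in genes.items() if len(es) == 1}
    per_eco = {}
    for g, e, d in sig:
        row = per_eco.setdefault(e, dict.fromkeys(
            ["total", "total_up", "total_down", "unique_total",
             "unique_up", "unique_down"], 0))
        row["total"] += 1
        if d == "up":
            row["total_up"] += 1
        elif d == "down":
            row["total_down"] += 1
        if g in unique:
            row["unique_total"] += 1
            if d == "up":
                row["unique_up"] += 1
            elif d == "down":
                row["unique_down"] += 1
    return per_eco, len(genes), len(unique)


class TestUnionAndSummary:
    def test_single_ecotype_all_unique(self):
        expr, _ = simulate_ecotype_experiment(300, ["A"], 3, 0.2, 2.0, 0.3, seed=2)
        records = de_records_all_ecotypes(expr)
        summary, membership = assemble_union(records)
        assert summary.unified_count == summary.unique_overall_count
        assert all(len(v) == 1 for v in membership.values())

    def test_gene_shared_between_two_ecotypes_is_not_unique(self):
        records = pd.DataFrame({
            "gene_id": ["g1", "g1", "g2"],
            "ecotype": ["A", "B", "A"],
            "log2fc": [1.0, 1.0, -1.0],
            "t_pvalue": [0.001, 0.001, 0.001],
            "direction": ["up", "up", "down"],
            "significant": [True, True, True],
        })
        summary, membership = assemble_union(records)
        assert summary.unified_count == 2
        assert summary.unique_overall_count == 1
        assert membership["g1"] == {"A", "B"}
        assert summary.per_ecotype.loc["A", "unique_total"] == 1  # only g2

    def test_counts_match_brute_force_recount(self):
        expr, _ = simulate_ecotype_experiment(
            800, ["A", "B", "C", "D"], 3, 0.1, 1.5, 0.3, seed=9)
        records = de_records_all_ecotypes(expr)
        summary, membership = assemble_union(records)
        ref_eco, ref_unified, ref_unique = _brute_force_summary(records)
        assert summary.unified_count == ref_unified
        assert summary.unique_overall_count == ref_unique
        for eco, row in summary.per_ecotype.iterrows():
            if eco in ref_eco:
                for col in row.index:
                    assert row[col] == ref_eco[eco][col], (eco, col)
        for eco in summary.per_ecotype.index:
            row = summary.per_ecotype.loc[eco]
            assert row["total"] == row["total_up"] + row["total_down"]
            assert row["unique_total"] <= row["total"]

    def test_empty_significant_set_tabulates_zeros(self):
        records = pd.DataFrame({
            "gene_id": ["g1"], "ecotype": ["A"], "log2fc": [0.1],
            "t_pvalue": [0.9], "direction": ["up"], "significant": [False]})
        summary = summarize_counts(records, {})
        assert summary.unified_count == 0
        assert (summary.per_ecotype.to_numpy() == 0).all()


class TestAnnotateGenes:
    def test_counts_and_unannotated(self):
        annot = AnnotationTable(tags={"g1": frozenset({"TF"}),
                                      "g2": frozenset({"TF", "HSP"}),
                                      "g3": frozenset({"TE"})})
        table, counts = annotate_genes(["g1", "g2", "g4", "g5"], annot)
        assert counts["TF"] == 2 and counts["HSP"] == 1 and counts["TE"] == 0
        assert counts["unannotated"] == 2
        assert list(table["gene_id"]) == ["g1", "g2", "g4", "g5"]

    def test_empty_list(self):
        table, counts = annotate_genes([], AnnotationTable(tags={}))
        assert table.empty and counts["TF"] == 0

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(50)]
        tags = {g: frozenset(rng.choice(["TF", "TE", "HSP"],
                                        size=rng.integers(0, 3), replace=False))
                for g in genes}
        annot = AnnotationTable(tags=tags)
        subset = genes[::3]
        _, counts = annotate_genes(subset, annot)
        for tag in ("TF", "TE", "HSP"):
            assert counts[tag] == sum(1 for g in subset if tag in tags[g])
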