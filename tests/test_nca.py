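"""Identifiability checking and the constrained ALS fit.

The structural-rank oracle used against ``check_identifiability`` is a
maximum-bipartite-matching computation (generic rank of a zero pattern
equals the maximum matching between rows and columns over its nonzeros) —
an independent route from the implementation's random-instantiation
numerical rank.
"""

import numpy as np
import pytest

import networkx as nx

from heatnca import (ConnectivityPattern, check_identifiability, fit_nca,
                     generate_connectivity, normalize_model,
                     pattern_from_mask, recovery_metrics,
                     reduce_to_identifiable, simulate_nca_instance)
from heatnca.nca import aligned_tfa_correlations


def structural_rank(mask: np.ndarray) -> int:
    """Generic rank of a sparsity pattern via maximum bipartite matching."""
    g = nx.Graph()
    rows = [("r", i) for i in range(mask.shape[0])]
    g.add_nodes_from(rows, bipartite=0)
    g.add_nodes_from((("c", j) for j in range(mask.shape[1])), bipartite=1)
    for i, j in zip(*np.nonzero(mask)):
        g.add_edge(("r", int(i)), ("c", int(j)))
    matching = nx.bipartite.maximum_matching(g, top_nodes=rows)
    return len(matching) // 2


def oracle_report(pattern: ConnectivityPattern, n_conditions: int):
    """Criteria 1-3 evaluated with the matching-based structural rank."""
    mask = pattern.mask()
    c1 = (pattern.n_tfs <= pattern.n_genes
          and structural_rank(mask) == pattern.n_tfs)
    c2 = []
    for l in range(pattern.n_tfs):
        reduced = mask[~mask[:, l]][:, np.arange(pattern.n_tfs) != l]
        c2.append(structural_rank(reduced) == pattern.n_tfs - 1)
    return c1, tuple(c2), n_conditions >= pattern.n_tfs


class TestCheckIdentifiability:
    def test_identity_pattern_passes_all(self):
        pat = pattern_from_mask(np.eye(3, dtype=bool))
        rep = check_identifiability(pat, n_conditions=3)
        assert rep.identifiable
        assert rep.criterion1 and all(rep.criterion2) and rep.criterion3

    def test_duplicate_columns_fail_criterion2_for_both(self):
        mask = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1], [0, 0, 1]], bool)
        rep = check_identifiability(pattern_from_mask(mask), n_conditions=3)
        assert rep.criterion2[0] is False and rep.criterion2[1] is False
        assert not rep.identifiable

    def test_criterion3_fails_when_conditions_below_tfs(self):
        pat = generate_connectivity(40, 6, 0.25, seed=3)
        rep = check_identifiability(pat, n_conditions=5)
        assert not rep.criterion3 and not rep.identifiable
        assert check_identifiability(pat, n_conditions=6).criterion3

    def test_agrees_with_matching_oracle_on_random_patterns(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            n_genes = int(rng.integers(3, 21))
            n_tfs = int(rng.integers(1, min(6, n_genes) + 1))
            mask = rng.random((n_genes, n_tfs)) < rng.uniform(0.15, 0.6)
            if not mask.any():
                continue
            pat = pattern_from_mask(mask)
            n_cond = int(rng.integers(1, 10))
            rep = check_identifiability(pat, n_cond)
            c1, c2, c3 = oracle_report(pat, n_cond)
            assert (rep.criterion1, rep.criterion2, rep.criterion3) == (c1, c2, c3)


class TestReduceToIdentifiable:
    def test_identifiable_pattern_unchanged(self):
        pat = generate_connectivity(30, 4, 0.3, seed=1)
        reduced, removed = reduce_to_identifiable(pat)
        assert removed == [] and reduced == pat

    def test_duplicate_column_resolved_by_removal(self):
        mask = np.array([[1, 1, 0], [1, 1, 0], [1, 1, 0], [0, 0, 1]], bool)
        reduced, removed = reduce_to_identifiable(pattern_from_mask(mask))
        assert len(removed) == 1 and removed[0] in (0, 1)
        rep = check_identifiability(reduced, n_conditions=reduced.n_tfs)
        assert rep.criterion1 and all(rep.criterion2)

    def test_empty_pattern_returns_empty_never_raises(self):
        pat = ConnectivityPattern(3, 2, ())
        reduced, removed = reduce_to_identifiable(pat)
        assert reduced.n_entries == 0
        assert sorted(removed) == [0, 1]


class TestFitNca:
    def test_noise_free_exact_recovery(self, small_pattern, noisefree_truth):
        model = fit_nca(noisefree_truth.expression, small_pattern, seed=3)
        metrics = recovery_metrics(model, noisefree_truth)
        assert metrics["relative_residual"] < 1e-6
        assert metrics["tfa_abs_corr"].min() >= 0.999
        assert model.converged

    def test_support_constraint_is_exact(self, small_pattern, noisefree_truth):
        model = fit_nca(noisefree_truth.expression, small_pattern, seed=3)
        off_support = ~small_pattern.mask()
        assert np.all(model.a_hat[off_support] == 0.0)

    def test_residual_trace_monotone_nonincreasing(self, small_pattern):
        truth = simulate_nca_instance(small_pattern, 20, 0.3, seed=17)
        model = fit_nca(truth.expression, small_pattern, seed=5)
        trace = np.array(model.residual_trace)
        assert np.all(np.diff(trace) <= 1e-9 * trace[0])

    def test_monotone_descent_with_ridge(self, small_pattern):
        truth = simulate_nca_instance(small_pattern, 3, 0.1, seed=23)
        model = fit_nca(truth.expression, small_pattern, seed=5)
        assert model.ridge > 0  # auto-ridge: 3 conditions < 5 TFs
        trace = np.array(model.residual_trace)
        assert np.all(np.diff(trace) <= 1e-9 * trace[0])

    def test_unit_norm_columns_after_fit(self, small_pattern, noisefree_truth):
        model = fit_nca(noisefree_truth.expression, small_pattern, seed=3)
        norms = np.linalg.norm(model.a_hat, axis=0)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)

    def test_all_zero_expression_returns_zero_model(self, small_pattern):
        model = fit_nca(np.zeros((60, 8)), small_pattern, seed=0)
        assert model.converged and model.residual_trace[-1] == 0.0
        assert not model.a_hat.any() and not model.p_hat.any()

    def test_nan_input_rejected(self, small_pattern):
        e = np.zeros((60, 8))
        e[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            fit_nca(e, small_pattern, seed=0)

    def test_dimension_mismatch_rejected(self, small_pattern):
        with pytest.raises(ValueError):
            fit_nca(np.zeros((10, 8)), small_pattern, seed=0)


class TestNormalizeModel:
    def test_column_scaling_is_invisible_in_product(self, small_pattern,
                                                    noisefree_truth):
        model = fit_nca(noisefree_truth.expression, small_pattern, seed=3)
        scales = np.array([2.0, -3.0, 0.5, 10.0, -0.25])
        scaled = model
        scaled.a_hat = model.a_hat * scales[np.newaxis, :]
        scaled.p_hat = model.p_hat / scales[:, np.newaxis]
        before = scaled.a_hat @ scaled.p_hat
        normalized = normalize_model(scaled)
        after = normalized.reconstruction()
        assert np.linalg.norm(before - after) < 1e-10
        np.testing.assert_allclose(
            np.linalg.norm(normalized.a_hat, axis=0), 1.0, atol=1e-12)

    def test_zero_column_flagged_indeterminate(self, small_pattern):
        model = fit_nca(np.zeros((60, 8)), small_pattern, seed=0)
        normalized = normalize_model(model)
        assert normalized.indeterminate_tfs == list(range(5))


class TestRecoveryMetrics:
    def test_truth_as_model_scores_perfectly(self, small_pattern):
        truth = simulate_nca_instance(small_pattern, 20, 0.1, seed=31)
        from heatnca.nca import NCAModel
        model = NCAModel(a_hat=truth.a_true, p_hat=truth.p_true,
                         residual_trace=[], iterations=0, converged=True,
                         ridge=0.0, pattern=small_pattern)
        metrics = recovery_metrics(model, truth)
        np.testing.assert_allclose(metrics["tfa_abs_corr"], 1.0, atol=1e-12)
        assert metrics["sign_agreement"] == 1.0
        noise_level = (np.linalg.norm(truth.expression - truth.a_true @ truth.p_true)
                       / np.linalg.norm(truth.expression))
        assert metrics["relative_residual"] == pytest.approx(noise_level)

    def test_permuted_tfa_rows_degrade_correlation(self, small_pattern):
        truth = simulate_nca_instance(small_pattern, 20, 0.0, seed=31)
        model = fit_nca(truth.expression, small_pattern, seed=1)
        permuted = np.roll(model.p_hat, 1, axis=0)
        assert aligned_tfa_correlations(permuted, truth.p_true).min() < 0.9

    def test_matches_per_row_correlation_loop(self, small_pattern):
        truth = simulate_nca_instance(small_pattern, 20, 0.2, seed=37)
        model = fit_nca(truth.expression, small_pattern, seed=2)
        metrics = recovery_metrics(model, truth)
        for l in range(5):
            x, y = model.p_hat[l], truth.p_true[l]
            ref = abs(np.corrcoef(x, y)[0, 1])
            assert metrics["tfa_abs_corr"][l] == pytest.approx(ref, abs=1e-12)
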