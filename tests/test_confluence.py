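"""Confluence scores, correlation-matrix PCA, rankings, and block detection.

Brute-force oracles: correlating phi and component scores directly from
data, scanning random linear combinations for optimality bounds, and
enumerating threshold counts by hand on 3x3 matrices.
"""

import numpy as np
import pytest

from confluentq import (CorrelationSummary, analyze,
                        charge_transfer_magnitudes, component_scores,
                        confluence_scores, correlation_matrix, find_blocks,
                        generate_nac_dataset, mpc_summary, pca,
                        pc_correlation, power_iteration_mpc, rank_methods,
                        standardized_matrix, threshold_counts, SynthConfig,
                        MethodSpec)
from confluentq.errors import DegenerateEigenvalueError, ValidationError

OMEGA3 = np.array([[1.0, 0.95, 0.85],
                   [0.95, 1.0, 0.70],
                   [0.85, 0.70, 1.0]])


def random_confluent_summary(rng, v=6, n=400):
    """Correlation summary of a mutually positively correlated dataset."""
    base = rng.standard_normal(n)
    data = np.column_stack([
        base + rng.uniform(0.2, 0.8) * rng.standard_normal(n)
        for _ in range(v)
    ])
    return correlation_matrix(data), standardized_matrix(data)


class TestChargeTransferMagnitudes:
    def summary(self):
        return CorrelationSummary.from_correlation(
            np.eye(3), ["qtaim", "ddec6", "hirshfeld"],
            sigma=np.array([0.6299, 0.3108, 0.1284]))

    def test_relative_to_reference(self):
        df = charge_transfer_magnitudes(self.summary(), "ddec6")
        assert round(df.loc["qtaim", "relative"], 3) == 2.027
        assert df.loc["ddec6", "relative"] == 1.0

    def test_extremal_ratio(self):
        df = charge_transfer_magnitudes(self.summary(), "ddec6")
        ratio = df["sigma"].max() / df["sigma"].min()
        assert round(ratio, 1) == 4.9

    def test_sorted_ascending_by_sigma(self):
        df = charge_transfer_magnitudes(self.summary(), "qtaim")
        assert list(df.index) == ["hirshfeld", "ddec6", "qtaim"]

    def test_unknown_reference(self):
        with pytest.raises(ValidationError):
            charge_transfer_magnitudes(self.summary(), "nope")


class TestConfluenceScores:
    def test_two_variable_closed_form(self, rng):
        # construct two standardized variables with correlation exactly 0.5
        base = rng.standard_normal(5000)
        other = rng.standard_normal(5000)
        x = base
        y = 0.5 * base + np.sqrt(0.75) * other
        summary = correlation_matrix(np.column_stack([x, y]))
        omega = summary.correlation[0, 1]
        scores = confluence_scores(summary, standardized_matrix(
            np.column_stack([x, y])))
        np.testing.assert_allclose(scores.s_alpha, [1 + omega] * 2)
        np.testing.assert_allclose(scores.s_phi, np.sqrt(2 + 2 * omega))
        np.testing.assert_allclose(scores.omega_alpha_phi,
                                   (1 + omega) / np.sqrt(2 + 2 * omega))
        # sigma_phi^2 = (1 + omega)/2 for two standardized variables
        np.testing.assert_allclose(scores.sigma_phi,
                                   np.sqrt((1 + omega) / 2), atol=1e-10)

    def test_uncorrelated_group(self):
        summary = CorrelationSummary.from_correlation(np.eye(4))
        scores = confluence_scores(summary)
        np.testing.assert_allclose(scores.s_alpha, 1.0)
        np.testing.assert_allclose(scores.s_phi, 2.0)

    def test_printed_ratio_reproduced(self):
        # S_alpha / S_phi at the dataset's printed values
        assert round(18.204 / 18.48063, 3) == 0.985

    def test_phi_correlation_identity_against_data(self, medium_summary,
                                                   medium_w):
        scores = confluence_scores(medium_summary, medium_w)
        for c in range(medium_summary.n_methods):
            direct = np.corrcoef(medium_w[:, c], scores.phi)[0, 1]
            np.testing.assert_allclose(scores.omega_alpha_phi[c], direct,
                                       atol=1e-10)

    def test_superdelegate_is_argmax(self, medium_summary):
        scores = confluence_scores(medium_summary)
        best = scores.method_names[int(np.argmax(scores.s_alpha))]
        assert scores.superdelegate == best


class TestPCA:
    def test_identity_matrix_degenerate(self):
        result = pca(np.eye(3))
        np.testing.assert_allclose(result.eigenvalues, 1.0)
        assert result.degenerate.all()

    def test_two_by_two_closed_form(self):
        result = pca(np.array([[1.0, 0.8], [0.8, 1.0]]))
        np.testing.assert_allclose(result.eigenvalues, [1.8, 0.2])
        np.testing.assert_allclose(result.mpc, [1 / np.sqrt(2)] * 2)

    def test_percent_explained_printed_value(self):
        assert round(17.158 / 20 * 100, 1) == 85.8

    def test_eigenvalue_sum_equals_v(self, medium_summary):
        result = pca(medium_summary.correlation)
        np.testing.assert_allclose(result.eigenvalues.sum(),
                                   medium_summary.n_methods, atol=1e-9)

    def test_orthonormal_and_unit_row_identity(self, medium_summary):
        result = pca(medium_summary.correlation)
        v = result.eigenvectors
        np.testing.assert_allclose(v.T @ v, np.eye(v.shape[1]), atol=1e-9)
        # sum_k lambda_k v_ak^2 = Omega_aa = 1 per variable
        per_var = (v ** 2) @ result.eigenvalues
        np.testing.assert_allclose(per_var, 1.0, atol=1e-9)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValidationError):
            pca(np.array([[1.0, 0.5], [0.3, 1.0]]))

    def test_mpc_sign_convention_all_positive_for_confluent(self, rng):
        summary, _ = random_confluent_summary(rng)
        result = pca(summary.correlation)
        assert np.all(result.mpc > 0)


class TestPCCorrelation:
    def test_printed_worked_example(self):
        assert round(float(pc_correlation(0.229, 17.158)), 3) == 0.949

    def test_zero_coefficient(self):
        assert pc_correlation(0.0, 5.0) == 0.0

    def test_matches_direct_component_score_correlation(self, rng):
        base = rng.standard_normal(3000)
        data = np.column_stack([base + 0.75 * rng.standard_normal(3000)
                                for _ in range(2)])
        summary = correlation_matrix(data)
        w = standardized_matrix(data)
        result = pca(summary.correlation)
        scores_k = component_scores(w, result, 0)
        for c in range(2):
            direct = np.corrcoef(w[:, c], scores_k)[0, 1]
            np.testing.assert_allclose(
                float(pc_correlation(result.mpc[c], result.lambda_mpc)),
                direct, atol=1e-10)


class TestPowerIteration:
    def test_one_step_exact_for_symmetric_two_by_two(self):
        omega = np.array([[1.0, 0.8], [0.8, 1.0]])
        lam, vec = power_iteration_mpc(omega, p=1)
        np.testing.assert_allclose(vec, [1 / np.sqrt(2)] * 2, atol=1e-12)
        np.testing.assert_allclose(lam, 1.8, atol=1e-12)

    def test_orthogonal_trial_rejected_or_stuck(self):
        omega = np.array([[1.0, 0.8], [0.8, 1.0]])
        lam, vec = power_iteration_mpc(omega, trial=np.array([1.0, -1.0]),
                                       p=50)
        # (1, -1) is itself an eigenvector: iteration never reaches the MPC
        assert abs(lam - 1.8) > 0.5

    def test_zero_trial_rejected(self):
        with pytest.raises(ValidationError):
            power_iteration_mpc(np.eye(2), trial=np.zeros(2))

    def test_one_step_near_mpc_on_confluent_twenty(self, medium_summary):
        omega = medium_summary.correlation
        _, one_step = power_iteration_mpc(omega, p=1)
        result = pca(omega)
        s = omega.sum(axis=1)
        np.testing.assert_allclose(one_step, s / np.linalg.norm(s), atol=1e-12)
        assert np.max(np.abs(one_step - result.mpc)) < 0.02

    def test_converges_to_eigendecomposition(self, medium_summary):
        omega = medium_summary.correlation
        lam, vec = power_iteration_mpc(omega, p=200)
        result = pca(omega)
        np.testing.assert_allclose(lam, result.lambda_mpc, atol=1e-9)
        np.testing.assert_allclose(vec, result.mpc, atol=1e-7)


class TestMPCSummary:
    def test_two_variable_exact_unity(self, rng):
        summary, w = random_confluent_summary(rng, v=2)
        scores = confluence_scores(summary, w)
        result = pca(summary.correlation)
        _, omega_phi_mpc = mpc_summary(scores, result)
        np.testing.assert_allclose(omega_phi_mpc, 1.0, atol=1e-12)

    def test_printed_ratio(self):
        assert round(18.4795 / 18.48063, 5) == 0.99994

    def test_identity_against_brute_force_on_data(self, rng):
        summary, w = random_confluent_summary(rng, v=6, n=2000)
        scores = confluence_scores(summary, w)
        result = pca(summary.correlation)
        _, omega_phi_mpc = mpc_summary(scores, result)
        direct = np.corrcoef(scores.phi, component_scores(w, result, 0))[0, 1]
        np.testing.assert_allclose(omega_phi_mpc, direct, atol=1e-10)

    def test_degenerate_top_eigenvalue_rejected(self):
        scores = confluence_scores(CorrelationSummary.from_correlation(np.eye(3)))
        with pytest.raises(DegenerateEigenvalueError):
            mpc_summary(scores, pca(np.eye(3)))


class TestThresholdCountsAndBlocks:
    def test_identity_counts_self_only(self):
        np.testing.assert_array_equal(threshold_counts(np.eye(4), 0.8), 1)

    @pytest.mark.parametrize("cut,expected", [
        (0.9, [2, 2, 1]),
        (0.8, [3, 2, 2]),
    ])
    def test_enumerated_counts(self, cut, expected):
        np.testing.assert_array_equal(
            threshold_counts(OMEGA3, cut, strict=True), expected)

    def test_strict_vs_inclusive_at_boundary(self):
        omega = np.array([[1.0, 0.9], [0.9, 1.0]])
        assert threshold_counts(omega, 0.9, strict=True).tolist() == [1, 1]
        assert threshold_counts(omega, 0.9, strict=False).tolist() == [2, 2]

    def test_identity_gives_singletons(self):
        blocks = find_blocks(np.eye(4), 0.9)
        assert all(len(g) == 1 for g in blocks.groups)

    def test_three_method_components(self):
        blocks = find_blocks(OMEGA3, 0.9, ["a", "b", "c"])
        assert sorted(map(sorted, blocks.groups)) == [["a", "b"], ["c"]]
        assert blocks.adjacency["a"] == ["b"]

    def test_two_factor_generator_recovery(self, medium_dataset,
                                           medium_summary):
        _, truth = medium_dataset
        blocks = find_blocks(medium_summary.correlation, 0.9,
                             medium_summary.method_names)
        by_prefix = {}
        for spec in truth.methods:
            by_prefix.setdefault(spec.name[:5], set()).add(spec.name)
        # the three generator factor groups come back as components
        recovered = sorted(map(frozenset, blocks.groups), key=len)
        assert frozenset(by_prefix["sideA"]) in recovered
        assert frozenset(by_prefix["sideB"]) in recovered

    def test_ordering_keeps_components_contiguous(self, medium_summary):
        blocks = find_blocks(medium_summary.correlation, 0.9,
                             medium_summary.method_names)
        pos = {m: i for i, m in enumerate(blocks.ordering)}
        for group in blocks.groups:
            idx = sorted(pos[m] for m in group)
            assert idx == list(range(idx[0], idx[0] + len(group)))


class TestRankings:
    def test_single_method_rank_one(self):
        data = np.column_stack([np.arange(4.0), np.arange(4.0) * 2])
        summary = correlation_matrix(data)
        scores = confluence_scores(summary)
        table = rank_methods(summary, scores, pca(summary.correlation))
        for crit in table.rankings:
            assert table.rankings[crit][0][0] == 1

    def test_three_method_row_sum_order(self):
        summary = CorrelationSummary.from_correlation(OMEGA3, ["a", "b", "c"])
        scores = confluence_scores(summary)
        np.testing.assert_allclose(scores.s_alpha, [2.80, 2.65, 2.55])
        table = rank_methods(summary, scores, pca(OMEGA3))
        assert table.order("S_alpha") == ["a", "b", "c"]

    def test_ranking_identities_on_random_confluent_matrices(self, rng):
        for _ in range(50):
            summary, _ = random_confluent_summary(rng, v=5, n=120)
            scores = confluence_scores(summary)
            table = rank_methods(summary, scores, pca(summary.correlation))
            assert table.order("S_alpha") == table.order("omega_phi")
            assert table.order("mpc_coefficient") == table.order("omega_mpc")


class TestConfluenceProperties:
    def test_phi_maximizes_summed_correlation(self, rng, medium_summary,
                                              medium_w):
        """S_tau <= S_phi for 200 random unit-norm linear combinations."""
        scores = confluence_scores(medium_summary, medium_w)
        omega = medium_summary.correlation
        v = medium_summary.n_methods
        for _ in range(200):
            coeff = rng.standard_normal(v)
            tau = medium_w @ coeff
            sigma_tau = np.sqrt(np.mean(tau ** 2))
            s_tau = (omega @ coeff).sum() / sigma_tau
            assert s_tau <= scores.s_phi + 1e-9

    def test_mpc_double_optimality(self, rng, medium_summary, medium_w):
        """No unit vector beats the MPC in variance or in summed squared
        correlations."""
        result = pca(medium_summary.correlation)
        omega = medium_summary.correlation
        lam = result.lambda_mpc
        for _ in range(200):
            u = rng.standard_normal(medium_summary.n_methods)
            u /= np.linalg.norm(u)
            assert u @ omega @ u <= lam + 1e-9              # variance
            proj = omega @ u
            var_u = u @ omega @ u
            assert proj @ proj / var_u <= lam + 1e-9        # sum of sq. corr.

    def test_phi_and_mpc_correlations_close(self, medium_summary, medium_w):
        scores = confluence_scores(medium_summary, medium_w)
        result = pca(medium_summary.correlation)
        omega_mpc = pc_correlation(result.mpc, result.lambda_mpc)
        gap = np.max(np.abs(scores.omega_alpha_phi - omega_mpc))
        assert gap < 0.02

    def test_two_methods_highly_confluent_implies_correlated(
            self, medium_summary, medium_w):
        scores = confluence_scores(medium_summary, medium_w)
        omega = medium_summary.correlation
        high = np.where(scores.omega_alpha_phi > 0.97)[0]
        for i in high:
            for j in high:
                assert omega[i, j] > 0.9

    def test_scale_invariance_of_correlation_outputs(self, medium_dataset):
        table, _ = medium_dataset
        scaled = table.copy()
        scaled.values[scaled.method_names[0]] *= 7.5
        s1 = correlation_matrix(table)
        s2 = correlation_matrix(scaled)
        np.testing.assert_allclose(s1.correlation, s2.correlation, atol=1e-12)
        r1, r2 = analyze(s1), analyze(s2)
        np.testing.assert_allclose(r1.scores.s_alpha, r2.scores.s_alpha,
                                   atol=1e-12)
        assert r1.ranking.order("S_alpha") == r2.ranking.order("S_alpha")
        # covariance-kind PCA is *not* invariant
        p1 = pca(s1.covariance, kind="covariance")
        p2 = pca(s2.covariance, kind="covariance")
        assert not np.allclose(p1.eigenvalues, p2.eigenvalues)
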