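import numpy as np
import pytest
from scipy import stats

import perturbcf as pcf
from perturbcf.model import BranchedModel, ModelConfig


class TestLinearBaseline:
    def test_singleton_combo_is_that_mean_profile(self, tiny_screen):
        screen, truth = tiny_screen
        single = next(c for c in truth.conditions if len(c.perts) == 1)
        pred = pcf.linear_baseline(screen, single.perts)
        np.testing.assert_allclose(
            pred, screen.outcome_matrix[single.rows].mean(axis=0)
        )

    def test_pair_is_mean_of_single_means(self, tiny_screen):
        screen, truth = tiny_screen
        pair = next(c for c in truth.conditions if len(c.perts) == 2)
        pred = pcf.linear_baseline(screen, pair.perts)
        singles = []
        for p in pair.perts:
            c = next(c for c in truth.conditions if c.perts == (p,))
            singles.append(screen.outcome_matrix[c.rows].mean(axis=0))
        np.testing.assert_allclose(pred, np.mean(singles, axis=0))

    def test_member_without_single_observation_rejected(self, tiny_screen):
        screen, truth = tiny_screen
        single_rows = [
            i for i in range(screen.n_samples)
            if len(screen.design.combo_key(i)) != 1
        ]
        with pytest.raises(ValueError, match="single-perturbation"):
            pcf.linear_baseline(screen, ["g0"], train_idx=single_rows)


class TestLinearBranchAverage:
    def test_singleton_equals_one_hot_forward(self, tiny_model):
        m = tiny_model
        x = np.random.default_rng(0).standard_normal(30)
        abl = pcf.linear_branch_average(m, x, ["g1"])
        t = np.array([0.0, 1.0, 0.0, 0.0])
        np.testing.assert_allclose(abl.mu, m.forward(x, t).mu, rtol=1e-12)

    def test_mean_mode_is_two_call_average(self, tiny_model):
        m = tiny_model
        x = np.random.default_rng(1).standard_normal(30)
        abl = pcf.linear_branch_average(m, x, ["g0", "g2"], mode="mean")
        a = m.forward(x, np.array([1.0, 0.0, 0.0, 0.0]))
        b = m.forward(x, np.array([0.0, 0.0, 1.0, 0.0]))
        np.testing.assert_allclose(abl.mu, (a.mu + b.mu) / 2, rtol=1e-12)

    def test_additive_mode_equals_full_forward_for_linear_decoder(self):
        """With an identity-activation (affine) decoder the ablation is exact."""
        cfg = ModelConfig(
            input_dim=10, output_dim=8, latent_dim=5, encoder_widths=[6],
            decoder_widths=[6], activation="identity", seed=4,
        )
        m = BranchedModel(cfg, ["a", "b", "c"])
        x = np.random.default_rng(2).standard_normal(10)
        t = np.array([1.0, 1.0, 0.0])
        abl = pcf.linear_branch_average(m, x, ["a", "b"], mode="additive")
        full = m.forward(x, t)
        np.testing.assert_allclose(abl.mu, full.mu, rtol=1e-9)

    def test_differs_from_full_forward_for_nonlinear_decoder(self, tiny_model):
        m = tiny_model
        x = np.random.default_rng(3).standard_normal(30)
        abl = pcf.linear_branch_average(m, x, ["g0", "g1"])
        full = m.forward(x, np.array([1.0, 1.0, 0.0, 0.0]))
        assert not np.allclose(abl.mu, full.mu)

    def test_empty_combo_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="empty"):
            pcf.linear_branch_average(tiny_model, np.zeros(30), [])


class TestRandomBaseline:
    def test_control_centroid(self, tiny_screen):
        screen, _ = tiny_screen
        np.testing.assert_allclose(
            pcf.random_baseline(screen), screen.controls.values.mean(axis=0)
        )

    def test_sampled_reproducible(self, tiny_screen):
        screen, _ = tiny_screen
        a = pcf.random_baseline(screen, seed=9, strategy="sampled")
        b = pcf.random_baseline(screen, seed=9, strategy="sampled")
        np.testing.assert_array_equal(a, b)


class TestTopKDegs:
    def test_k_equals_p_returns_all(self):
        idx = pcf.top_k_degs(np.arange(5.0), np.zeros(5), 5)
        assert sorted(idx) == list(range(5))

    def test_toy_ranking_by_absolute_shift(self):
        pert = np.array([0.0, 3.0, 1.0, -4.0, 2.0, 0.0])
        idx = pcf.top_k_degs(pert, np.zeros(6), 2)
        assert list(idx) == [3, 1]

    def test_all_ties_keep_input_order(self):
        idx = pcf.top_k_degs(np.ones(6), np.ones(6), 3)
        assert list(idx) == [0, 1, 2]

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            pcf.top_k_degs(np.ones(3), np.zeros(3), 0)


class TestEvalCondition:
    def test_perfect_prediction_scores(self):
        rng = np.random.default_rng(4)
        truth = rng.random((10, 6))
        control = rng.random(6)
        rep = pcf.eval_condition(truth.mean(0), truth, control, k=3,
                                 baseline=control)
        assert rep.all_genes.r2 == pytest.approx(1.0)
        assert rep.all_genes.pcc == pytest.approx(1.0)
        assert rep.top_k.nmse == pytest.approx(0.0)

    def test_baseline_prediction_has_unit_normalized_mse(self):
        rng = np.random.default_rng(5)
        truth = rng.random((8, 5))
        base = rng.random(5)
        rep = pcf.eval_condition(base, truth, np.zeros(5), k=5, baseline=base)
        assert rep.all_genes.nmse == pytest.approx(1.0)
        assert rep.top_k.nmse == pytest.approx(1.0)

    def test_hand_computed_toy_metrics(self):
        pred = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        truth = np.array([1.0, 2.0, 2.0, 5.0, 4.0])
        rep = pcf.eval_condition(pred, truth, np.zeros(5), k=5)
        ss_res = np.sum((pred - truth) ** 2)
        ss_tot = np.sum((truth - truth.mean()) ** 2)
        assert rep.all_genes.r2 == pytest.approx(1 - ss_res / ss_tot)
        assert rep.all_genes.mse == pytest.approx(ss_res / 5)
        assert rep.all_genes.pcc == pytest.approx(stats.pearsonr(pred, truth).statistic)

    def test_correlations_match_scipy_references(self):
        rng = np.random.default_rng(6)
        pred, truth = rng.random(40), rng.random((3, 40))
        rep = pcf.eval_condition(pred, truth, np.zeros(40), k=40)
        tm = truth.mean(0)
        assert rep.all_genes.pcc == pytest.approx(stats.pearsonr(pred, tm).statistic, abs=1e-12)
        assert rep.all_genes.scc == pytest.approx(stats.spearmanr(pred, tm).statistic, abs=1e-12)

    def test_constant_prediction_correlation_reported_missing(self):
        truth = np.random.default_rng(7).random((4, 5))
        rep = pcf.eval_condition(np.full(5, 2.0), truth, np.zeros(5), k=5)
        assert rep.all_genes.pcc is None
        assert rep.all_genes.scc is None

    def test_normalized_mse_invariant_to_joint_affine_rescaling(self):
        rng = np.random.default_rng(8)
        pred, base = rng.random(6), rng.random(6)
        truth = rng.random((5, 6))
        control = np.zeros(6)
        r1 = pcf.eval_condition(pred, truth, control, k=6, baseline=base)
        a, b = 3.5, -1.2
        r2 = pcf.eval_condition(
            a * pred + b, a * truth + b, a * control + b, k=6, baseline=a * base + b
        )
        assert r1.all_genes.nmse == pytest.approx(r2.all_genes.nmse)

    def test_effect_pcc_ignores_control_background(self):
        rng = np.random.default_rng(9)
        control = rng.random(30) * 10
        effect = rng.standard_normal(30)
        truth = (control + effect)[None, :]
        # prediction with the right effect on a wrong background still
        # correlates perfectly on the effect scale
        pred = control + 0.5 * effect
        rep = pcf.eval_condition(pred, truth, control, k=30)
        assert rep.all_genes.effect_pcc == pytest.approx(1.0)
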