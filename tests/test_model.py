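import numpy as np
import pytest

import perturbcf as pcf
from perturbcf.model import BranchedModel, ModelConfig


def _random_model(seed, K=4, input_dim=9, output_dim=6, latent_dim=5, **kw):
    cfg = ModelConfig(
        input_dim=input_dim,
        output_dim=output_dim,
        latent_dim=latent_dim,
        encoder_widths=[8],
        decoder_widths=[8],
        seed=seed,
        **kw,
    )
    return BranchedModel(cfg, [f"p{i}" for i in range(K)])


class TestEncode:
    def test_deterministic_and_batch_consistent(self):
        m = _random_model(0)
        x = np.random.default_rng(1).standard_normal((2, 9))
        np.testing.assert_array_equal(m.encode(x), m.encode(x))
        batch = m.encode(x)
        # batched rows match single-profile calls (up to BLAS summation order)
        np.testing.assert_allclose(batch[0], m.encode(x[0])[0], rtol=1e-12, atol=1e-15)
        np.testing.assert_allclose(batch[1], m.encode(x[1])[0], rtol=1e-12, atol=1e-15)

    @pytest.mark.parametrize("latent_dim", [1, 3, 17])
    def test_output_width_is_latent_dim(self, latent_dim):
        m = _random_model(2, latent_dim=latent_dim)
        assert m.encode(np.zeros(9)).shape == (1, latent_dim)

    def test_dimension_mismatch_rejected(self):
        m = _random_model(0)
        with pytest.raises(ValueError, match="features"):
            m.encode(np.zeros(5))


class TestBranchApply:
    def test_output_shape_is_latent_dim(self):
        m = _random_model(1)
        h = np.zeros((3, 5))
        assert m.branch_apply(h, 2).shape == (3, 5)

    def test_dose_on_undosed_model_rejected(self):
        m = _random_model(1)
        with pytest.raises(ValueError, match="not dose-conditioned"):
            m.branch_apply(np.zeros((1, 5)), 0, dose=0.5)

    def test_reference_dose_equals_undosed_sentinel(self):
        m = _random_model(3, dosed=True)
        m.fit_dose_transform([0.01, 0.1, 1.0])
        h = np.random.default_rng(0).standard_normal((2, 5))
        # smallest training dose maps to feature 0, same as "no dose"
        np.testing.assert_array_equal(
            m.branch_apply(h, 0, dose=0.01), m.branch_apply(h, 0, dose=None)
        )

    def test_distinct_doses_give_distinct_outputs(self):
        m = _random_model(3, dosed=True)
        m.fit_dose_transform([0.01, 0.1, 1.0])
        h = np.ones((1, 5))
        a = m.branch_apply(h, 1, dose=0.01)
        b = m.branch_apply(h, 1, dose=1.0)
        assert not np.allclose(a, b)


class TestAggregate:
    def test_single_active_branch_is_branch_output(self):
        m = _random_model(4)
        e = m.encode(np.random.default_rng(2).standard_normal(9))
        f2 = m.branch_apply(e, 2)
        z = m.aggregate({2: f2}, np.array([0.0, 0.0, 1.0, 0.0]))
        np.testing.assert_array_equal(z, f2)

    def test_pair_sum_matches_brute_force_and_permutation(self):
        m = _random_model(4)
        e = m.encode(np.random.default_rng(3).standard_normal((2, 9)))
        outs = {0: m.branch_apply(e, 0), 1: m.branch_apply(e, 1)}
        w = np.tile([1.0, 1.0, 0.0, 0.0], (2, 1))
        z = m.aggregate(outs, w)
        np.testing.assert_allclose(z, outs[0] + outs[1], rtol=1e-15)
        z_perm = m.aggregate({1: outs[1], 0: outs[0]}, w)
        np.testing.assert_allclose(z, z_perm, rtol=1e-15)

    def test_all_zero_weights_give_zero_vector(self):
        m = _random_model(4)
        z = m.aggregate({}, np.zeros((3, 4)))
        np.testing.assert_array_equal(z, np.zeros((3, 5)))


class TestDecode:
    def test_variance_floor_applied(self):
        m = _random_model(5)
        # push raw log-variance far below the floor
        m.decoder.b[-1][m.config.output_dim :] = -100.0
        pred = m.decode_gaussian(np.zeros((1, 5)))
        np.testing.assert_array_equal(pred.sigma2, np.full((1, 6), 1e-6))

    def test_sigma2_strictly_positive_over_random_decodes(self):
        rng = np.random.default_rng(6)
        for seed in range(5):
            m = _random_model(seed)
            z = rng.standard_normal((50, 5)) * 10
            pred = m.decode_gaussian(z)
            assert (pred.sigma2 >= m.config.variance_floor).all()
            assert pred.mu.shape == (50, 6)

    def test_head_mismatch_rejected(self):
        m = _random_model(0, head="scalar")
        with pytest.raises(ValueError):
            m.decode_gaussian(np.zeros((1, 5)))
        with pytest.raises(ValueError):
            _random_model(0).decode_scalar(np.zeros((1, 5)))

    def test_scalar_batched_equals_looped(self):
        m = _random_model(7, head="scalar")
        z = np.random.default_rng(0).standard_normal((4, 5))
        batched = m.decode_scalar(z)
        looped = [m.decode_scalar(z[i : i + 1])[0] for i in range(4)]
        np.testing.assert_allclose(batched, looped, rtol=1e-12, atol=1e-15)


class TestForward:
    def test_skipping_bitwise_equals_naive_evaluation(self):
        for trial in range(100):
            rng = np.random.default_rng(trial)
            K = int(rng.integers(2, 6))
            m = _random_model(trial, K=K)
            x = rng.standard_normal((3, 9))
            t = np.where(rng.random((3, K)) < 0.5, 0.0, rng.random((3, K)))
            a = m.forward(x, t, skip_zero_branches=True)
            b = m.forward(x, t, skip_zero_branches=False)
            assert (a.mu == b.mu).all() and (a.sigma2 == b.sigma2).all()

    def test_one_hot_equals_decode_of_single_branch(self):
        m = _random_model(8)
        x = np.random.default_rng(4).standard_normal(9)
        t = np.array([0.0, 0.0, 0.0, 1.0])
        pred = m.forward(x, t)
        manual = m.decode_gaussian(m.branch_apply(m.encode(x), 3))
        np.testing.assert_array_equal(pred.mu, manual.mu[0])

    def test_fractional_proxy_row_mixes_branches(self):
        m = _random_model(9, K=5)
        x = np.random.default_rng(5).standard_normal(9)
        t = np.array([0.0, 0.4, 0.35, 0.25, 0.0])
        e = m.encode(x)
        z = 0.4 * m.branch_apply(e, 1) + 0.35 * m.branch_apply(e, 2) + 0.25 * m.branch_apply(e, 3)
        np.testing.assert_allclose(m.forward(x, t).mu, m.decode_gaussian(z).mu[0], rtol=1e-12)

    def test_aggregation_linear_in_weights_at_latent_level(self):
        m = _random_model(10)
        x = np.random.default_rng(6).standard_normal((2, 9))
        t1 = np.tile([1.0, 0.0, 1.0, 0.0], (2, 1))
        t2 = np.tile([0.0, 1.0, 0.0, 0.0], (2, 1))
        a, b = 0.3, 1.7
        z1 = m._latent(x, t1)
        z2 = m._latent(x, t2)
        z_comb = m._latent(x, a * t1 + b * t2)
        np.testing.assert_allclose(z_comb, a * z1 + b * z2, rtol=1e-10)

    def test_empty_treatment_row_decodes_latent_zero(self):
        m = _random_model(11)
        x = np.random.default_rng(7).standard_normal(9)
        pred = m.forward(x, np.zeros(4))
        np.testing.assert_array_equal(pred.mu, m.decode_gaussian(np.zeros((1, 5))).mu[0])


class TestReproducibilityAndSerialization:
    def test_same_config_seed_gives_identical_parameters(self):
        m1 = _random_model(12)
        m2 = _random_model(12)
        for p1, p2 in zip(m1.parameters(), m2.parameters()):
            np.testing.assert_array_equal(p1, p2)

    def test_checkpoint_round_trip(self, tmp_path):
        m = _random_model(13, dosed=True)
        m.fit_dose_transform([0.1, 1.0, 10.0])
        path = tmp_path / "model.npz"
        m.save(path)
        back = BranchedModel.load(path)
        assert back.perturbation_ids == m.perturbation_ids
        assert back.dose_lo == m.dose_lo and back.dose_hi == m.dose_hi
        x = np.random.default_rng(8).standard_normal((3, 9))
        t = np.tile([1.0, 0.0, 1.0, 0.0], (3, 1))
        d = np.tile([0.5, 0.0, 2.0, 0.0], (3, 1))
        mask = d > 0
        a = m.forward(x, t, d, mask)
        b = back.forward(x, t, d, mask)
        np.testing.assert_array_equal(a.mu, b.mu)
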