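"""Two-stage network contracts: locality, latent space, sampling."""
import numpy as np
import pytest

from dcepk.autodiff import Tensor
from dcepk.nets import (
    LatentDistribution,
    ModelConfig,
    PredictionSet,
    TwoStageNet,
    kl_divergence,
    load_checkpoint,
    receptive_field,
    save_checkpoint,
)


@pytest.fixture(scope="module")
def net():
    return TwoStageNet(ModelConfig(seed=7))


@pytest.fixture(scope="module")
def x16():
    return np.random.default_rng(0).random((16, 16, 60)).astype(np.float32)


class TestTCNStage:
    def test_receptive_field_covers_all_frames(self):
        cfg = ModelConfig()
        assert receptive_field(cfg.tcn_kernel, cfg.tcn_dilations) >= cfg.n_frames

    def test_insufficient_receptive_field_rejected(self):
        with pytest.raises(ValueError, match="receptive field"):
            ModelConfig(tcn_dilations=(1, 2, 4))

    def test_voxelwise_locality(self, net, x16):
        """Perturbing one voxel's curve changes only that voxel's features."""
        a = net.temporal_features(x16[None]).numpy()[0]
        x2 = x16.copy()
        x2[5, 9, :] += 0.5
        b = net.temporal_features(x2[None]).numpy()[0]
        diff = np.abs(a - b).sum(axis=0)
        assert diff[5, 9] > 0
        diff[5, 9] = 0.0
        assert np.all(diff == 0.0)

    def test_spatial_permutation_equivariance(self, net, x16):
        rng = np.random.default_rng(3)
        perm = rng.permutation(16 * 16)
        feats = net.temporal_features(x16[None]).numpy()[0].reshape(3, -1)
        xp = x16.reshape(-1, 60)[perm].reshape(16, 16, 60)
        fp = net.temporal_features(xp[None]).numpy()[0].reshape(3, -1)
        np.testing.assert_allclose(fp, feats[:, perm], atol=1e-6)

    def test_constant_curve_finite_deterministic(self, net):
        x = np.ones((8, 8, 60), dtype=np.float32)
        f1 = net.temporal_features(x[None]).numpy()
        f2 = net.temporal_features(x[None]).numpy()
        assert np.all(np.isfinite(f1))
        np.testing.assert_array_equal(f1, f2)

    def test_frame_count_mismatch_rejected(self, net):
        with pytest.raises(ValueError, match="frames"):
            net.temporal_features(np.zeros((1, 8, 8, 30), dtype=np.float32))


class TestLatentSpace:
    def test_prior_deterministic_and_floored(self, net, x16):
        f = net.temporal_features(x16[None])
        d1 = net.prior_encode(f)
        d2 = net.prior_encode(f)
        np.testing.assert_array_equal(d1.mu.numpy(), d2.mu.numpy())
        assert np.all(d1.sigma.numpy() >= net.cfg.sigma_floor)

    def test_zero_weight_encoder_closed_form(self, x16):
        """With all-zero weights: mu = 0, sigma = softplus(0) (+ floor)."""
        model = TwoStageNet(ModelConfig(seed=0))
        for layer in (model.prior_c1, model.prior_c2):
            layer.w.data[...] = 0.0
            layer.b.data[...] = 0.0
        model.prior_fc.w.data[...] = 0.0
        model.prior_fc.b.data[...] = 0.0
        d = model.prior_encode(model.temporal_features(x16[None]))
        np.testing.assert_allclose(d.mu.numpy(), 0.0, atol=1e-7)
        np.testing.assert_allclose(d.sigma.numpy(), np.log(2.0), atol=1e-5)

    def test_kl_identical_distributions_zero(self):
        mu = Tensor(np.array([0.3, -1.0]))
        sig = Tensor(np.array([0.5, 2.0]))
        q = LatentDistribution(mu, sig)
        p = LatentDistribution(Tensor(mu.numpy().copy()), Tensor(sig.numpy().copy()))
        assert float(kl_divergence(q, p).data) == pytest.approx(0.0, abs=1e-7)

    def test_kl_matches_hand_computed_two_dim(self):
        mq, sq = np.array([0.5, -0.2]), np.array([0.8, 1.5])
        mp, sp = np.array([0.0, 0.4]), np.array([1.0, 0.9])
        q = LatentDistribution(Tensor(mq), Tensor(sq))
        p = LatentDistribution(Tensor(mp), Tensor(sp))
        hand = np.sum(np.log(sp / sq) + (sq**2 + (mq - mp) ** 2) / (2 * sp**2) - 0.5)
        assert float(kl_divergence(q, p).data) == pytest.approx(hand, rel=1e-5)

    def test_kl_nonnegative_posterior_vs_prior(self, net, x16):
        f = net.temporal_features(x16[None])
        gt = Tensor(np.random.default_rng(1).random((1, 3, 16, 16)).astype(np.float32))
        kl = float(kl_divergence(net.posterior_encode(f, gt), net.prior_encode(f)).data)
        assert np.isfinite(kl) and kl >= 0.0


class TestDecoderAndPrediction:
    def test_same_latent_same_maps_nonnegative(self, net, x16):
        f = net.temporal_features(x16[None])
        z = Tensor(np.random.default_rng(2).standard_normal((1, net.cfg.latent_dim)).astype(np.float32))
        a = net.decode(f, z).numpy()
        b = net.decode(f, z).numpy()
        np.testing.assert_array_equal(a, b)
        assert np.all(a >= 0.0)

    def test_distinct_latents_distinct_maps_after_training(self, x16):
        """The output correction is zero-initialised, so latent sensitivity
        is a post-training property: once trained, distinct z give distinct
        maps."""
        from dcepk.training import TrainConfig, train

        rng = np.random.default_rng(4)
        y = np.abs(rng.normal(0.05, 0.02, size=(3, 16, 16)))
        cfg = TrainConfig(mode="full", epochs=5, batch_size=1, seed=0,
                          model=ModelConfig(latent_dim=3, seed=0))
        model, _ = train([(x16, y)], cfg)
        f = model.temporal_features(x16[None])
        z1 = Tensor(rng.standard_normal((1, model.cfg.latent_dim)).astype(np.float32))
        z2 = Tensor(rng.standard_normal((1, model.cfg.latent_dim)).astype(np.float32))
        assert np.any(model.decode(f, z1).numpy() != model.decode(f, z2).numpy())

    def test_bad_latent_shape_rejected(self, net, x16):
        f = net.temporal_features(x16[None])
        with pytest.raises(ValueError, match="latent"):
            net.decode(f, Tensor(np.zeros((1, 3), dtype=np.float32)))

    def test_prediction_set_consistency(self, net, x16):
        """Mean and sd maps bit-match recomputation from stored samples."""
        ps = net.predict(x16, n_samples=4, seed=11)
        assert ps.n_samples == 4 and ps.samples.shape[0] == 4
        np.testing.assert_array_equal(
            ps.mean_maps.ktrans[..., 0], ps.samples.mean(axis=0)[0]
        )
        np.testing.assert_array_equal(
            ps.uncertainty_maps.vp[..., 0], ps.samples.std(axis=0, ddof=0)[2]
        )
        assert np.all(ps.uncertainty_maps.ktrans >= 0)
        # mean inside the voxelwise convex hull of samples
        assert np.all(ps.mean_maps.ve[..., 0] <= ps.samples[:, 1].max(axis=0) + 1e-12)
        assert np.all(ps.mean_maps.ve[..., 0] >= ps.samples[:, 1].min(axis=0) - 1e-12)

    def test_predict_seeded_reproducible(self, net, x16):
        # open the zero-initialised spatial-correction gate so the latent
        # reaches the output (as it would after training)
        net.gate_sp.data[...] = 0.1
        try:
            a = net.predict(x16, seed=3)
            b = net.predict(x16, seed=3)
            np.testing.assert_array_equal(a.samples, b.samples)
            assert np.any(a.samples != net.predict(x16, seed=4).samples)
        finally:
            net.gate_sp.data[...] = 0.0

    def test_n_samples_validation(self, net, x16):
        with pytest.raises(ValueError):
            net.predict(x16, n_samples=0)
        with pytest.raises(ValueError):
            PredictionSet.from_samples(np.zeros((1, 3, 4, 4)), (0,))

    def test_collapsed_latent_zero_uncertainty(self, x16):
        """Forcing prior sigma to the floor makes sampling deterministic."""
        model = TwoStageNet(ModelConfig(seed=1))
        L = model.cfg.latent_dim
        model.prior_fc.w.data[:, L:] = 0.0
        model.prior_fc.b.data[L:] = -40.0  # softplus(-40) ~ 0 -> sigma = floor
        ps = model.predict(x16, n_samples=4, seed=0)
        assert ps.uncertainty_maps.ktrans.max() < 1e-5

    def test_ablation_head_is_voxelwise(self, net, x16):
        f1 = net.temporal_features(x16[None])
        m1 = net.ablation_maps(f1).numpy()[0]
        x2 = x16.copy()
        x2[3, 3, :] *= 1.5
        m2 = net.ablation_maps(net.temporal_features(x2[None])).numpy()[0]
        diff = np.abs(m1 - m2).sum(axis=0)
        diff[3, 3] = 0.0
        assert np.all(diff == 0.0)


class TestCheckpoint:
    def test_round_trip_identical_predictions(self, net, x16, tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(net, path)
        other = load_checkpoint(path)
        np.testing.assert_array_equal(
            net.predict(x16, seed=2).samples, other.predict(x16, seed=2).samples
        )

    def test_state_dict_key_mismatch_rejected(self, net):
        bad = net.state_dict()
        bad.pop(next(iter(bad)))
        with pytest.raises(ValueError):
            TwoStageNet(net.cfg).load_state_dict(bad)
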