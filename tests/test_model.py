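"""VAE-GAN building blocks: posteriors, KL, losses, persistence."""

import numpy as np
import pytest

from cyclemap.model import (EncoderOutput, ManifoldModel, decode,
                            discriminate, encode, gan_losses_from_scores,
                            kl_divergence, reconstruction_loss, sample_latent)


class TestEncodeDecode:
    def test_zero_image_yields_finite_posterior(self, tiny_model):
        out = encode(tiny_model, np.zeros((16, 16)))
        assert out.mu.shape == (1, 4)
        assert np.isfinite(out.mu).all() and np.isfinite(out.logvar).all()

    def test_encoding_is_deterministic(self, tiny_model, rng):
        img = rng.random((16, 16))
        a, b = encode(tiny_model, img), encode(tiny_model, img)
        np.testing.assert_array_equal(a.mu, b.mu)
        np.testing.assert_array_equal(a.logvar, b.logvar)

    def test_batch_matches_per_item_forward(self, tiny_model, rng):
        imgs = rng.random((5, 16, 16))
        batch = encode(tiny_model, imgs)
        for i in range(5):
            single = encode(tiny_model, imgs[i])
            np.testing.assert_allclose(batch.mu[i], single.mu[0], atol=1e-5)

    def test_decode_output_in_unit_range(self, tiny_model, rng):
        z = rng.normal(size=(7, 4)) * 3
        imgs = decode(tiny_model, z)
        assert imgs.shape == (7, 16, 16)
        assert imgs.min() >= 0 and imgs.max() <= 1

    def test_shape_validation(self, tiny_model, rng):
        with pytest.raises(ValueError):
            encode(tiny_model, rng.random((8, 8)))
        with pytest.raises(ValueError):
            decode(tiny_model, np.zeros(3))


class TestSampleLatent:
    def test_zero_variance_returns_mean(self):
        post = EncoderOutput(mu=np.ones(4), logvar=np.full(4, -60.0))
        z = sample_latent(post, np.random.default_rng(0))
        np.testing.assert_allclose(z, 1.0, atol=1e-10)

    def test_reproducible_given_seed(self):
        post = EncoderOutput(mu=np.zeros(4), logvar=np.zeros(4))
        z1 = sample_latent(post, np.random.default_rng(3))
        z2 = sample_latent(post, np.random.default_rng(3))
        np.testing.assert_array_equal(z1, z2)

    def test_empirical_mean_matches_mu(self):
        mu = np.array([0.5, -1.0, 2.0])
        post = EncoderOutput(mu=np.tile(mu, (10_000, 1)),
                             logvar=np.zeros((10_000, 3)))
        z = sample_latent(post, np.random.default_rng(11))
        se = 1.0 / np.sqrt(10_000)
        assert np.all(np.abs(z.mean(axis=0) - mu) < 4 * se)


class TestKlDivergence:
    def test_standard_normal_posterior_has_zero_kl(self):
        assert kl_divergence(EncoderOutput(np.zeros(4), np.zeros(4))) == 0.0

    def test_unit_mean_shift_in_one_dimension(self):
        assert np.isclose(
            kl_divergence(EncoderOutput(np.array([1.0]), np.array([0.0]))), 0.5)

    def test_non_negative_on_random_posteriors(self, rng):
        for _ in range(50):
            post = EncoderOutput(rng.normal(size=6), rng.normal(size=6))
            assert kl_divergence(post) >= 0

    def test_matches_monte_carlo_estimate(self):
        rng = np.random.default_rng(21)
        mu, logvar = rng.normal(size=5), rng.normal(size=5) * 0.5
        n = 100_000
        sd = np.exp(logvar / 2)
        z = mu + sd * rng.standard_normal((n, 5))
        log_q = -0.5 * np.sum((z - mu) ** 2 / sd**2 + logvar + np.log(2 * np.pi),
                              axis=1)
        log_p = -0.5 * np.sum(z**2 + np.log(2 * np.pi), axis=1)
        mc = log_q - log_p
        closed = kl_divergence(EncoderOutput(mu, logvar))
        assert abs(closed - mc.mean()) < 3 * mc.std() / np.sqrt(n)


class TestLosses:
    def test_perfect_reconstruction_costs_nothing(self, tiny_model, rng):
        x = rng.random((16, 16))
        assert reconstruction_loss(x, x, tiny_model) == 0.0

    def test_without_feature_term_equals_pixel_mse(self, rng):
        x, y = rng.random((16, 16)), rng.random((16, 16))
        assert np.isclose(reconstruction_loss(x, y, model=None),
                          np.mean((x - y) ** 2))

    def test_symmetric_in_arguments(self, tiny_model, rng):
        x, y = rng.random((16, 16)), rng.random((16, 16))
        assert np.isclose(reconstruction_loss(x, y, tiny_model),
                          reconstruction_loss(y, x, tiny_model))

    def test_gan_losses_closed_forms(self):
        # perfect discriminator / generator limits and the 0.5 equilibrium
        disc, _ = gan_losses_from_scores(np.ones(4), np.zeros(4))
        assert disc < 1e-5
        _, gen = gan_losses_from_scores(np.ones(4), np.ones(4))
        assert gen < 1e-5
        disc, gen = gan_losses_from_scores(np.full(4, 0.5), np.full(4, 0.5))
        assert np.isclose(disc, 2 * np.log(2)) and np.isclose(gen, np.log(2))


class TestDiscriminatorAndPersistence:
    def test_discriminator_outputs_are_finite_probabilities(self, tiny_model):
        out = discriminate(tiny_model, np.zeros((16, 16)))
        assert 0 < out.realness < 1
        assert np.isfinite(out.features).all()

    def test_identical_inputs_identical_features(self, tiny_model, rng):
        img = rng.random((16, 16))
        a, b = discriminate(tiny_model, img), discriminate(tiny_model, img)
        np.testing.assert_array_equal(a.features, b.features)

    def test_save_load_round_trip_is_bit_exact(self, tiny_model, rng, tmp_path):
        imgs = rng.random((3, 16, 16))
        tiny_model.save(tmp_path / "ckpt")
        clone = ManifoldModel.load(tmp_path / "ckpt")
        np.testing.assert_array_equal(encode(tiny_model, imgs).mu,
                                      encode(clone, imgs).mu)
        z = rng.normal(size=(3, 4))
        np.testing.assert_array_equal(decode(tiny_model, z), decode(clone, z))
        np.testing.assert_array_equal(discriminate(tiny_model, imgs).features,
                                      discriminate(clone, imgs).features)
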