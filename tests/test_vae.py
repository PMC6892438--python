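import copy

import numpy as np
import pytest

import movae
from _oracles import kl_monte_carlo
from movae.bench import ami, kmeans_cluster
from movae.vae import (
    LatentSpace,
    MultiOmicsVAE,
    VAEConfig,
    build_model,
    kl_term,
    load_model,
    reconstruction_term,
    save_model,
    train,
    transform,
    warmup_beta,
)


class TestLossTerms:
    def test_kl_zero_when_posterior_equals_prior(self):
        assert kl_term(np.zeros(5), np.ones(5))[0] == 0.0

    def test_kl_closed_form_values(self):
        assert kl_term([1.0], [1.0])[0] == pytest.approx(0.5)
        assert kl_term([0.0], [2.0])[0] == pytest.approx(0.5 * (4 - 1 - np.log(4)))

    def test_kl_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            kl_term([0.0], [0.0])

    @pytest.mark.parametrize("mu,sigma", [(0.3, 1.7), (-1.2, 0.4), (2.0, 2.5)])
    def test_kl_matches_monte_carlo(self, mu, sigma):
        rng = np.random.default_rng(0)
        mc = kl_monte_carlo(mu, sigma, 200_000, rng)
        assert kl_term([mu], [sigma])[0] == pytest.approx(mc, rel=0.03, abs=0.01)

    def test_cross_entropy_values(self):
        assert reconstruction_term([0.5], [0.5])[0] == pytest.approx(np.log(2))
        assert reconstruction_term([1.0], [0.5])[0] == pytest.approx(np.log(2))
        assert reconstruction_term([1.0], [1.0 - 1e-9])[0] == pytest.approx(0.0, abs=1e-5)


class TestWarmup:
    def test_schedule(self):
        assert warmup_beta(0, 0.01) == 0.0
        assert warmup_beta(100, 0.01) == 1.0
        assert warmup_beta(400, 0.01) == 1.0  # clamped

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            warmup_beta(-1, 0.01)


class TestArchitecture:
    def test_same_seed_builds_identical_weights(self):
        cfg = VAEConfig(n_hidden=16, n_latent=4, epochs=10, batch_size=8)
        a, b = build_model(30, cfg), build_model(30, cfg)
        for k in a.params_:
            np.testing.assert_array_equal(a.params_[k], b.params_[k])

    def test_latent_head_has_mu_and_logvar_branches(self):
        m = build_model(30, VAEConfig(n_hidden=16, n_latent=4, epochs=10))
        assert m.params_["W_mu"].shape == (16, 4)
        assert m.params_["W_lv"].shape == (16, 4)
        assert m.params_["W_out"].shape == (16, 30)

    def test_forward_of_zeros_lands_in_unit_interval(self):
        m = build_model(12, VAEConfig(n_hidden=8, n_latent=3, epochs=10))
        x_hat = m.reconstruct(np.zeros((2, 12)))
        assert np.isfinite(x_hat).all() and (x_hat > 0).all() and (x_hat < 1).all()

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        m = MultiOmicsVAE(n_hidden=7, n_latent=3, epochs=1, seed=1)
        m.build(5)
        X = rng.uniform(0.1, 0.9, (6, 5))
        eps = rng.standard_normal((6, 3))
        _, _, _, grads = copy.deepcopy(m)._loss_and_grads(X, 0.7, eps)
        h = 1e-5
        for key in m.params_:
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in m.params_[key].shape)
                p1 = copy.deepcopy(m.params_)
                p1[key][idx] += h
                p2 = copy.deepcopy(m.params_)
                p2[key][idx] -= h
                m1, m2 = copy.deepcopy(m), copy.deepcopy(m)
                m1.params_, m2.params_ = p1, p2
                num = (
                    m1._loss_and_grads(X, 0.7, eps)[0]
                    - m2._loss_and_grads(X, 0.7, eps)[0]
                ) / (2 * h)
                assert grads[key][idx] == pytest.approx(num, abs=1e-4, rel=1e-3)


@pytest.fixture(scope="module")
def small_scaled():
    stack, truth = movae.generate_multiomics(
        n_samples=120, n_expr=60, n_mut=30, n_cnv=20, seed=2
    )
    scaled, scaling = movae.scale_stack(stack)
    return scaled, scaling, truth


class TestTraining:
    def test_loss_decreases_over_training(self, small_scaled):
        scaled, _, _ = small_scaled
        cfg = VAEConfig(n_hidden=32, n_latent=8, epochs=60, batch_size=40, seed=0)
        model, history = train(scaled, cfg)
        assert history["loss"].tail(10).mean() < history["loss"].head(10).mean()

    def test_beta_schedule_recorded_in_history(self, small_scaled):
        scaled, _, _ = small_scaled
        cfg = VAEConfig(n_hidden=8, n_latent=4, epochs=110, batch_size=60, seed=0)
        _, history = train(scaled, cfg)
        beta = history["beta"].to_numpy()
        assert beta[0] == 0.0
        assert (beta[100:] == 1.0).all()
        assert (np.diff(beta) >= 0).all()

    def test_same_seed_same_final_loss(self, small_scaled):
        scaled, _, _ = small_scaled
        cfg = VAEConfig(n_hidden=16, n_latent=4, epochs=15, batch_size=40, seed=5)
        _, h1 = train(scaled, cfg)
        _, h2 = train(scaled, cfg)
        assert h1["loss"].iloc[-1] == h2["loss"].iloc[-1]

    def test_unscaled_input_rejected(self):
        m = MultiOmicsVAE(n_hidden=4, n_latent=2, epochs=1)
        with pytest.raises(ValueError, match="scaled"):
            m.fit(np.array([[2.0, -1.0], [0.5, 0.5]]))

    def test_plain_autoencoder_reconstructs_at_least_as_well(
        self, small_scaled, monkeypatch
    ):
        scaled, _, _ = small_scaled
        cfg = VAEConfig(n_hidden=32, n_latent=8, epochs=40, batch_size=40, seed=0)
        _, h_vae = train(scaled, cfg)
        monkeypatch.setattr("movae.vae.warmup_beta", lambda epoch, kappa: 0.0)
        _, h_ae = train(scaled, cfg)
        assert (
            h_ae["reconstruction"].iloc[-1] <= h_vae["reconstruction"].iloc[-1] + 1e-9
        )


class TestTransform:
    def test_latent_is_nonnegative_with_expected_shape(self, small_scaled):
        scaled, _, _ = small_scaled
        cfg = VAEConfig(n_hidden=16, n_latent=6, epochs=10, batch_size=40, seed=0)
        model, _ = train(scaled, cfg)
        Z = transform(model, scaled)
        assert Z.values.shape == (scaled.n_samples, 6)
        assert (Z.values >= 0).all()
        assert Z.factor_ids[0] == "LF1"

    def test_duplicate_sample_gets_identical_latent_row(self, small_scaled):
        scaled, _, _ = small_scaled
        cfg = VAEConfig(n_hidden=16, n_latent=6, epochs=10, batch_size=40, seed=0)
        model, _ = train(scaled, cfg)
        X = scaled.values.T
        Z = model.transform(np.vstack([X, X[:1]]))
        np.testing.assert_array_equal(Z[0], Z[-1])

    def test_feature_mismatch_lists_offending_ids(self, small_scaled):
        scaled, _, _ = small_scaled
        cfg = VAEConfig(n_hidden=16, n_latent=6, epochs=5, batch_size=40, seed=0)
        model, _ = train(scaled, cfg)
        renamed = copy.deepcopy(scaled)
        renamed.matrices[0].feature_ids[0] = "ROGUE"
        with pytest.raises(ValueError, match="ROGUE"):
            transform(model, renamed)

    def test_checkpoint_round_trip(self, small_scaled, tmp_path):
        scaled, _, _ = small_scaled
        cfg = VAEConfig(n_hidden=16, n_latent=6, epochs=5, batch_size=40, seed=0)
        model, _ = train(scaled, cfg)
        save_model(model, tmp_path / "ckpt")
        reloaded = load_model(tmp_path / "ckpt")
        np.testing.assert_array_equal(
            model.transform(scaled.values.T), reloaded.transform(scaled.values.T)
        )


class TestStructureRecovery:
    def test_planted_clusters_recovered(self, recovery):
        score = ami(recovery["clusters"].labels, recovery["truth"].cluster_labels)
        assert score >= 0.8

    def test_two_seeds_give_consistent_partitions(self, recovery):
        scaled = recovery["scaled"]
        other = MultiOmicsVAE(
            n_hidden=128, n_latent=32, epochs=200, batch_size=100, seed=1
        )
        other.fit(scaled.values.T)
        Z2 = LatentSpace(other.transform(scaled.values.T), scaled.sample_ids)
        labels2 = kmeans_cluster(Z2, 4, n_init=100, seed=0).labels
        assert ami(recovery["clusters"].labels, labels2) >= 0.6
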