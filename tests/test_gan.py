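"""Tests for the conditional WGAN-GP building blocks and training loop."""

import numpy as np
import pandas as pd
import pytest

from scintigan.gan import (
    Checkpoint,
    GanConfig,
    build_critic,
    build_generator,
    critic_forward,
    generate,
    generator_forward,
    gradient_penalty,
    load_checkpoint,
    save_checkpoint,
    select_best_checkpoint,
    train,
)
from scintigan.phasespace import CONDITION_COLUMNS, FEATURE_COLUMNS, compute_stats, normalize


def _zero_params(sizes):
    return [
        (np.zeros((o, i), dtype=np.float32), np.zeros(o, dtype=np.float32))
        for i, o in zip(sizes[:-1], sizes[1:])
    ]


@pytest.fixture(scope="module")
def small_config():
    return GanConfig(hidden=8, latent_dim=8, batch_size=32, epochs=2, iterations_per_epoch=10, seed=1)


class TestForwardPasses:
    def test_generator_shape_contract(self, small_config):
        gen = build_generator(small_config, np.random.default_rng(0))
        out = generator_forward(
            np.zeros((5, small_config.latent_dim)), np.zeros((5, 3)), gen.params
        )
        assert out.shape == (5, 6)

    def test_zero_parameters_give_zero_output(self, small_config):
        params = _zero_params(small_config.generator_sizes)
        out = generator_forward(
            np.random.default_rng(1).normal(size=(4, small_config.latent_dim)),
            np.ones((4, 3)),
            params,
        )
        assert np.all(out == 0.0)

    def test_generator_determinism(self, small_config):
        gen = build_generator(small_config, np.random.default_rng(2))
        z = np.random.default_rng(3).normal(size=(7, small_config.latent_dim))
        c = np.random.default_rng(4).normal(size=(7, 3))
        assert np.array_equal(generator_forward(z, c, gen.params), generator_forward(z, c, gen.params))

    def test_generator_dimension_mismatch(self, small_config):
        gen = build_generator(small_config, np.random.default_rng(5))
        with pytest.raises(ValueError):
            generator_forward(np.zeros((3, 2)), np.zeros((3, 3)), gen.params)

    def test_critic_shape_and_row_independence(self, small_config):
        critic = build_critic(small_config, np.random.default_rng(6))
        x = np.random.default_rng(7).normal(size=(1, 6))
        c = np.random.default_rng(8).normal(size=(1, 3))
        s1 = critic_forward(x, c, critic.params)
        assert s1.shape == (1,)
        s2 = critic_forward(np.vstack([x, x]), np.vstack([c, c]), critic.params)
        assert s2[0] == s2[1]  # identical rows score identically
        assert s2[0] == pytest.approx(s1[0], rel=1e-5)  # float32 batch round-off

    def test_critic_zero_params(self, small_config):
        params = _zero_params(small_config.critic_sizes)
        scores = critic_forward(np.ones((3, 6)), np.ones((3, 3)), params)
        assert np.all(scores == 0.0)


class TestGradientPenalty:
    def _linear_critic(self, weights):
        # single-layer critic over [features(6), condition(3)]
        w = np.zeros((1, 9), dtype=np.float32)
        w[0, :6] = weights
        return [(w, np.zeros(1, dtype=np.float32))]

    def test_unit_gradient_linear_critic(self):
        w = np.zeros(6)
        w[0] = 1.0  # gradient norm exactly 1
        params = self._linear_critic(w)
        rng = np.random.default_rng(0)
        p = gradient_penalty(rng.normal(size=(16, 6)), rng.normal(size=(16, 6)),
                             rng.normal(size=(16, 3)), params, seed=1)
        assert p == pytest.approx(0.0, abs=1e-10)

    def test_constant_critic(self):
        params = self._linear_critic(np.zeros(6))
        rng = np.random.default_rng(1)
        p = gradient_penalty(rng.normal(size=(8, 6)), rng.normal(size=(8, 6)),
                             rng.normal(size=(8, 3)), params, seed=2)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_gradient_norm_three(self):
        w = np.zeros(6)
        w[1] = 3.0
        params = self._linear_critic(w)
        rng = np.random.default_rng(2)
        p = gradient_penalty(rng.normal(size=(8, 6)), rng.normal(size=(8, 6)),
                             rng.normal(size=(8, 3)), params, seed=3)
        assert p == pytest.approx(4.0, abs=1e-6)

    def test_shape_mismatch(self):
        params = self._linear_critic(np.ones(6))
        with pytest.raises(ValueError):
            gradient_penalty(np.zeros((4, 6)), np.zeros((5, 6)), np.zeros((4, 3)), params)


class TestWassersteinOracle:
    def test_linear_critic_loss_gradient_is_mean_difference(self):
        """For f(x) = w.x the critic-loss gradient dL/dw is E[fake] - E[real],
        the analytic Wasserstein-1 gradient for two point masses in 1-D."""
        from scintigan._nn import DenseNet

        net = DenseNet([], rng=None)
        net.set_params([(np.array([[0.5] + [0.0] * 8], dtype=np.float32),
                        np.zeros(1, dtype=np.float32))])
        real = np.zeros((64, 9), dtype=np.float32)
        fake = np.zeros((64, 9), dtype=np.float32)
        real[:, 0] = 1.0   # point mass at x=1
        fake[:, 0] = -2.0  # point mass at x=-2
        _, cache_f = net.forward(fake, return_cache=True)
        _, cache_r = net.forward(real, return_cache=True)
        one = np.full((64, 1), 1.0 / 64, dtype=np.float32)
        gf, _ = net.backward(cache_f, one)
        gr, _ = net.backward(cache_r, -one)
        grad_w = gf[0][0] + gr[0][0]
        assert grad_w[0, 0] == pytest.approx(-2.0 - 1.0, abs=1e-6)


class TestTraining:
    def _toy_problem(self, n=512, seed=0):
        """Degenerate target: features are a fixed constant vector per condition."""
        rng = np.random.default_rng(seed)
        half = n // 2
        rows = []
        for label, const in ((0.0, 0.5), (1.0, -0.5)):
            feats = np.full((half, 6), const) + rng.normal(0, 0.02, size=(half, 6))
            for f in feats:
                rows.append(list(f) + [label, label, 5.0 + label])
        table = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS + CONDITION_COLUMNS))
        return table.sample(frac=1.0, random_state=1).reset_index(drop=True)

    def test_smoke_run_bookkeeping(self, small_config):
        table = self._toy_problem()
        stats = compute_stats(table)
        result = train(normalize(table, stats), stats, small_config, reference=[])
        assert [c.epoch for c in result.checkpoints] == [1, 2]
        assert result.generator_updates == 2 * 10
        assert result.critic_updates == 3 * result.generator_updates  # exact 3:1 ratio
        assert set(result.history.columns) >= {"epoch", "critic_loss", "generator_loss", "penalty"}

    def test_point_mass_recovery(self):
        """A short run pulls the generated mean toward a two-point target."""
        table = self._toy_problem(n=2048, seed=3)
        stats = compute_stats(table)
        config = GanConfig(
            hidden=16, latent_dim=8, batch_size=128, epochs=2, iterations_per_epoch=150,
            learning_rate=1e-3, seed=4,
        )
        norm = normalize(table, stats)
        result = train(norm, stats, config, reference=[])
        ckpt = result.checkpoints[-1]
        for label in (0.0, 1.0):
            cond_rows = norm[np.isclose(norm["emX"], ((label - stats.mean[6]) / stats.std[6]))]
            target = cond_rows[list(FEATURE_COLUMNS)].mean().to_numpy()
            z = np.random.default_rng(5).standard_normal((512, config.latent_dim))
            cond = np.tile(cond_rows[list(CONDITION_COLUMNS)].iloc[0].to_numpy(), (512, 1))
            out = generator_forward(z, cond, ckpt.generator_params)
            assert np.abs(out.mean(axis=0) - target).max() < 0.35

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")  # deliberate blow-up
    def test_nan_abort_names_iteration(self):
        table = self._toy_problem()
        stats = compute_stats(table)
        config = GanConfig(hidden=8, latent_dim=8, batch_size=32, epochs=1,
                           iterations_per_epoch=5, learning_rate=1e6, seed=6)
        with pytest.raises(RuntimeError, match="epoch"):
            train(normalize(table, stats), stats, config, reference=[])


class TestCheckpointSelection:
    def _ckpt(self, epoch, sim):
        config = GanConfig(hidden=8, latent_dim=8, epochs=1, iterations_per_epoch=1)
        return Checkpoint(epoch=epoch, generator_params=[], config=config, similarity=sim)

    def test_argmax(self):
        cks = [self._ckpt(1, 0.8), self._ckpt(2, 0.95), self._ckpt(3, 0.9)]
        assert select_best_checkpoint(cks).epoch == 2

    def test_singleton(self):
        cks = [self._ckpt(1, 0.7)]
        assert select_best_checkpoint(cks) is cks[0]

    def test_tie_goes_to_later_epoch(self):
        cks = [self._ckpt(1, 0.9), self._ckpt(2, 0.9)]
        assert select_best_checkpoint(cks).epoch == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best_checkpoint([])

    def test_similarity_bounds_validated(self):
        with pytest.raises(ValueError):
            self._ckpt(1, 1.5)


class TestCheckpointPersistence:
    def test_round_trip_reproduces_probe_outputs(self, tiny_checkpoint, tmp_path):
        path = tmp_path / "ckpt.npz"
        save_checkpoint(tiny_checkpoint, path)
        loaded = load_checkpoint(path)
        assert loaded.epoch == tiny_checkpoint.epoch
        assert loaded.similarity == tiny_checkpoint.similarity
        assert loaded.stats.dataset_hash == tiny_checkpoint.stats.dataset_hash
        z = np.random.default_rng(9).standard_normal((16, tiny_checkpoint.config.latent_dim))
        c = np.zeros((16, 3))
        a = generator_forward(z, c, tiny_checkpoint.generator_params)
        b = generator_forward(z, c, loaded.generator_params)
        assert np.array_equal(a, b)

    def test_generate_denormalizes_to_physical_scale(self, tiny_checkpoint):
        out = generate(tiny_checkpoint, (0.5, 0.5, 1.0), 100, seed=1)
        assert list(out.columns) == list(FEATURE_COLUMNS)
        assert len(out) == 100
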