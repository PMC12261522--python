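"""Conditional Wasserstein GAN with gradient penalty for phase-space data.

The generator maps a standard-normal latent vector concatenated with
the (normalized) emission coordinates to the six phase-space features;
the critic scores feature/condition pairs with an unbounded real value.
Hidden widths follow the H, 2H, 2H, 4H (generator) and 4H, 2H, 2H, H
(critic) ladder with ReLU activations and a linear generator output.
Training minimizes the Wasserstein critic loss

    L_C = E[f(fake)] - E[f(real)] + lambda * E[(||grad f(x_hat)|| - 1)^2]

with x_hat interpolated uniformly between real and fake feature rows
(the gradient is taken w.r.t. the feature part of the critic input),
and the generator loss L_G = -E[f(fake)].  Both networks use Adam with
beta1 = 0.5, beta2 = 0.9 at a 3:1 critic:generator update ratio.

A checkpoint is stored after every epoch and scored by mean 1 - JSD
similarity between generated and held-out reference samples; the best
checkpoint (ties broken toward the later epoch) is the one shipped to
the generation pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._nn import Adam, DenseNet
from .evaluation import similarity_report
from .phasespace import CONDITION_COLUMNS, FEATURE_COLUMNS, NormalizationStats, denormalize

__all__ = [
    "GanConfig",
    "Checkpoint",
    "TrainingResult",
    "build_generator",
    "build_critic",
    "generator_forward",
    "critic_forward",
    "gradient_penalty",
    "train",
    "select_best_checkpoint",
    "save_checkpoint",
    "load_checkpoint",
    "generate",
]


@dataclass
class GanConfig:
    """Architecture and optimizer settings for the conditional WGAN-GP."""

    hidden: int = 128  # H
    latent_dim: int = 64
    feature_dim: int = 6
    condition_dim: int = 3
    learning_rate: float = 5e-5
    adam_beta1: float = 0.5
    adam_beta2: float = 0.9
    critic_updates_per_generator_update: int = 3
    gp_lambda: float = 10.0
    batch_size: int = 1024
    epochs: int = 10
    iterations_per_epoch: int = 100
    seed: int = 0
    #: decay of the exponential moving average of generator weights used for
    #: checkpoints (0 disables averaging and checkpoints the raw weights)
    ema_decay: float = 0.0
    #: the generator's output layer starts at this fraction of its He-init
    #: scale, so initial samples sit near the (z-scored) data mean
    generator_final_init_scale: float = 0.1

    def __post_init__(self) -> None:
        counts = (
            self.hidden,
            self.latent_dim,
            self.feature_dim,
            self.condition_dim,
            self.critic_updates_per_generator_update,
            self.batch_size,
            self.epochs,
            self.iterations_per_epoch,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all GanConfig counts must be positive")
        if self.gp_lambda < 0:
            raise ValueError("gp_lambda must be non-negative")
        if not 0.0 <= self.ema_decay < 1.0:
            raise ValueError("ema_decay must lie in [0, 1)")

    @property
    def generator_sizes(self):
        H = self.hidden
        return [self.latent_dim + self.condition_dim, H, 2 * H, 2 * H, 4 * H, self.feature_dim]

    @property
    def critic_sizes(self):
        H = self.hidden
        return [self.feature_dim + self.condition_dim, 4 * H, 2 * H, 2 * H, H, 1]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GanConfig":
        return cls(**d)


@dataclass
class Checkpoint:
    """Generator snapshot after one epoch, with its similarity score."""

    epoch: int
    generator_params: list
    config: GanConfig
    stats: NormalizationStats | None = None
    similarity: float | None = None
    critic_params: list | None = None

    def __post_init__(self) -> None:
        if self.similarity is not None and not (0.0 <= self.similarity <= 1.0 + 1e-12):
            raise ValueError("similarity score must lie in [0, 1]")


@dataclass
class TrainingResult:
    """Checkpoints plus the per-epoch training log and update counters."""

    checkpoints: list
    history: pd.DataFrame
    critic_updates: int
    generator_updates: int

    def __iter__(self):
        return iter(self.checkpoints)

    def __len__(self):
        return len(self.checkpoints)


# ---------------------------------------------------------------------------
# network construction and functional forward passes
# ---------------------------------------------------------------------------


def build_generator(config: GanConfig, rng) -> DenseNet:
    net = DenseNet(config.generator_sizes, rng=rng)
    scale = np.float32(config.generator_final_init_scale)
    if scale != 1.0:
        w, b = net.params[-1]
        net.params[-1] = (w * scale, b)
    return net


def build_critic(config: GanConfig, rng) -> DenseNet:
    return DenseNet(config.critic_sizes, rng=rng)


def _net_from_params(params) -> DenseNet:
    net = DenseNet(sizes=[], rng=None)
    net.set_params(params)
    return net


def generator_forward(latent, condition, params):
    """Map (latent, condition) batches to normalized feature batches."""
    latent = np.asarray(latent, dtype=np.float32)
    condition = np.asarray(condition, dtype=np.float32)
    if latent.ndim != 2 or condition.ndim != 2 or latent.shape[0] != condition.shape[0]:
        raise ValueError("latent and condition must be 2-D with equal row counts")
    net = _net_from_params(params)
    expected = net.params[0][0].shape[1]
    if latent.shape[1] + condition.shape[1] != expected:
        raise ValueError(
            f"generator expects input width {expected}, got "
            f"{latent.shape[1]} + {condition.shape[1]}"
        )
    return net.forward(np.concatenate([latent, condition], axis=1))


def critic_forward(features, condition, params):
    """Score feature/condition batches; one unbounded real per row."""
    features = np.asarray(features, dtype=np.float32)
    condition = np.asarray(condition, dtype=np.float32)
    if features.ndim != 2 or condition.ndim != 2 or features.shape[0] != condition.shape[0]:
        raise ValueError("features and condition must be 2-D with equal row counts")
    net = _net_from_params(params)
    expected = net.params[0][0].shape[1]
    if features.shape[1] + condition.shape[1] != expected:
        raise ValueError(
            f"critic expects input width {expected}, got "
            f"{features.shape[1]} + {condition.shape[1]}"
        )
    return net.forward(np.concatenate([features, condition], axis=1))[:, 0]


def _penalty_and_grads(critic: DenseNet, x_real, x_fake, condition, rng, feature_dim):
    """Gradient penalty value and its parameter gradients at one interpolate batch."""
    n = x_real.shape[0]
    eps = rng.random((n, 1), dtype=np.float32)
    x_hat = eps * x_real + (1.0 - eps) * x_fake
    inp = np.concatenate([x_hat, condition], axis=1)
    _, cache = critic.forward(inp, return_cache=True)
    g_full, s_list = critic.input_gradient(cache)
    g = g_full[:, :feature_dim]
    norm = np.sqrt(np.sum(g.astype(np.float64) ** 2, axis=1))
    penalty = float(np.mean((norm - 1.0) ** 2))
    safe = np.maximum(norm, 1e-12)
    coef = (2.0 * (norm - 1.0) / safe / n).astype(np.float32)
    r = np.zeros_like(g_full)
    r[:, :feature_dim] = coef[:, None] * g
    grads = critic.gradient_penalty_grads(cache, s_list, r)
    return penalty, grads


def gradient_penalty(real_batch, fake_batch, condition, params, seed=None, rng=None):
    """WGAN-GP penalty E[(||grad_x critic(x_hat, cond)|| - 1)^2].

    ``x_hat`` interpolates uniformly between real and fake feature rows;
    the gradient is taken with respect to the interpolated features.
    """
    real = np.asarray(real_batch, dtype=np.float32)
    fake = np.asarray(fake_batch, dtype=np.float32)
    condition = np.asarray(condition, dtype=np.float32)
    if real.shape != fake.shape:
        raise ValueError("real and fake batches must have the same shape")
    rng = np.random.default_rng(seed) if rng is None else rng
    critic = _net_from_params(params)
    penalty, _ = _penalty_and_grads(critic, real, fake, condition, rng, real.shape[1])
    return penalty


def _accumulate(*grad_lists, weights=None):
    weights = weights or [1.0] * len(grad_lists)
    out = []
    for layer in zip(*grad_lists):
        dw = sum(w * g[0] for w, g in zip(weights, layer))
        db = sum(w * g[1] for w, g in zip(weights, layer))
        out.append((dw.astype(np.float32), db.astype(np.float32)))
    return out


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _normalized_condition(point, stats: NormalizationStats):
    cond_stats = stats.subset(CONDITION_COLUMNS)
    return ((np.asarray(point, dtype=float) - cond_stats.mean) / cond_stats.std).astype(np.float32)


def _evaluate_similarity(gen: DenseNet, stats, reference, config, rng, n_bins=100):
    """Mean 1 - JSD similarity of generated vs reference samples over points."""
    scores = []
    for point, ref_table in reference:
        n = len(ref_table)
        cond = np.tile(_normalized_condition(point, stats), (n, 1))
        z = rng.standard_normal((n, config.latent_dim)).astype(np.float32)
        feats = gen.forward(np.concatenate([z, cond], axis=1))
        gen_table = pd.DataFrame(np.asarray(feats, dtype=float), columns=list(FEATURE_COLUMNS))
        gen_table = denormalize(gen_table, stats.subset(FEATURE_COLUMNS))
        rep = similarity_report(ref_table, gen_table, n_bins=n_bins)
        scores.append(rep.mean_similarity)
    return float(np.mean(scores))


def train(dataset, stats, config: GanConfig, reference, log_path=None) -> TrainingResult:
    """Train the conditional WGAN-GP on a normalized phase-space table.

    Parameters
    ----------
    dataset
        Phase-space table already normalized with *stats* (all nine
        columns z-scored).
    stats
        The :class:`NormalizationStats` used to normalize *dataset*;
        stored in every checkpoint for denormalization at generation
        time.
    config
        Architecture and optimizer settings.
    reference
        Sequence of ``(emission_point, table)`` pairs with held-out
        simulator tables in physical units, used to score each epoch's
        checkpoint by mean 1 - JSD similarity.
    log_path
        Optional CSV path for the per-epoch training log.
    """
    feats = dataset[list(FEATURE_COLUMNS)].to_numpy(dtype=np.float32)
    conds = dataset[list(CONDITION_COLUMNS)].to_numpy(dtype=np.float32)
    n = feats.shape[0]
    reference = list(reference)

    ss = np.random.SeedSequence(config.seed)
    init_rng, batch_rng, eval_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    gen = build_generator(config, init_rng)
    critic = build_critic(config, init_rng)
    opt_g = Adam(gen, config.learning_rate, config.adam_beta1, config.adam_beta2)
    opt_c = Adam(critic, config.learning_rate, config.adam_beta1, config.adam_beta2)

    B = config.batch_size
    fdim = config.feature_dim
    ema_params = gen.copy_params() if config.ema_decay > 0.0 else None
    checkpoints = []
    history_rows = []
    critic_updates = 0
    generator_updates = 0

    for epoch in range(1, config.epochs + 1):
        ep_closs = ep_gloss = ep_pen = 0.0
        for it in range(config.iterations_per_epoch):
            for _ in range(config.critic_updates_per_generator_update):
                idx = batch_rng.integers(0, n, size=B)
                real, cond = feats[idx], conds[idx]
                z = batch_rng.standard_normal((B, config.latent_dim)).astype(np.float32)
                fake = gen.forward(np.concatenate([z, cond], axis=1))

                out_f, cache_f = critic.forward(
                    np.concatenate([fake, cond], axis=1), return_cache=True
                )
                out_r, cache_r = critic.forward(
                    np.concatenate([real, cond], axis=1), return_cache=True
                )
                w_loss = float(out_f.mean() - out_r.mean())
                one = np.full((B, 1), 1.0 / B, dtype=np.float32)
                grads_f, _ = critic.backward(cache_f, one)
                grads_r, _ = critic.backward(cache_r, -one)
                penalty, grads_p = _penalty_and_grads(critic, real, fake, cond, batch_rng, fdim)
                total = _accumulate(
                    grads_f, grads_r, grads_p, weights=[1.0, 1.0, config.gp_lambda]
                )
                c_loss = w_loss + config.gp_lambda * penalty
                if not np.isfinite(c_loss):
                    raise RuntimeError(
                        f"non-finite critic loss at epoch {epoch}, iteration {it}"
                    )
                opt_c.step(total)
                critic_updates += 1

            idx = batch_rng.integers(0, n, size=B)
            cond = conds[idx]
            z = batch_rng.standard_normal((B, config.latent_dim)).astype(np.float32)
            gen_in = np.concatenate([z, cond], axis=1)
            fake, cache_g = gen.forward(gen_in, return_cache=True)
            out, cache_c = critic.forward(
                np.concatenate([fake, cond], axis=1), return_cache=True
            )
            g_loss = float(-out.mean())
            if not np.isfinite(g_loss):
                raise RuntimeError(f"non-finite generator loss at epoch {epoch}, iteration {it}")
            _, grad_in = critic.backward(cache_c, np.full((B, 1), -1.0 / B, dtype=np.float32))
            gen_grads, _ = gen.backward(cache_g, grad_in[:, :fdim])
            opt_g.step(gen_grads)
            generator_updates += 1
            if config.ema_decay > 0.0:
                d = np.float32(config.ema_decay)
                ema_params = [
                    (d * ew + (1 - d) * w, d * eb + (1 - d) * b)
                    for (ew, eb), (w, b) in zip(ema_params, gen.params)
                ]

            ep_closs += c_loss
            ep_gloss += g_loss
            ep_pen += penalty

        k = config.iterations_per_epoch
        ckpt_net = gen if ema_params is None else _net_from_params(ema_params)
        score = (
            _evaluate_similarity(ckpt_net, stats, reference, config, eval_rng)
            if reference
            else None
        )
        checkpoints.append(
            Checkpoint(
                epoch=epoch,
                generator_params=ckpt_net.copy_params(),
                config=config,
                stats=stats,
                similarity=score,
                critic_params=None,
            )
        )
        history_rows.append(
            {
                "epoch": epoch,
                "critic_loss": ep_closs / k,
                "generator_loss": ep_gloss / k,
                "penalty": ep_pen / k,
                "similarity": score,
            }
        )

    history = pd.DataFrame(history_rows)
    if log_path is not None:
        history.to_csv(log_path, index=False)
    return TrainingResult(
        checkpoints=checkpoints,
        history=history,
        critic_updates=critic_updates,
        generator_updates=generator_updates,
    )


def select_best_checkpoint(checkpoints) -> Checkpoint:
    """Checkpoint with maximal similarity; ties go to the later epoch."""
    if isinstance(checkpoints, TrainingResult):
        checkpoints = checkpoints.checkpoints
    checkpoints = [c for c in checkpoints if c.similarity is not None]
    if not checkpoints:
        raise ValueError("no checkpoints with a similarity score")
    return max(checkpoints, key=lambda c: (c.similarity, c.epoch))


# ---------------------------------------------------------------------------
# checkpoint persistence and generation
# ---------------------------------------------------------------------------


def save_checkpoint(checkpoint: Checkpoint, path) -> None:
    """Persist a checkpoint as a single .npz container."""
    arrays = {}
    for i, (w, b) in enumerate(checkpoint.generator_params):
        arrays[f"gen_w{i}"] = w
        arrays[f"gen_b{i}"] = b
    meta = {
        "epoch": checkpoint.epoch,
        "similarity": checkpoint.similarity,
        "config": checkpoint.config.to_dict(),
        "stats": checkpoint.stats.to_dict() if checkpoint.stats is not None else None,
        "n_gen_layers": len(checkpoint.generator_params),
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> Checkpoint:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"].tobytes()).decode())
        params = [
            (data[f"gen_w{i}"], data[f"gen_b{i}"]) for i in range(meta["n_gen_layers"])
        ]
    return Checkpoint(
        epoch=meta["epoch"],
        generator_params=params,
        config=GanConfig.from_dict(meta["config"]),
        stats=NormalizationStats.from_dict(meta["stats"]) if meta["stats"] else None,
        similarity=meta["similarity"],
    )


def generate(checkpoint: Checkpoint, point, n, seed=None, rng=None, batch_rows=65536):
    """Sample ``n`` denormalized feature rows at one emission point."""
    if checkpoint.stats is None:
        raise ValueError("checkpoint carries no normalization statistics")
    rng = np.random.default_rng(seed) if rng is None else rng
    config = checkpoint.config
    cond = np.tile(_normalized_condition(point, checkpoint.stats), (n, 1))
    z = rng.standard_normal((n, config.latent_dim)).astype(np.float32)
    net = _net_from_params(checkpoint.generator_params)
    outs = []
    for start in range(0, n, batch_rows):
        sl = slice(start, min(start + batch_rows, n))
        outs.append(net.forward(np.concatenate([z[sl], cond[sl]], axis=1)))
    feats = np.concatenate(outs, axis=0) if outs else np.empty((0, config.feature_dim), np.float32)
    table = pd.DataFrame(np.asarray(feats, dtype=float), columns=list(FEATURE_COLUMNS))
    return denormalize(table, checkpoint.stats.subset(FEATURE_COLUMNS))
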