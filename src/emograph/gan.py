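"""1-D convolutional GAN for per-class EEG segment augmentation.

A generator maps a latent noise vector to one 3-channel, 125-sample segment;
a discriminator scores segments as real or generated.  Training alternates
discriminator and generator updates on the two-term minimax value

    V(G, D) = E_x[log D(x)] + E_z[log(1 - D(G(z)))]

which the discriminator ascends.  The generator uses the standard
non-saturating surrogate (maximize log D(G(z))); V is still what the history
records.  Augmentation is restricted to training-split windows of a single
class — feeding any validation or test window in is a hard error, since
generated samples join the training set downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .preprocess import WindowSet, SPLIT_CODES

__all__ = ["GANConfig", "GANPair", "gan_value", "train_gan", "synthesize",
           "DataLeakageError"]

EPS = 1e-7


class DataLeakageError(ValueError):
    """Raised when non-training windows reach the GAN."""


@dataclass(frozen=True)
class GANConfig:
    n_conv_layers: int = 6
    optimizer_name: str = "adamax"
    learning_rate: float = 0.001
    batch_size: int = 8
    latent_dim: int = 64
    segment_len: int = 125
    n_channels: int = 3
    epochs: int = 30
    hidden_channels: int = 16
    # kernel spans >= one alpha-band period at 500 Hz; shorter kernels leave
    # the discriminator blind to band structure and the adversary oscillates
    kernel: int = 31
    seed: int = 0

    def __post_init__(self):
        if self.latent_dim <= 0 or self.batch_size <= 0:
            raise ValueError("latent_dim and batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.n_conv_layers < 1:
            raise ValueError("need at least one conv layer")


def gan_value(d_real, d_fake) -> float:
    """Empirical minimax value mean(log D(x)) + mean(log(1 - D(G(z)))).

    Probabilities are clamped to [EPS, 1 - EPS] before the logs.
    """
    d_real = np.asarray(d_real, dtype=float).ravel()
    d_fake = np.asarray(d_fake, dtype=float).ravel()
    if d_real.size == 0 or d_fake.size == 0:
        raise ValueError("empty probability batch")
    d_real = np.clip(d_real, EPS, 1.0 - EPS)
    d_fake = np.clip(d_fake, EPS, 1.0 - EPS)
    return float(np.log(d_real).mean() + np.log(1.0 - d_fake).mean())


def _build_generator(cfg: GANConfig, rng) -> nn.Sequential:
    c, L, h = cfg.n_channels, cfg.segment_len, cfg.hidden_channels
    layers = [
        nn.Dense(cfg.latent_dim, h * L, rng),
        nn.LeakyReLU(0.2),
        nn.Reshape((h, L)),
    ]
    chans = [h] * cfg.n_conv_layers + [c]
    for i in range(cfg.n_conv_layers):
        layers.append(nn.Conv1d(chans[i], chans[i + 1], cfg.kernel, rng))
        if i < cfg.n_conv_layers - 1:
            layers.append(nn.LeakyReLU(0.2))
    return nn.Sequential(*layers)


def _build_discriminator(cfg: GANConfig, rng) -> nn.Sequential:
    c, L, h = cfg.n_channels, cfg.segment_len, cfg.hidden_channels
    l1 = (L + 2 * (cfg.kernel // 2) - cfg.kernel) // 2 + 1
    l2 = (l1 + 2 * (cfg.kernel // 2) - cfg.kernel) // 2 + 1
    return nn.Sequential(
        nn.Conv1d(c, h, cfg.kernel, rng, stride=2),
        nn.LeakyReLU(0.2),
        nn.Conv1d(h, h, cfg.kernel, rng, stride=2),
        nn.LeakyReLU(0.2),
        nn.Flatten(),
        nn.Dense(h * l2, 1, rng),
        nn.Sigmoid(),
    )


@dataclass
class GANPair:
    """Generator/discriminator pair with training history."""

    config: GANConfig
    generator: nn.Sequential
    discriminator: nn.Sequential
    scale: float = 1.0            # real-data std used for normalization
    history: list = field(default_factory=list)   # (epoch, V_D, V_G)
    trained: bool = False

    def generate(self, n_segments: int, rng: np.random.Generator) -> np.ndarray:
        """[n_segments, n_channels, segment_len] in original signal units."""
        z = rng.standard_normal((n_segments, self.config.latent_dim))
        return self.generator.forward(z) * self.scale

    def discriminate(self, segments: np.ndarray) -> np.ndarray:
        return self.discriminator.forward(
            np.asarray(segments, dtype=float) / self.scale).ravel()


def train_gan(real: WindowSet, config: GANConfig) -> GANPair:
    """Train on training-split windows of one class.

    Per batch: one discriminator ascent step on real + generated segments,
    then one generator step on fresh noise.  The recorded history holds the
    empirical V(G, D) for the discriminator and the generator objective.
    """
    if len(real) == 0:
        raise ValueError("no training windows supplied")
    if np.any(real.split != SPLIT_CODES["train"]):
        raise DataLeakageError(
            "GAN input must contain only training-split windows")
    if np.unique(real.labels).size != 1:
        raise ValueError("GAN input must contain a single class")

    rng = np.random.default_rng(config.seed)
    G = _build_generator(config, rng)
    D = _build_discriminator(config, rng)
    x_all = np.asarray(real.windows, dtype=np.float64)
    scale = float(x_all.std()) or 1.0
    x_all = x_all / scale
    pair = GANPair(config, G, D, scale=scale)

    opt_d = nn.make_optimizer(config.optimizer_name, D.all_params, D.all_grads,
                              lr=config.learning_rate)
    opt_g = nn.make_optimizer(config.optimizer_name, G.all_params, G.all_grads,
                              lr=config.learning_rate)
    n = x_all.shape[0]
    bs = min(config.batch_size, n)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        v_d_sum, v_g_sum, n_batches = 0.0, 0.0, 0
        for start in range(0, n - bs + 1, bs):
            xb = x_all[order[start:start + bs]]
            # --- discriminator step (ascend V)
            z = rng.standard_normal((bs, config.latent_dim))
            fake = G.forward(z)
            D.zero_grad()
            p_real = D.forward(xb, training=True)
            _, d_real = nn.bce_loss(p_real, 1.0, eps=EPS)
            D.backward(d_real)
            p_fake = D.forward(fake, training=True)
            _, d_fake = nn.bce_loss(p_fake, 0.0, eps=EPS)
            D.backward(d_fake)
            opt_d.step()
            v_d_sum += gan_value(p_real, p_fake)
            # --- generator step (non-saturating: maximize log D(G(z)))
            z = rng.standard_normal((bs, config.latent_dim))
            G.zero_grad()
            D.zero_grad()
            fake = G.forward(z, training=True)
            p = D.forward(fake, training=True)
            loss_g, dp = nn.bce_loss(p, 1.0, eps=EPS)
            G.backward(D.backward(dp))
            opt_g.step()
            v_g_sum += loss_g
            n_batches += 1
        if n_batches:
            pair.history.append(
                (epoch, v_d_sum / n_batches, v_g_sum / n_batches))
    pair.trained = True
    return pair


def synthesize(pair: GANPair, n_samples_total: int, seed: int = 0,
               ) -> np.ndarray:
    """Generate a [n_channels, n_samples_total] signal by concatenating
    generated segments (ceil to whole segments, truncate the tail)."""
    if not pair.trained:
        raise RuntimeError("GAN pair has not been trained")
    if n_samples_total < 0:
        raise ValueError("n_samples_total must be >= 0")
    c = pair.config.n_channels
    if n_samples_total == 0:
        return np.empty((c, 0))
    seg = pair.config.segment_len
    n_seg = -(-n_samples_total // seg)
    rng = np.random.default_rng(seed)
    segments = pair.generate(n_seg, rng)          # [n_seg, c, seg]
    out = segments.transpose(1, 0, 2).reshape(c, n_seg * seg)
    return out[:, :n_samples_total]


def augment_class(real_train: WindowSet, config: GANConfig,
                  target_samples: int, seed: int = 0):
    """Train a GAN on one class's training windows and return a stacked
    real+generated signal truncated to ``target_samples`` (provenance
    tracked), plus the trained pair."""
    from .preprocess import StackedClassSignal
    from .synthgen import LABELS

    pair = train_gan(real_train, config)
    wins = np.asarray(real_train.windows, dtype=np.float64)
    real_sig = wins.transpose(1, 0, 2).reshape(wins.shape[1], -1)
    n_real = real_sig.shape[1]
    n_gan = max(0, target_samples - n_real)
    if n_gan > 0:
        gen = synthesize(pair, n_gan, seed=seed)
        sig = np.concatenate([real_sig, gen], axis=1)
        prov = [(0, n_real, "real"), (n_real, n_real + n_gan, "gan")]
    else:
        sig = real_sig[:, :target_samples]
        prov = [(0, target_samples, "real")]
    label = LABELS[int(real_train.labels[0])]
    pid = int(real_train.participant_ids[0])
    stacked = StackedClassSignal(sig[:, :target_samples], label, pid,
                                 provenance=[(s, min(e, target_samples), t)
                                             for s, e, t in prov
                                             if s < target_samples])
    return stacked, pair
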