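"""Conditional GAN over min-max-normalised molecular descriptors.

The generator maps (noise, class-label embedding) to a descriptor vector
through fully connected layers of 128 and 256 units with batch
normalisation and LeakyReLU, ending in a sigmoid so outputs live in (0, 1)
— the range of min-max-scaled training descriptors.  The discriminator sees
(descriptor vector, label embedding) through 256- and 128-unit LeakyReLU
layers and emits a real/fake probability.  Both are trained adversarially
with binary cross-entropy and Adam (lr 1e-4, β1 0.5, β2 0.999), one-sided
label smoothing on the real targets, and a single seeded random stream, so
a run is bit-reproducible on one platform (single-threaded NumPy).

Organised statsmodels-style: ``ConditionalGAN(table, config)`` is the model,
``.fit()`` returns a :class:`GANResults` carrying the trained parameters,
the per-epoch loss history, and ``sample()`` for class-conditional
generation back in original descriptor units.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn, scaling
from .errors import DivergenceError, ValidationError
from .tables import ID_COL, LABEL_COL, LABELS, SYNTHETIC_PREFIX, feature_columns

_LABEL_INDEX = {label: i for i, label in enumerate(LABELS)}


@dataclass(frozen=True)
class CganConfig:
    """Architecture and optimisation settings.

    Layer widths, learning rate, Adam betas, epoch count and the global
    seed follow the reference workflow; noise/embedding dimensions, batch
    size, LeakyReLU slope and the smoothing target are free choices exposed
    here (common GAN practice defaults).
    """

    noise_dim: int = 64
    label_embedding_dim: int = 8
    generator_hidden: tuple[int, int] = (128, 256)
    discriminator_hidden: tuple[int, int] = (256, 128)
    leaky_slope: float = 0.2
    real_label_smoothing: float = 0.9
    epochs: int = 1000
    batch_size: int = 32
    learning_rate: float = 1e-4
    beta1: float = 0.5
    beta2: float = 0.999
    seed: int = 42

    def __post_init__(self) -> None:
        counts = (
            self.noise_dim,
            self.label_embedding_dim,
            *self.generator_hidden,
            *self.discriminator_hidden,
            self.epochs,
            self.batch_size,
        )
        if any(int(c) != c or c < 1 for c in counts):
            raise ValidationError("all size/count settings must be positive integers")
        if not self.learning_rate > 0:
            raise ValidationError("learning_rate must be positive")
        if not 0 < self.real_label_smoothing <= 1:
            raise ValidationError("real_label_smoothing must lie in (0, 1]")


def build_generator(config: CganConfig, n_features: int, rng: np.random.Generator):
    """(noise, label) -> descriptor vector in (0,1)^n_features."""
    if n_features < 1:
        raise ValidationError("n_features must be positive")
    h1, h2 = config.generator_hidden
    net = nn.Sequential(
        [
            nn.Dense(config.noise_dim + config.label_embedding_dim, h1, rng),
            nn.BatchNorm1d(h1),
            nn.LeakyReLU(config.leaky_slope),
            nn.Dense(h1, h2, rng),
            nn.BatchNorm1d(h2),
            nn.LeakyReLU(config.leaky_slope),
            nn.Dense(h2, n_features, rng),
            nn.Sigmoid(),
        ]
    )
    embedding = nn.Embedding(len(LABELS), config.label_embedding_dim, rng)
    return net, embedding


def build_discriminator(config: CganConfig, n_features: int, rng: np.random.Generator):
    """(descriptor vector, label) -> real/fake logit (sigmoid applied at use)."""
    if n_features < 1:
        raise ValidationError("n_features must be positive")
    h1, h2 = config.discriminator_hidden
    net = nn.Sequential(
        [
            nn.Dense(n_features + config.label_embedding_dim, h1, rng),
            nn.LeakyReLU(config.leaky_slope),
            nn.Dense(h1, h2, rng),
            nn.LeakyReLU(config.leaky_slope),
            nn.Dense(h2, 1, rng),
        ]
    )
    embedding = nn.Embedding(len(LABELS), config.label_embedding_dim, rng)
    return net, embedding


class ConditionalGAN:
    """Model object: a labelled descriptor table plus a :class:`CganConfig`.

    The min-max scaler is fit internally on the full provided table, so the
    caller passes descriptors in original units.
    """

    def __init__(self, table: pd.DataFrame, config: CganConfig | None = None):
        if LABEL_COL not in table.columns:
            raise ValidationError("training table must carry a label column")
        counts = table[LABEL_COL].value_counts()
        for label in LABELS:
            if counts.get(label, 0) < 2:
                raise ValidationError(f"need at least 2 rows of class {label!r}")
        unknown = set(table[LABEL_COL]) - set(LABELS)
        if unknown:
            raise ValidationError(f"unknown labels {sorted(unknown)}")
        self.table = table.reset_index(drop=True)
        self.config = config or CganConfig()
        self.feature_names = feature_columns(table)

    def _init_state(self):
        rng = np.random.default_rng(self.config.seed)
        scaler = scaling.fit(self.table, "minmax")
        g_net, g_emb = build_generator(self.config, len(self.feature_names), rng)
        d_net, d_emb = build_discriminator(self.config, len(self.feature_names), rng)
        return rng, scaler, g_net, g_emb, d_net, d_emb

    def untrained_results(self) -> "GANResults":
        """Freshly initialised generator, no training — a fidelity baseline."""
        _, scaler, g_net, g_emb, d_net, d_emb = self._init_state()
        history = pd.DataFrame({"epoch": [], "g_loss": [], "d_loss": []})
        return GANResults(self.config, self.feature_names, scaler, g_net, g_emb, d_net, d_emb, history)

    def fit(self) -> "GANResults":
        cfg = self.config
        rng, scaler, g_net, g_emb, d_net, d_emb = self._init_state()
        x_all = scaling.transform(self.table, scaler)[self.feature_names].to_numpy(dtype=float)
        y_all = self.table[LABEL_COL].map(_LABEL_INDEX).to_numpy()
        n, nf = x_all.shape

        opt_g = nn.Adam(g_net.params() + g_emb.params(), cfg.learning_rate, cfg.beta1, cfg.beta2)
        opt_d = nn.Adam(d_net.params() + d_emb.params(), cfg.learning_rate, cfg.beta1, cfg.beta2)

        g_hist, d_hist = [], []
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            g_losses, d_losses = [], []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                if len(idx) < 2:  # batch norm needs ≥2 rows
                    continue
                xb, yb = x_all[idx], y_all[idx]
                b = len(idx)

                # --- discriminator step: real (smoothed target) + fake (target 0)
                z = rng.normal(size=(b, cfg.noise_dim))
                fake = g_net.forward(np.concatenate([z, g_emb.forward(yb)], axis=1), True)
                d_in = np.concatenate(
                    [
                        np.concatenate([xb, d_emb.forward(yb)], axis=1),
                        np.concatenate([fake, d_emb.forward(yb)], axis=1),
                    ]
                )
                d_emb.forward(np.concatenate([yb, yb]))  # cache indices for backward
                targets = np.concatenate(
                    [np.full((b, 1), cfg.real_label_smoothing), np.zeros((b, 1))]
                )
                logits = d_net.forward(d_in, True)
                d_loss, grad = nn.bce_with_logits(logits, targets)
                gin = d_net.backward(grad)
                d_emb.backward(gin[:, nf:])
                opt_d.step()

                # --- generator step: fool the discriminator (target 1)
                z = rng.normal(size=(b, cfg.noise_dim))
                g_in = np.concatenate([z, g_emb.forward(yb)], axis=1)
                fake = g_net.forward(g_in, True)
                logits = d_net.forward(
                    np.concatenate([fake, d_emb.forward(yb)], axis=1), True
                )
                g_loss, grad = nn.bce_with_logits(logits, np.ones((b, 1)))
                gfake = d_net.backward(grad)[:, :nf]
                gz = g_net.backward(gfake)
                g_emb.backward(gz[:, cfg.noise_dim :])
                opt_g.step()

                d_losses.append(d_loss)
                g_losses.append(g_loss)

            g_epoch, d_epoch = float(np.mean(g_losses)), float(np.mean(d_losses))
            if not (np.isfinite(g_epoch) and np.isfinite(d_epoch)):
                raise DivergenceError(f"non-finite adversarial loss at epoch {epoch}")
            g_hist.append(g_epoch)
            d_hist.append(d_epoch)

        history = pd.DataFrame(
            {"epoch": np.arange(cfg.epochs), "g_loss": g_hist, "d_loss": d_hist}
        )
        return GANResults(cfg, self.feature_names, scaler, g_net, g_emb, d_net, d_emb, history)


class GANResults:
    """Trained (or baseline) generator/discriminator with sampling."""

    def __init__(self, config, feature_names, scaler, g_net, g_emb, d_net, d_emb, history):
        self.config = config
        self.feature_names = list(feature_names)
        self.scaler = scaler
        self.generator = g_net
        self.generator_embedding = g_emb
        self.discriminator = d_net
        self.discriminator_embedding = d_emb
        self.loss_history = history
        self.label_vocabulary = LABELS

    def sample(self, label: str, n: int, seed: int = 0) -> pd.DataFrame:
        """Generate ``n`` rows of the given class in original descriptor units.

        Deterministic given ``seed``; ids carry the synthetic prefix so the
        leakage guard can recognise generated rows anywhere downstream.
        """
        if label not in _LABEL_INDEX:
            raise ValidationError(f"unknown class label {label!r}")
        rng = np.random.default_rng(seed)
        cfg = self.config
        idx = np.full(n, _LABEL_INDEX[label])
        if n == 0:
            scaled = np.empty((0, len(self.feature_names)))
        else:
            z = rng.normal(size=(n, cfg.noise_dim))
            g_in = np.concatenate([z, self.generator_embedding.forward(idx)], axis=1)
            scaled = self.generator.forward(g_in, training=False)
        out = pd.DataFrame(scaled, columns=self.feature_names)
        out = scaling.inverse_transform(out, self.scaler)
        out.insert(0, ID_COL, [f"{SYNTHETIC_PREFIX}{label}-{seed}-{i:04d}" for i in range(n)])
        out[LABEL_COL] = label
        return out

    def sample_balanced(self, n_per_class: int, seed: int = 0) -> pd.DataFrame:
        """Evenly split synthetic table (the augmentation default: 50 + 50)."""
        parts = [self.sample(label, n_per_class, seed + i) for i, label in enumerate(LABELS)]
        return pd.concat(parts, ignore_index=True)

    def discriminate(self, table: pd.DataFrame) -> np.ndarray:
        """Real/fake probability for labelled rows in original units."""
        x = scaling.transform(table, self.scaler)[self.feature_names].to_numpy(dtype=float)
        idx = table[LABEL_COL].map(_LABEL_INDEX).to_numpy()
        d_in = np.concatenate([x, self.discriminator_embedding.forward(idx)], axis=1)
        return nn.sigmoid(self.discriminator.forward(d_in, training=False)).ravel()

    def summary(self) -> str:
        h = self.loss_history
        lines = [
            "Conditional GAN results",
            f"  features: {len(self.feature_names)}",
            f"  epochs trained: {len(h)}",
        ]
        if len(h):
            lines.append(f"  final losses: G {h.g_loss.iloc[-1]:.4f}, D {h.d_loss.iloc[-1]:.4f}")
        return "\n".join(lines)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "GANResults":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, cls):
            raise ValidationError(f"{path} is not a saved GANResults archive")
        return obj
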