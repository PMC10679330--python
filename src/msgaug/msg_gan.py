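"""Multi-scale-gradients GAN with a relativistic average hinge loss.

The generator emits an RGB image at every intermediate resolution (4x4,
8x8, ..., 2**(depth+1)); the discriminator consumes the whole pyramid, so
its gradients reach every generator scale simultaneously — the mechanism
that stabilises adversarial training when real and fake distributions have
little overlap.  One model is trained per image class.

Losses (relativistic average hinge, R(x) = max(x, 0)):

    rf = D(x_real) - E[D(x_fake)]        fr = D(x_fake) - E[D(x_real)]
    l_dis = E[R(1 - rf)] + E[R(1 + fr)]
    l_gen = E[R(1 + rf)] + E[R(1 - fr)]

Training follows the two-time-scale update rule: the discriminator's Adam
learning rate is 4x the generator's by default (1e-4 / 4e-4), alternating
one discriminator step (with freshly generated fakes) and one generator
step per batch.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .data import LabeledImageSet

__all__ = [
    "GanConfig",
    "RelativisticScores",
    "MsgGenerator",
    "MsgDiscriminator",
    "MsgGan",
    "real_pyramid",
    "discriminator_loss",
    "generator_loss",
    "train_gan",
    "sample_images",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1


@dataclasses.dataclass(frozen=True)
class GanConfig:
    """Hyperparameters of one per-class GAN.

    ``depth`` blocks give a top resolution of ``2**(depth+1)``; the
    reference configuration for 256x256 patches is depth 7 with a 256-dim
    latent.  Desk-scale runs use depth 3-4 (16-32 px).
    """

    latent_dim: int = 256
    depth: int = 4
    base_channels: int = 32
    lr_generator: float = 1e-4
    lr_discriminator: float = 4e-4
    batch_size: int = 8
    epochs: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.lr_generator <= 0 or self.lr_discriminator <= 0:
            raise ValueError("learning rates must be positive")
        if self.latent_dim < 1 or self.base_channels < 1:
            raise ValueError("latent_dim and base_channels must be positive")

    @property
    def top_resolution(self) -> int:
        return 2 ** (self.depth + 1)

    def channels(self, level: int) -> int:
        """Feature width at pyramid level (level 0 = 4x4); halved per doubling, floor 16."""
        return max(self.base_channels >> level, 16)


# ---------------------------------------------------------------------------
# Relativistic hinge loss
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RelativisticScores:
    """Discriminator outputs on real/fake batches and the derived rf/fr."""

    scores_real: np.ndarray
    scores_fake: np.ndarray
    rf: np.ndarray = dataclasses.field(init=False)
    fr: np.ndarray = dataclasses.field(init=False)

    def __post_init__(self):
        self.scores_real = np.asarray(self.scores_real, dtype=np.float64).ravel()
        self.scores_fake = np.asarray(self.scores_fake, dtype=np.float64).ravel()
        if self.scores_real.size == 0 or self.scores_fake.size == 0:
            raise ValueError("need at least one real and one fake score")
        self.rf = self.scores_real - self.scores_fake.mean()
        self.fr = self.scores_fake - self.scores_real.mean()


def _hinge_terms(sr: nn.Tensor, sf: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
    rf = sr - sf.mean()
    fr = sf - sr.mean()
    return rf, fr


def _dis_loss_t(sr: nn.Tensor, sf: nn.Tensor) -> nn.Tensor:
    rf, fr = _hinge_terms(sr, sf)
    return (1.0 - rf).relu().mean() + (1.0 + fr).relu().mean()


def _gen_loss_t(sr: nn.Tensor, sf: nn.Tensor) -> nn.Tensor:
    rf, fr = _hinge_terms(sr, sf)
    return (1.0 + rf).relu().mean() + (1.0 - fr).relu().mean()


def discriminator_loss(s: RelativisticScores) -> float:
    """l_dis = E[max(1 - rf, 0)] + E[max(1 + fr, 0)]; zero iff every
    rf >= 1 and every fr <= -1 (real/fake separated by a full margin)."""
    return float(np.maximum(1.0 - s.rf, 0.0).mean()
                 + np.maximum(1.0 + s.fr, 0.0).mean())


def generator_loss(s: RelativisticScores) -> float:
    """l_gen = E[max(1 + rf, 0)] + E[max(1 - fr, 0)]."""
    return float(np.maximum(1.0 + s.rf, 0.0).mean()
                 + np.maximum(1.0 - s.fr, 0.0).mean())


# ---------------------------------------------------------------------------
# Image pyramids
# ---------------------------------------------------------------------------

def real_pyramid(images: np.ndarray, depth: int) -> list[np.ndarray]:
    """Multi-resolution pyramid of a real batch (NHWC in, NCHW levels out).

    The top level is the batch unchanged; each lower level halves the
    resolution by 2x2 average pooling, down to 4x4.
    """
    images = np.asarray(images, dtype=np.float32)
    if images.ndim != 4 or images.shape[-1] != 3:
        raise ValueError(f"expected (N, H, W, 3) batch, got {images.shape}")
    res = images.shape[1]
    if res != 2 ** (depth + 1):
        raise ValueError(
            f"resolution {res} does not match depth {depth} (need {2 ** (depth + 1)})")
    level = images.transpose(0, 3, 1, 2)  # NCHW
    levels = [level]
    for _ in range(depth - 1):
        n, c, h, w = level.shape
        level = level.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))
        levels.append(level)
    return levels[::-1]  # level 0 = 4x4


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

class _GenBlock(nn.Module):
    def __init__(self, c_in: int, c_out: int, rng, first: bool, latent_dim: int = 0):
        super().__init__()
        self.first = first
        if first:
            # learned projection of the latent onto a 4x4 feature grid
            self.proj = nn.Linear(latent_dim, c_out * 16, rng)
        else:
            self.up = nn.UpsampleNearest2x()
        self.conv1 = nn.Conv2d(c_in, c_out, 3, rng)
        self.conv2 = nn.Conv2d(c_out, c_out, 3, rng)
        self.act = nn.LeakyReLU(0.2)
        self.c_out = c_out

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        if self.first:
            x = self.act(self.proj(x)).reshape(x.shape[0], self.c_out, 4, 4)
        else:
            x = self.up(x)
        x = self.act(self.conv1(x))
        return self.act(self.conv2(x))


class MsgGenerator(nn.Module):
    """Latent vector -> pyramid of RGB images, one per block (1x1-conv heads)."""

    def __init__(self, config: GanConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        chans = [config.channels(i) for i in range(config.depth)]
        for i in range(config.depth):
            c_in = chans[i] if i == 0 else chans[i - 1]
            setattr(self, f"block{i}",
                    _GenBlock(c_in, chans[i], rng, first=(i == 0),
                              latent_dim=config.latent_dim))
            setattr(self, f"to_rgb{i}", nn.Conv2d(chans[i], 3, 1, rng))
        self.tanh = nn.Tanh()

    def forward(self, z: nn.Tensor) -> list[nn.Tensor]:
        if z.ndim != 2 or z.shape[1] != self.config.latent_dim:
            raise ValueError(
                f"latent batch must be (N, {self.config.latent_dim}), got {z.shape}")
        pyramid, x = [], z
        for i in range(self.config.depth):
            x = getattr(self, f"block{i}")(x)
            pyramid.append(self.tanh(getattr(self, f"to_rgb{i}")(x)))
        return pyramid


class MsgDiscriminator(nn.Module):
    """Pyramid of RGB images -> one unbounded real score per sample.

    Processes the pyramid top-down; at each level below the top, the
    incoming RGB image is projected by a 1x1 convolution and concatenated
    channel-wise with the pooled feature map from the previous block, so
    every scale influences the score.
    """

    RGB_FEATURES = 16

    def __init__(self, config: GanConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        d = config.depth
        chans = [config.channels(i) for i in range(d)]  # chans[0] at 4x4
        for i in range(d - 1, -1, -1):
            setattr(self, f"from_rgb{i}",
                    nn.Conv2d(3, self.RGB_FEATURES, 1, rng))
            c_in = self.RGB_FEATURES + (0 if i == d - 1 else chans[i + 1])
            setattr(self, f"conv{i}a", nn.Conv2d(c_in, chans[i], 3, rng))
            setattr(self, f"conv{i}b", nn.Conv2d(chans[i], chans[i], 3, rng))
        self.act = nn.LeakyReLU(0.2)
        self.pool = nn.AvgPool2x()
        self.head = nn.Linear(chans[0] * 16, 1, rng)

    def forward(self, pyramid: list[nn.Tensor]) -> nn.Tensor:
        d = self.config.depth
        if len(pyramid) != d:
            raise ValueError(f"pyramid has {len(pyramid)} levels, expected {d}")
        feat = None
        for i in range(d - 1, -1, -1):
            rgb = self.act(getattr(self, f"from_rgb{i}")(pyramid[i]))
            x = rgb if feat is None else nn.concat([rgb, feat], axis=1)
            x = self.act(getattr(self, f"conv{i}a")(x))
            x = self.act(getattr(self, f"conv{i}b")(x))
            feat = self.pool(x) if i > 0 else x
        scores = self.head(feat.reshape(feat.shape[0], -1))
        return scores.reshape(scores.shape[0])


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class MsgGan:
    """A per-class generator/discriminator pair with its optimizers."""

    def __init__(self, config: GanConfig, class_id: int = 0,
                 class_names: list[str] | None = None):
        self.config = config
        self.class_id = int(class_id)
        if class_names is None:
            class_names = [f"class{k}" for k in range(class_id + 1)]
        if class_id >= len(class_names):
            raise ValueError("class_id out of range for class_names")
        self.class_names = list(class_names)
        self.class_name = self.class_names[class_id]
        ss = np.random.SeedSequence([config.seed, 0x6A4, class_id])
        g_seed, d_seed, self._train_seed = ss.spawn(3)
        self.generator = MsgGenerator(config, np.random.default_rng(g_seed))
        self.discriminator = MsgDiscriminator(config, np.random.default_rng(d_seed))
        betas = (0.0, 0.99)
        self.opt_g = nn.Adam(self.generator.parameters(),
                             config.lr_generator, betas=betas)
        self.opt_d = nn.Adam(self.discriminator.parameters(),
                             config.lr_discriminator, betas=betas)

    # -- sampling -----------------------------------------------------------
    def sample(self, n: int, seed: int, batch_size: int = 64) -> LabeledImageSet:
        if n <= 0:
            raise ValueError(f"n must be positive, got {n}")
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5A9]))
        self.generator.eval()
        chunks = []
        for start in range(0, n, batch_size):
            m = min(batch_size, n - start)
            z = nn.Tensor(rng.standard_normal((m, self.config.latent_dim)))
            top = self.generator(z)[-1].data  # highest resolution only
            chunks.append(np.clip(top.transpose(0, 2, 3, 1), -1.0, 1.0))
        self.generator.train()
        images = np.concatenate(chunks)
        labels = np.full(n, self.class_id)
        return LabeledImageSet(images, labels, self.class_names)

    # -- one training step --------------------------------------------------
    def _step(self, real_levels: list[np.ndarray],
              rng: np.random.Generator) -> tuple[float, float]:
        cfg = self.config
        real_t = [nn.Tensor(lv) for lv in real_levels]
        n = real_levels[0].shape[0]

        # discriminator update on a fresh fake batch (generator detached)
        z = nn.Tensor(rng.standard_normal((n, cfg.latent_dim)))
        fake_detached = [nn.Tensor(lv.data) for lv in self.generator(z)]
        sr = self.discriminator(real_t)
        sf = self.discriminator(fake_detached)
        d_loss = _dis_loss_t(sr, sf)
        self.opt_d.zero_grad()
        d_loss.backward()
        self.opt_d.step()

        # generator update on another fresh fake batch
        z = nn.Tensor(rng.standard_normal((n, cfg.latent_dim)))
        fake = self.generator(z)
        sr = self.discriminator([nn.Tensor(lv) for lv in real_levels])
        sf = self.discriminator(fake)
        g_loss = _gen_loss_t(sr, sf)
        self.opt_g.zero_grad()
        self.opt_d.zero_grad()
        g_loss.backward()
        self.opt_g.step()
        self.opt_d.zero_grad()
        return float(d_loss.item()), float(g_loss.item())

    def fit(self, class_images: LabeledImageSet) -> pd.DataFrame:
        """Alternating adversarial training on a single-class image set."""
        cfg = self.config
        if len(np.unique(class_images.labels)) > 1:
            raise ValueError("train_gan expects images of a single class")
        if class_images.resolution != cfg.top_resolution:
            raise ValueError(
                f"images are {class_images.resolution}px but depth {cfg.depth} "
                f"expects {cfg.top_resolution}px")
        if len(class_images) < cfg.batch_size:
            raise ValueError("fewer images than one batch")
        rng = np.random.default_rng(self._train_seed)
        levels_full = real_pyramid(class_images.images, cfg.depth)
        rows = []
        step = 0
        n_batches = len(class_images) // cfg.batch_size
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(class_images))
            for b in range(n_batches):  # final partial batch dropped
                idx = order[b * cfg.batch_size:(b + 1) * cfg.batch_size]
                batch_levels = [lv[idx] for lv in levels_full]
                d_loss, g_loss = self._step(batch_levels, rng)
                if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch} step {step}: "
                        f"d={d_loss}, g={g_loss}")
                rows.append((step, epoch, d_loss, g_loss))
                step += 1
        return pd.DataFrame(rows, columns=["step", "epoch", "d_loss", "g_loss"])


def train_gan(class_images: LabeledImageSet, config: GanConfig,
              class_id: int | None = None) -> tuple[MsgGan, pd.DataFrame]:
    """Train one GAN on one class; returns the model and its loss log."""
    if class_id is None:
        if len(class_images) == 0:
            raise ValueError("empty training set")
        class_id = int(class_images.labels[0])
    gan = MsgGan(config, class_id=class_id,
                 class_names=class_images.class_names)
    log = gan.fit(class_images)
    return gan, log


def sample_images(gan: MsgGan, n: int, seed: int) -> LabeledImageSet:
    """Draw ``n`` images at the top resolution from a trained generator."""
    return gan.sample(n, seed)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(gan: MsgGan, path: str | Path) -> None:
    header = {
        "version": CHECKPOINT_VERSION,
        "kind": "msg_gan",
        "config": dataclasses.asdict(gan.config),
        "class_id": gan.class_id,
        "class_names": gan.class_names,
    }
    arrays = {}
    arrays.update({"G." + k: v for k, v in gan.generator.state_arrays().items()})
    arrays.update({"D." + k: v for k, v in gan.discriminator.state_arrays().items()})
    arrays.update({"optG." + k: v for k, v in gan.opt_g.state_arrays().items()})
    arrays.update({"optD." + k: v for k, v in gan.opt_d.state_arrays().items()})
    np.savez(path, __header__=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> MsgGan:
    with np.load(path) as npz:
        header = json.loads(bytes(npz["__header__"]).decode())
        if header.get("kind") != "msg_gan":
            raise ValueError(f"{path} is not a GAN checkpoint")
        if header["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {header['version']}")
        arrays = {k: npz[k] for k in npz.files if k != "__header__"}
    config = GanConfig(**header["config"])
    gan = MsgGan(config, class_id=header["class_id"],
                 class_names=header["class_names"])
    gan.generator.load_state_arrays(
        {k[2:]: v for k, v in arrays.items() if k.startswith("G.")})
    gan.discriminator.load_state_arrays(
        {k[2:]: v for k, v in arrays.items() if k.startswith("D.")})
    gan.opt_g.load_state_arrays(
        {k[5:]: v for k, v in arrays.items() if k.startswith("optG.")})
    gan.opt_d.load_state_arrays(
        {k[5:]: v for k, v in arrays.items() if k.startswith("optD.")})
    return gan
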