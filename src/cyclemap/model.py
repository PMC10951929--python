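"""The VAE-GAN that learns the cell-cycle manifold.

Three networks share one latent space:

* an **encoder** mapping a single-channel nucleus patch to a diagonal-Gaussian
  posterior ``N(mu, diag(exp(logvar)))`` in a 16-dimensional latent space
  (three stride-2 convolutions with batch normalisation, then dense layers);
* a **generator/decoder** mirroring the encoder with three transposed
  convolutions and a final sigmoid so reconstructions live in [0, 1];
* a **discriminator** with five convolutional layers whose feature maps after
  the fourth layer define a *learned similarity metric*: reconstructions are
  penalised in discriminator-feature space as well as pixel space, which is
  what gives VAE-GAN reconstructions their sharpness.

All forward passes run on the package's NumPy autodiff core, so a trained
model is a plain ``.npz`` of arrays plus a JSON sidecar of hyperparameters
and reloads with bit-identical behaviour.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._autodiff import Tensor
from ._nn import (BatchNorm2d, Conv2d, ConvTranspose2d, Dense, Flatten,
                  LeakyReLU, Module, Reshape, Sequential)

__all__ = [
    "EncoderOutput", "DiscriminatorOutput", "ManifoldModel",
    "encode", "sample_latent", "decode", "discriminate",
    "kl_divergence", "reconstruction_loss", "adversarial_losses",
    "gan_losses_from_scores",
]

_EPS = 1e-7


@dataclass
class EncoderOutput:
    """Per-image Gaussian posterior: mean and log of the diagonal variance."""

    mu: np.ndarray
    logvar: np.ndarray

    def __post_init__(self):
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=np.float64))
        self.logvar = np.atleast_2d(np.asarray(self.logvar, dtype=np.float64))
        if self.mu.shape != self.logvar.shape:
            raise ValueError("mu and logvar must have matching shapes")
        if not (np.isfinite(self.mu).all() and np.isfinite(self.logvar).all()):
            raise ValueError("non-finite posterior parameters")

    @property
    def latent_dim(self) -> int:
        return self.mu.shape[1]


@dataclass
class DiscriminatorOutput:
    """Realness probability and the layer-4 feature maps."""

    realness: np.ndarray
    features: np.ndarray


class Encoder(Module):
    def __init__(self, patch_size, latent_dim, channels, dense, rng, dtype):
        super().__init__()
        self.latent_dim = latent_dim
        c1, c2, c3 = channels
        s = patch_size // 8
        self.body = Sequential(
            Conv2d(1, c1, rng=rng, dtype=dtype), BatchNorm2d(c1, dtype=dtype),
            LeakyReLU(),
            Conv2d(c1, c2, rng=rng, dtype=dtype), BatchNorm2d(c2, dtype=dtype),
            LeakyReLU(),
            Conv2d(c2, c3, rng=rng, dtype=dtype), BatchNorm2d(c3, dtype=dtype),
            LeakyReLU(),
            Flatten(),
            Dense(c3 * s * s, dense, rng=rng, dtype=dtype), LeakyReLU(),
            Dense(dense, 2 * latent_dim, rng=rng, dtype=dtype),
        )

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h = self.body(x)
        return h[:, : self.latent_dim], h[:, self.latent_dim:]


class Generator(Module):
    def __init__(self, patch_size, latent_dim, channels, dense, rng, dtype):
        super().__init__()
        c1, c2, c3 = channels
        s = patch_size // 8
        self.body = Sequential(
            Dense(latent_dim, dense, rng=rng, dtype=dtype), LeakyReLU(),
            Dense(dense, c3 * s * s, rng=rng, dtype=dtype), LeakyReLU(),
            Reshape(c3, s, s),
            ConvTranspose2d(c3, c2, rng=rng, dtype=dtype),
            BatchNorm2d(c2, dtype=dtype), LeakyReLU(),
            ConvTranspose2d(c2, c1, rng=rng, dtype=dtype),
            BatchNorm2d(c1, dtype=dtype), LeakyReLU(),
            ConvTranspose2d(c1, 1, rng=rng, dtype=dtype),
        )

    def forward(self, z: Tensor) -> Tensor:
        return self.body(z).sigmoid()


class Discriminator(Module):
    """Five conv layers; features are tapped after the fourth."""

    def __init__(self, patch_size, channels, rng, dtype):
        super().__init__()
        c1, c2, c3, c4 = channels
        self.front = Sequential(
            Conv2d(1, c1, rng=rng, dtype=dtype), LeakyReLU(),
            Conv2d(c1, c2, rng=rng, dtype=dtype), BatchNorm2d(c2, dtype=dtype),
            LeakyReLU(),
            Conv2d(c2, c3, rng=rng, dtype=dtype), BatchNorm2d(c3, dtype=dtype),
            LeakyReLU(),
            Conv2d(c3, c4, rng=rng, dtype=dtype), BatchNorm2d(c4, dtype=dtype),
            LeakyReLU(),
        )
        k = patch_size // 16  # remaining spatial extent after four stride-2 convs
        self.head = Conv2d(c4, 1, kernel=k, stride=1, padding=0, rng=rng,
                           dtype=dtype)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        feats = self.front(x)
        logit = self.head(feats).reshape(x.shape[0])
        return logit, feats


@dataclass
class ManifoldModel:
    """Trained parameter set for the cell-cycle manifold."""

    patch_size: int = 64
    latent_dim: int = 16
    enc_channels: tuple = (32, 64, 128)
    disc_channels: tuple = (32, 64, 128, 256)
    dense: int = 256
    seed: int = 0
    dtype: str = "float32"
    stage_reached: int = 0
    encoder: Encoder = field(init=False, repr=False)
    generator: Generator = field(init=False, repr=False)
    discriminator: Discriminator = field(init=False, repr=False)

    def __post_init__(self):
        if self.patch_size % 16 or self.patch_size < 16:
            raise ValueError("patch_size must be a positive multiple of 16")
        dt = np.dtype(self.dtype).type
        rng = np.random.default_rng(self.seed)
        self.encoder = Encoder(self.patch_size, self.latent_dim,
                               self.enc_channels, self.dense, rng, dt)
        self.generator = Generator(self.patch_size, self.latent_dim,
                                   self.enc_channels, self.dense, rng, dt)
        self.discriminator = Discriminator(self.patch_size, self.disc_channels,
                                           rng, dt)

    # ------------------------------------------------------------------ io
    def eval(self) -> "ManifoldModel":
        for net in (self.encoder, self.generator, self.discriminator):
            net.eval()
        return self

    def _as_batch(self, images: np.ndarray) -> Tensor:
        x = np.asarray(images, dtype=self.dtype)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:
            x = x[:, None]
        if x.ndim != 4 or x.shape[2] != self.patch_size or x.shape[3] != self.patch_size:
            raise ValueError(
                f"expected {self.patch_size}x{self.patch_size} patches, got "
                f"{images.shape}")
        return Tensor(x)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        state = {}
        for name, net in (("encoder", self.encoder), ("generator", self.generator),
                          ("discriminator", self.discriminator)):
            state.update(net.named_state(name + "."))
        np.savez(path.with_suffix(".npz"), **state)
        meta = {k: getattr(self, k) for k in
                ("patch_size", "latent_dim", "dense", "seed", "dtype",
                 "stage_reached")}
        meta["enc_channels"] = list(self.enc_channels)
        meta["disc_channels"] = list(self.disc_channels)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ManifoldModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        meta["enc_channels"] = tuple(meta["enc_channels"])
        meta["disc_channels"] = tuple(meta["disc_channels"])
        model = cls(**meta)
        with np.load(path.with_suffix(".npz")) as state:
            arrays = dict(state)
        model.encoder.load_state(arrays, "encoder.")
        model.generator.load_state(arrays, "generator.")
        model.discriminator.load_state(arrays, "discriminator.")
        return model


# ------------------------------------------------------------- functional API

def encode(model: ManifoldModel, images: np.ndarray) -> EncoderOutput:
    """Posterior parameters for one patch or a batch (deterministic)."""
    single = np.asarray(images).ndim == 2
    model.encoder.eval()
    mu, logvar = model.encoder(model._as_batch(images))
    out = EncoderOutput(mu.data, logvar.data)
    if single:
        return EncoderOutput(out.mu[0], out.logvar[0])
    return out


def sample_latent(post: EncoderOutput, rng: np.random.Generator) -> np.ndarray:
    """Reparameterised draw ``z = mu + exp(logvar / 2) * eps``."""
    eps = rng.standard_normal(post.mu.shape)
    z = post.mu + np.exp(post.logvar / 2.0) * eps
    return z[0] if z.shape[0] == 1 else z


def decode(model: ManifoldModel, z: np.ndarray) -> np.ndarray:
    """Generate patches from latent vectors; output pixels lie in [0, 1]."""
    z = np.asarray(z, dtype=model.dtype)
    single = z.ndim == 1
    z = np.atleast_2d(z)
    if z.shape[1] != model.latent_dim:
        raise ValueError(f"latent vectors must have length {model.latent_dim}")
    model.generator.eval()
    out = model.generator(Tensor(z)).data[:, 0]
    return out[0] if single else out


def discriminate(model: ManifoldModel, images: np.ndarray) -> DiscriminatorOutput:
    single = np.asarray(images).ndim == 2
    model.discriminator.eval()
    logit, feats = model.discriminator(model._as_batch(images))
    real = 1.0 / (1.0 + np.exp(-logit.data))
    if single:
        return DiscriminatorOutput(float(real[0]), feats.data[0])
    return DiscriminatorOutput(real, feats.data)


def kl_divergence(post: EncoderOutput) -> float:
    """Closed-form KL(q || N(0, I)) for a diagonal-Gaussian posterior.

    ``0.5 * sum_d(mu_d^2 + exp(logvar_d) - logvar_d - 1)``, averaged over the
    batch when ``post`` holds several posteriors.
    """
    per_item = 0.5 * np.sum(
        post.mu**2 + np.exp(post.logvar) - post.logvar - 1.0, axis=1)
    return float(np.mean(per_item))


def reconstruction_loss(x: np.ndarray, x_rec: np.ndarray,
                        model: ManifoldModel | None = None,
                        lambda_feat: float = 1.0) -> float:
    """Pixel MSE plus the learned-similarity (discriminator-feature) MSE.

    With ``model=None`` or ``lambda_feat=0`` this is plain pixel MSE.
    """
    x = np.asarray(x, dtype=np.float64)
    x_rec = np.asarray(x_rec, dtype=np.float64)
    if x.shape != x_rec.shape:
        raise ValueError("input and reconstruction shapes differ")
    loss = float(np.mean((x - x_rec) ** 2))
    if model is not None and lambda_feat > 0:
        fa = discriminate(model, x).features
        fb = discriminate(model, x_rec).features
        loss += lambda_feat * float(np.mean((fa - fb) ** 2))
    return loss


def gan_losses_from_scores(d_real: np.ndarray, d_fake: np.ndarray
                           ) -> tuple[float, float]:
    """Non-saturating GAN losses from realness probabilities.

    ``disc = -mean[log D(real) + log(1 - D(fake))]``;
    ``gen = -mean[log D(fake)]``.
    """
    d_real = np.clip(np.asarray(d_real, dtype=np.float64), _EPS, 1 - _EPS)
    d_fake = np.clip(np.asarray(d_fake, dtype=np.float64), _EPS, 1 - _EPS)
    disc = -float(np.mean(np.log(d_real) + np.log(1.0 - d_fake)))
    gen = -float(np.mean(np.log(d_fake)))
    return disc, gen


def adversarial_losses(model: ManifoldModel, real: np.ndarray,
                       fake: np.ndarray) -> tuple[float, float]:
    """Discriminator and generator losses for batches of real/fake patches."""
    d_real = discriminate(model, real).realness
    d_fake = discriminate(model, fake).realness
    return gan_losses_from_scores(d_real, d_fake)
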