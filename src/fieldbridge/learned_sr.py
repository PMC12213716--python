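"""Learned super-resolution models: ESPCN, SRGAN and TCGAN.

Desk-scale 2-D implementations of the three architectures, trainable on the
synthetic cohort with the package's numpy network engine:

* **ESPCN** — convolutions in low-resolution space, a sub-pixel (pixel
  shuffle) head, mean-squared-error training.
* **SRGAN** — residual-block generator with pixel-shuffle upsampling and
  leaky-ReLU/batch-norm conv discriminator, trained adversarially with
  pixel and perceptual terms.
* **TCGAN** — a transformer generator (patch embedding + self-attention
  blocks) arranged **in series** with a CNN U-Net generator, judged by a
  patch-level discriminator that scores overlapping image patches; trained
  with a weighted sum of adversarial, L1 pixel and perceptual feature losses.

All three are exposed as sklearn-style estimators (``fit(X_low, y_high)`` /
``transform(X_low)``).  Scale 1 is supported throughout: low- and high-field
grids match and the models act as same-grid restorers, which is how the
1.5T→3T harmonization setting mostly behaves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

from .features import FeatureBackbone, default_backbone, feature_distance
from .nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    LeakyReLU,
    Module,
    PixelShuffle,
    Sequential,
    Tanh,
    Tensor,
    TransformerBlock,
)
from .nn.layers import Linear
from .types import FIELD_HIGH, SliceStack

DEFAULT_LOSS_WEIGHTS = {"adversarial": 1e-3, "pixel": 1.0, "perceptual": 6e-3}


# ---------------------------------------------------------------------------
# plain-numpy pixel shuffle (the spec-level primitive, also used in tests)
# ---------------------------------------------------------------------------

def pixel_shuffle(features: np.ndarray, r: int) -> np.ndarray:
    """Rearrange (C·r², H, W) feature maps into (C, rH, rW) images.

    Channel ``c·r² + i·r + j`` of cell (h, w) lands at output pixel
    (h·r + i, w·r + j).  Bijective; ``r=1`` is the identity.
    """
    if int(r) != r or r < 1:
        raise ValueError("r must be a positive integer")
    r = int(r)
    features = np.asarray(features)
    squeeze = features.ndim == 3
    if squeeze:
        features = features[None]
    n, cr2, h, w = features.shape
    if cr2 % (r * r) != 0:
        raise ValueError(f"channel count {cr2} not divisible by r^2={r*r}")
    c = cr2 // (r * r)
    out = (
        features.reshape(n, c, r, r, h, w)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(n, c, h * r, w * r)
    )
    return out[0] if squeeze else out


def pixel_unshuffle(images: np.ndarray, r: int) -> np.ndarray:
    """Inverse rearrangement of :func:`pixel_shuffle`."""
    if int(r) != r or r < 1:
        raise ValueError("r must be a positive integer")
    r = int(r)
    images = np.asarray(images)
    squeeze = images.ndim == 3
    if squeeze:
        images = images[None]
    n, c, hr, wr = images.shape
    if hr % r or wr % r:
        raise ValueError("spatial dims not divisible by r")
    h, w = hr // r, wr // r
    out = (
        images.reshape(n, c, h, r, w, r)
        .transpose(0, 1, 3, 5, 2, 4)
        .reshape(n, c * r * r, h, w)
    )
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# network definitions
# ---------------------------------------------------------------------------

class ESPCNNet(Module):
    """Conv stack in LR space + sub-pixel upsampling head."""

    def __init__(self, scale: int, channels: int, rng: np.random.Generator):
        self.scale = scale
        self.body = Sequential(
            Conv2d(1, channels, 5, rng),
            Tanh(),
            Conv2d(channels, max(channels // 2, 4), 3, rng),
            Tanh(),
            Conv2d(max(channels // 2, 4), scale * scale, 3, rng),
            PixelShuffle(scale),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.body(x)


class _ResidualBlock(Module):
    def __init__(self, c: int, rng: np.random.Generator):
        self.conv1 = Conv2d(c, c, 3, rng)
        self.bn1 = BatchNorm2d(c)
        self.act = LeakyReLU(0.2)
        self.conv2 = Conv2d(c, c, 3, rng)
        self.bn2 = BatchNorm2d(c)

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn2(self.conv2(self.act(self.bn1(self.conv1(x)))))
        return x + y


class SRResNetGenerator(Module):
    """Residual-block generator with pixel-shuffle upsampling."""

    def __init__(self, scale: int, channels: int, n_blocks: int,
                 rng: np.random.Generator):
        if scale not in (1, 2, 4):
            raise ValueError("scale must be 1, 2 or 4")
        self.head = Conv2d(1, channels, 3, rng)
        self.act = LeakyReLU(0.2)
        self.blocks = [_ResidualBlock(channels, rng) for _ in range(n_blocks)]
        self.post = Conv2d(channels, channels, 3, rng)
        ups: List[Module] = []
        s = scale
        while s > 1:
            ups += [Conv2d(channels, channels * 4, 3, rng), PixelShuffle(2),
                    LeakyReLU(0.2)]
            s //= 2
        self.upsample = Sequential(*ups)
        self.tail = Conv2d(channels, 1, 3, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.act(self.head(x))
        y = h
        for b in self.blocks:
            y = b(y)
        y = h + self.post(y)
        y = self.upsample(y)
        return self.tail(y)


class ConvDiscriminator(Module):
    """Global (scalar-logit) discriminator for SRGAN."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.features = Sequential(
            Conv2d(1, channels, 3, rng, stride=1),
            LeakyReLU(0.2),
            Conv2d(channels, channels, 3, rng, stride=2),
            BatchNorm2d(channels),
            LeakyReLU(0.2),
            Conv2d(channels, 2 * channels, 3, rng, stride=2),
            BatchNorm2d(2 * channels),
            LeakyReLU(0.2),
        )
        self.head = Linear(2 * channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        f = self.features(x)
        pooled = f.mean(axis=(2, 3))  # (N, C)
        return self.head(pooled)  # (N, 1) logits


def _sinusoidal_positions(t: int, d: int) -> np.ndarray:
    pos = np.arange(t)[:, None]
    i = np.arange(d // 2)[None, :]
    ang = pos / (10000 ** (2 * i / d))
    emb = np.zeros((t, d))
    emb[:, 0::2] = np.sin(ang)
    emb[:, 1::2] = np.cos(ang)
    return emb


class TransformerGenerator(Module):
    """Patch-embedding + self-attention generator operating on the target
    grid; predicts a residual added to its input."""

    def __init__(self, patch_size: int, depth: int, heads: int, d_model: int,
                 rng: np.random.Generator):
        self.p = patch_size
        self.embed = Linear(patch_size * patch_size, d_model, rng)
        self.blocks = [TransformerBlock(d_model, heads, rng) for _ in range(depth)]
        self.unembed = Linear(d_model, patch_size * patch_size, rng)
        self.res_scale = Tensor(np.array(0.1), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        p = self.p
        if h % p or w % p:
            raise ValueError(f"image size must be divisible by patch size {p}")
        gh, gw = h // p, w // p
        tok = x.reshape(n, gh, p, gw, p).transpose(0, 1, 3, 2, 4)
        tok = tok.reshape(n, gh * gw, p * p)
        z = self.embed(tok) + Tensor(_sinusoidal_positions(gh * gw, self.embed.weight.shape[1]))
        for b in self.blocks:
            z = b(z)
        out = self.unembed(z)  # (N, T, p*p)
        out = out.reshape(n, gh, gw, p, p).transpose(0, 1, 3, 2, 4)
        out = out.reshape(n, 1, h, w)
        return x + out * self.res_scale


class UNetGenerator(Module):
    """Two-level U-Net refiner with a global residual connection."""

    def __init__(self, channels: int, rng: np.random.Generator):
        act = LeakyReLU(0.2)
        self.enc1 = Sequential(Conv2d(1, channels, 3, rng), act,
                               Conv2d(channels, channels, 3, rng), act)
        self.enc2 = Sequential(Conv2d(channels, 2 * channels, 3, rng), act,
                               Conv2d(2 * channels, 2 * channels, 3, rng), act)
        self.up = Conv2d(2 * channels, channels, 3, rng)
        self.dec = Sequential(Conv2d(2 * channels, channels, 3, rng), act,
                              Conv2d(channels, channels, 3, rng), act)
        self.tail = Conv2d(channels, 1, 3, rng)

    def forward(self, x: Tensor) -> Tensor:
        e1 = self.enc1(x)
        e2 = self.enc2(e1.avg_pool2())
        u = self.up(e2.upsample_nearest2())
        d = self.dec(u.concat(e1, axis=1))
        return x + self.tail(d)


class TCGANGenerator(Module):
    """Transformer generator and CNN U-Net generator in series.

    At scale > 1 the input is first brought onto the target grid by
    nearest-neighbor sub-pixel duplication (a fixed pixel-shuffle of repeated
    channels), then refined globally by the transformer stage and locally by
    the U-Net stage.  ``use_transformer`` exists to ablate the first stage.
    """

    def __init__(self, scale: int, channels: int, patch_size: int, depth: int,
                 heads: int, d_model: int, rng: np.random.Generator,
                 use_transformer: bool = True):
        self.scale = scale
        self.use_transformer = use_transformer
        self.transformer = TransformerGenerator(patch_size, depth, heads, d_model, rng)
        self.unet = UNetGenerator(channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        if self.scale > 1:
            r = self.scale
            n, c, h, w = x.shape
            # duplicate the single channel r^2 times, then shuffle to the HR grid

            def back(g):
                x._accum(g.reshape(x.shape[0], r * r, *x.shape[2:]).sum(axis=1, keepdims=True))

            dup = x._make(np.repeat(x.data, r * r, axis=1), (x,), back)
            x = dup.pixel_shuffle(r)
        if self.use_transformer:
            x = self.transformer(x)
        return self.unet(x)


class PatchDiscriminator(Module):
    """PatchGAN-style discriminator: a grid of patch logits, not a scalar."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.body = Sequential(
            Conv2d(1, channels, 3, rng, stride=2),
            LeakyReLU(0.2),
            Conv2d(channels, 2 * channels, 3, rng, stride=2),
            BatchNorm2d(2 * channels),
            LeakyReLU(0.2),
            Conv2d(2 * channels, 1, 3, rng, stride=1),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.body(x)  # (N, 1, H/4, W/4) logits


# ---------------------------------------------------------------------------
# spec + functional surface
# ---------------------------------------------------------------------------

@dataclass
class SRModelSpec:
    """Configuration for one learned SR architecture."""

    arch: str = "espcn"
    scale: int = 1
    base_channels: int = 32
    n_residual_blocks: int = 4
    transformer: Dict[str, int] = field(
        default_factory=lambda: {"patch_size": 8, "depth": 2, "heads": 2}
    )
    loss_weights: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOSS_WEIGHTS)
    )
    epochs: int = 40
    batch_size: int = 8
    lr: float = 2e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arch not in ("espcn", "srgan", "tcgan"):
            raise ValueError(f"unknown arch {self.arch!r}")
        if int(self.scale) < 1:
            raise ValueError("scale must be >= 1")


def _bce_with_logits(logits: Tensor, target: float) -> Tensor:
    """Numerically stable binary cross-entropy on logits, averaged."""
    sp = logits.relu() - logits * target + ((-(logits.abs())).exp() + 1.0).log()
    return sp.mean()


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _as_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def _validate_pairs(X, y, scale: int) -> Tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 2:
        X, y = X[None], y[None]
    if X.ndim != 3 or y.ndim != 3 or X.shape[0] != y.shape[0] or X.shape[0] == 0:
        raise ValueError("expected matching non-empty stacks of 2-D slices")
    if (y.shape[1], y.shape[2]) != (scale * X.shape[1], scale * X.shape[2]):
        raise ValueError(
            f"high-res shape {y.shape[1:]} is not scale={scale} times "
            f"low-res shape {X.shape[1:]}"
        )
    return X, y


class _LearnedSRBase(BaseEstimator, TransformerMixin):
    """Common fit/transform machinery for the three learned SR estimators."""

    arch: str = ""

    def _spec(self) -> SRModelSpec:
        p = self.get_params()
        return SRModelSpec(
            arch=self.arch,
            scale=p["scale"],
            base_channels=p["base_channels"],
            n_residual_blocks=p.get("n_residual_blocks", 4),
            transformer={
                "patch_size": p.get("patch_size", 8),
                "depth": p.get("depth", 2),
                "heads": p.get("heads", 2),
            },
            loss_weights=p.get("loss_weights") or dict(DEFAULT_LOSS_WEIGHTS),
            epochs=p["epochs"],
            batch_size=p["batch_size"],
            lr=p["lr"],
            seed=p["seed"],
        )

    # subclasses fill these in
    def _build(self, rng: np.random.Generator) -> None:
        raise NotImplementedError

    def _fit_loop(self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> None:
        raise NotImplementedError

    def fit(self, X, y=None):
        if y is None:
            raise ValueError("fit requires paired low/high slices (X, y)")
        spec = self._spec()
        X, y = _validate_pairs(X, y, spec.scale)
        rng = np.random.default_rng(spec.seed)
        self._build(rng)
        self.loss_history_: List[Dict[str, float]] = []
        self._fit_loop(X, y, rng)
        self.n_epochs_ = len(self.loss_history_)
        for rec in self.loss_history_:
            if not all(np.isfinite(v) for v in rec.values()):
                raise FloatingPointError("non-finite loss during training")
        return self

    def _infer(self, batch: np.ndarray) -> np.ndarray:
        self.generator_.eval()
        out = self.generator_(Tensor(batch[:, None, :, :])).data[:, 0]
        return np.clip(out, 0.0, 1.0)

    def save(self, path) -> None:
        """Serialize the fitted model to one ``.npz`` file: generator (and
        discriminator) arrays plus the constructor parameters and seed."""
        if not hasattr(self, "generator_"):
            raise NotFittedError(f"{type(self).__name__} is not fitted")
        import json as _json

        payload = {"__params__": np.frombuffer(
            _json.dumps({"arch": self.arch, **self.get_params(deep=False)},
                        default=str).encode(), dtype=np.uint8)}
        for i, arr in enumerate(self.generator_.state_arrays()):
            payload[f"g{i}"] = arr
        if hasattr(self, "discriminator_"):
            for i, arr in enumerate(self.discriminator_.state_arrays()):
                payload[f"d{i}"] = arr
        np.savez(path, **payload)

    def load(self, path) -> "_LearnedSRBase":
        """Restore fitted parameters written by :meth:`save` into this
        estimator (architectures are rebuilt from the stored seed)."""
        import json as _json

        with np.load(path) as data:
            stored = _json.loads(bytes(data["__params__"]).decode())
            if stored.pop("arch") != self.arch:
                raise ValueError("checkpoint architecture mismatch")
            self._build(np.random.default_rng(self.seed))
            g = [data[k] for k in sorted(
                (k for k in data.files if k.startswith("g")),
                key=lambda k: int(k[1:]))]
            self.generator_.load_arrays(g)
            d_keys = sorted((k for k in data.files if k.startswith("d")),
                            key=lambda k: int(k[1:]))
            if d_keys and hasattr(self, "discriminator_"):
                self.discriminator_.load_arrays([data[k] for k in d_keys])
        self.loss_history_ = getattr(self, "loss_history_", [])
        return self

    def transform(self, X):
        if not hasattr(self, "generator_"):
            raise NotFittedError(f"{type(self).__name__} is not fitted")
        if isinstance(X, SliceStack):
            out = self._infer(X.slices)
            return X.copy_with(
                slices=out, field_strength=FIELD_HIGH, provenance=X
            )
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            return self._infer(X[None])[0]
        return self._infer(X)


class ESPCN(_LearnedSRBase):
    """Efficient sub-pixel CNN, trained by mean squared error."""

    arch = "espcn"

    def __init__(self, scale: int = 1, base_channels: int = 32, epochs: int = 40,
                 batch_size: int = 8, lr: float = 2e-3, seed: int = 0):
        self.scale = scale
        self.base_channels = base_channels
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.seed = seed

    def _build(self, rng):
        self.generator_ = ESPCNNet(self.scale, self.base_channels, rng)

    def _fit_loop(self, X, y, rng):
        opt = Adam(self.generator_.parameters(), lr=self.lr)
        for _ in range(self.epochs):
            self.generator_.train()
            losses = []
            for idx in _as_batches(len(X), self.batch_size, rng):
                xb = Tensor(X[idx][:, None])
                yb = Tensor(y[idx][:, None])
                pred = self.generator_(xb)
                loss = ((pred - yb) ** 2).mean()
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            self.loss_history_.append({"generator_loss": float(np.mean(losses))})


class _GANBase(_LearnedSRBase):
    """Shared adversarial training loop (SRGAN, TCGAN)."""

    def _fit_loop(self, X, y, rng):
        wts = self.loss_weights or dict(DEFAULT_LOSS_WEIGHTS)
        backbone = self.backbone or default_backbone()
        g_opt = Adam(self.generator_.parameters(), lr=self.lr, betas=(0.5, 0.999))
        d_opt = Adam(self.discriminator_.parameters(), lr=self.lr, betas=(0.5, 0.999))
        for _ in range(self.epochs):
            self.generator_.train()
            self.discriminator_.train()
            g_losses, d_losses = [], []
            for idx in _as_batches(len(X), self.batch_size, rng):
                xb = Tensor(X[idx][:, None])
                yb = Tensor(y[idx][:, None])

                # discriminator step
                fake = self.generator_(xb)
                fake_detached = Tensor(fake.data.copy())
                d_loss = 0.5 * (
                    _bce_with_logits(self.discriminator_(yb), 1.0)
                    + _bce_with_logits(self.discriminator_(fake_detached), 0.0)
                )
                d_opt.zero_grad()
                d_loss.backward()
                d_opt.step()

                # generator step
                fake = self.generator_(xb)
                adv = _bce_with_logits(self.discriminator_(fake), 1.0)
                pix = (fake - yb).abs().mean()
                perc = feature_distance(fake, yb, backbone)
                g_loss = (
                    wts["adversarial"] * adv
                    + wts["pixel"] * pix
                    + wts["perceptual"] * perc
                )
                g_opt.zero_grad()
                g_loss.backward()
                g_opt.step()

                g_losses.append(float(g_loss.data))
                d_losses.append(float(d_loss.data))
            self.loss_history_.append(
                {
                    "generator_loss": float(np.mean(g_losses)),
                    "discriminator_loss": float(np.mean(d_losses)),
                }
            )


class SRGAN(_GANBase):
    """Residual-block GAN with adversarial + L1 + perceptual training."""

    arch = "srgan"

    def __init__(self, scale: int = 1, base_channels: int = 32,
                 n_residual_blocks: int = 4, epochs: int = 20,
                 batch_size: int = 8, lr: float = 1e-3, seed: int = 0,
                 loss_weights: Optional[Dict[str, float]] = None,
                 backbone: Optional[FeatureBackbone] = None):
        self.scale = scale
        self.base_channels = base_channels
        self.n_residual_blocks = n_residual_blocks
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.seed = seed
        self.loss_weights = loss_weights
        self.backbone = backbone

    def _build(self, rng):
        self.generator_ = SRResNetGenerator(
            self.scale, self.base_channels, self.n_residual_blocks, rng
        )
        self.discriminator_ = ConvDiscriminator(self.base_channels, rng)


class TCGAN(_GANBase):
    """Transformer + CNN U-Net generators in series with a patch discriminator."""

    arch = "tcgan"

    def __init__(self, scale: int = 1, base_channels: int = 32,
                 patch_size: int = 8, depth: int = 2, heads: int = 2,
                 d_model: int = 32, epochs: int = 20, batch_size: int = 8,
                 lr: float = 1e-3, seed: int = 0,
                 loss_weights: Optional[Dict[str, float]] = None,
                 use_transformer: bool = True,
                 backbone: Optional[FeatureBackbone] = None):
        self.scale = scale
        self.base_channels = base_channels
        self.patch_size = patch_size
        self.depth = depth
        self.heads = heads
        self.d_model = d_model
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.seed = seed
        self.loss_weights = loss_weights
        self.use_transformer = use_transformer
        self.backbone = backbone

    def _build(self, rng):
        self.generator_ = TCGANGenerator(
            self.scale, self.base_channels, self.patch_size, self.depth,
            self.heads, self.d_model, rng, use_transformer=self.use_transformer,
        )
        self.discriminator_ = PatchDiscriminator(self.base_channels, rng)


# ---------------------------------------------------------------------------
# functional wrappers over the estimator surface
# ---------------------------------------------------------------------------

def build_model(spec: SRModelSpec):
    """Instantiate the (unfitted) estimator described by ``spec``."""
    if spec.arch == "espcn":
        return ESPCN(scale=spec.scale, base_channels=spec.base_channels,
                     epochs=spec.epochs, batch_size=spec.batch_size,
                     lr=spec.lr, seed=spec.seed)
    if spec.arch == "srgan":
        return SRGAN(scale=spec.scale, base_channels=spec.base_channels,
                     n_residual_blocks=spec.n_residual_blocks,
                     epochs=spec.epochs, batch_size=spec.batch_size,
                     lr=spec.lr, seed=spec.seed, loss_weights=spec.loss_weights)
    return TCGAN(scale=spec.scale, base_channels=spec.base_channels,
                 patch_size=spec.transformer["patch_size"],
                 depth=spec.transformer["depth"], heads=spec.transformer["heads"],
                 epochs=spec.epochs, batch_size=spec.batch_size, lr=spec.lr,
                 seed=spec.seed, loss_weights=spec.loss_weights)


def train(model: _LearnedSRBase, pairs: Sequence[Tuple[np.ndarray, np.ndarray]],
          epochs: Optional[int] = None) -> Dict[str, float]:
    """Fit ``model`` on (low, high) slice pairs; returns the final loss record."""
    if not pairs:
        raise ValueError("no training pairs")
    X = np.stack([np.asarray(p[0], dtype=float) for p in pairs])
    y = np.stack([np.asarray(p[1], dtype=float) for p in pairs])
    if epochs is not None:
        model.set_params(epochs=epochs)
    model.fit(X, y)
    return model.loss_history_[-1]


def apply_sr(model: _LearnedSRBase, low: SliceStack) -> SliceStack:
    """Per-slice inference on a low-field stack; output tagged high-field and
    clipped to the valid intensity range."""
    return model.transform(low)
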