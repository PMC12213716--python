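"""Fixed-seed convolutional feature extractor.

Serves two roles: the embedding behind the perceptual patch-distance metric,
and the feature space for the perceptual loss term of the GAN generators.
The weights are random but *frozen* (drawn once from a fixed seed), giving a
deterministic, training-free multi-scale texture embedding.  Random shallow
convolutional features are a standard choice when a pretrained backbone is
not wanted; absolute distances in this space are not comparable to published
learned-perceptual-metric values — only orderings are meaningful, and only
orderings are used anywhere in the package.
"""

from __future__ import annotations

from typing import List

import numpy as np

from .nn import Conv2d, LeakyReLU, Module, Sequential, Tensor

DEFAULT_BACKBONE_SEED = 20240917


class FeatureBackbone(Module):
    """Three-stage conv stack tapped after each stage.

    Input: (N, 1, H, W) in [0, 1].  Stages halve resolution via stride-2
    convolutions, widening channels 8 → 16 → 24.
    """

    def __init__(self, seed: int = DEFAULT_BACKBONE_SEED):
        rng = np.random.default_rng(seed)
        self.stage1 = Sequential(Conv2d(1, 8, 3, rng), LeakyReLU(0.2))
        self.stage2 = Sequential(Conv2d(8, 16, 3, rng, stride=2), LeakyReLU(0.2))
        self.stage3 = Sequential(Conv2d(16, 24, 3, rng, stride=2), LeakyReLU(0.2))
        self.eval()
        # Frozen: exclude from parameter discovery so optimizers skip it.
        for p in super().parameters():
            p.requires_grad = False
        self._frozen = True

    def parameters(self):
        return []

    def forward(self, x: Tensor) -> List[Tensor]:
        f1 = self.stage1(x)
        f2 = self.stage2(f1)
        f3 = self.stage3(f2)
        return [f1, f2, f3]


_default_backbone: FeatureBackbone | None = None


def default_backbone() -> FeatureBackbone:
    global _default_backbone
    if _default_backbone is None:
        _default_backbone = FeatureBackbone()
    return _default_backbone


def _unit_normalize(feat: Tensor, eps: float = 1e-10) -> Tensor:
    norm = ((feat**2).sum(axis=1, keepdims=True) + eps) ** 0.5
    return feat / norm


def feature_distance(a: Tensor, b: Tensor, backbone: FeatureBackbone) -> Tensor:
    """Mean squared distance between channel-unit-normalized feature maps,
    averaged over tap layers.  Differentiable; 0 for identical inputs."""
    fa = backbone(a)
    fb = backbone(b)
    total = None
    for xa, xb in zip(fa, fb):
        d = ((_unit_normalize(xa) - _unit_normalize(xb)) ** 2).mean()
        total = d if total is None else total + d
    return total * (1.0 / len(fa))
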