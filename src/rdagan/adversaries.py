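"""Discriminators and the frozen VGG-19 feature extractor.

Two discriminators drive the adversarial game: an image discriminator that
classifies real-HR vs super-resolved patches from pixels (SRGAN-style conv
stack with a dense head), and a feature discriminator that classifies the
two from *frozen VGG-19 feature maps*, pushing the generator toward real
structural high-frequency content rather than hallucinated noise.

The extractor supports two weight sources: ``seeded-random`` (Kaiming init
from a recorded seed — fully offline and deterministic, the test-suite
default) and ``file`` (a user-supplied ``.npz`` of conv weights, e.g.
converted from a pretrained VGG-19).  Extractor parameters are frozen:
gradients flow through them to the input image but never into them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import ConfigurationError, InvalidInputError, InvalidStateError
from .nn import functional as F
from .nn.tensor import Tensor

# VGG-19 convolutional schedule: widths per block, 'M' = 2×2 max pool
_VGG19_LAYOUT: list[tuple[str, int] | str] = []
for _b, (_n, _w) in enumerate([(2, 64), (2, 128), (4, 256), (4, 512), (4, 512)],
                              start=1):
    for _i in range(1, _n + 1):
        _VGG19_LAYOUT.append((f"conv{_b}_{_i}", _w))
    _VGG19_LAYOUT.append("M")

VGG19_TAPS = tuple(name for item in _VGG19_LAYOUT
                   if isinstance(item, tuple) for name in [item[0]])

# ImageNet channel statistics used to normalize extractor inputs
VGG_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
VGG_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


@dataclass(frozen=True)
class FeatureExtractorSpec:
    """Where to tap the VGG-19 stack and how its weights are sourced.

    ``layer_tag`` names the activation AFTER that conv's ReLU; the default
    ``conv5_4`` is the activation after the last conv of block 5, before the
    fifth pooling (the usual perceptual-loss tap).
    """

    layer_tag: str = "conv5_4"
    weights_source: str = "seeded-random"   # or "file"
    seed: int = 0
    weights_file: str | None = None
    normalize: bool = True

    def __post_init__(self):
        if self.layer_tag not in VGG19_TAPS:
            raise ConfigurationError(
                f"unknown VGG-19 tap {self.layer_tag!r}; "
                f"valid tags: {', '.join(VGG19_TAPS)}")
        if self.weights_source not in ("seeded-random", "file"):
            raise ConfigurationError(
                f"weights_source must be 'seeded-random' or 'file', "
                f"got {self.weights_source!r}")
        if self.weights_source == "file" and not self.weights_file:
            raise ConfigurationError("weights_source='file' needs weights_file")


def tap_channels(layer_tag: str) -> int:
    """Channel width of the feature map at a tap point."""
    for item in _VGG19_LAYOUT:
        if isinstance(item, tuple) and item[0] == layer_tag:
            return item[1]
    raise ConfigurationError(f"unknown VGG-19 tap {layer_tag!r}")


def tap_downscale(layer_tag: str) -> int:
    """Spatial downscale factor (2^pools) accumulated before a tap point."""
    factor = 1
    for item in _VGG19_LAYOUT:
        if item == "M":
            factor *= 2
        elif item[0] == layer_tag:
            return factor
    raise ConfigurationError(f"unknown VGG-19 tap {layer_tag!r}")


class VGGFeatureExtractor(nn.Module):
    """VGG-19 conv stack truncated at ``spec.layer_tag``; parameters frozen."""

    def __init__(self, spec: FeatureExtractorSpec):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self.ops: list[tuple[str, nn.Conv2d | None]] = []
        convs = nn.ModuleList()
        in_ch = 3
        for item in _VGG19_LAYOUT:
            if item == "M":
                self.ops.append(("pool", None))
                continue
            tag, width = item
            conv = nn.Conv2d(in_ch, width, 3, rng)
            convs.append(conv)
            self.ops.append((tag, conv))
            in_ch = width
            if tag == spec.layer_tag:
                break
        self.convs = convs
        if spec.weights_source == "file":
            self._load_weights(spec.weights_file)
        for p in self.parameters():
            p.requires_grad = False          # frozen forever

    def _load_weights(self, path: str):
        archive = np.load(path)
        for i, conv in enumerate(self.convs):
            conv.weight.data = np.asarray(
                archive[f"conv{i}_weight"], dtype=np.float32)
            conv.bias.data = np.asarray(
                archive[f"conv{i}_bias"], dtype=np.float32)

    @property
    def out_channels(self) -> int:
        return tap_channels(self.spec.layer_tag)

    def forward(self, x: Tensor) -> Tensor:
        if self.spec.normalize:
            mean = VGG_MEAN.reshape(1, 3, 1, 1)
            std = VGG_STD.reshape(1, 3, 1, 1)
            x = (x - mean) / std
        for tag, conv in self.ops:
            if tag == "pool":
                x = F.max_pool2d(x, 2)
            else:
                x = F.relu(conv(x))
        return x


def vgg_features(img: Tensor, extractor: VGGFeatureExtractor) -> Tensor:
    """Activation at the extractor's tap point for a batch of images."""
    return extractor(img)


class ImageDiscriminator(nn.Module):
    """SRGAN-style pixel-domain classifier for HR-sized patches.

    Eight 3×3 convs with widths w, w, 2w, 2w, 4w, 4w, 8w, 8w alternating
    stride 1/2, LeakyReLU(0.2), batch normalization from the second conv on,
    then a dense head ending in a sigmoid.
    """

    def __init__(self, rng: np.random.Generator, input_size: int = 192,
                 base_width: int = 64, in_channels: int = 3):
        super().__init__()
        if input_size % 16 or input_size < 16:
            raise ConfigurationError(
                f"input_size must be a multiple of 16 (the stride chain "
                f"divides by 16), got {input_size}")
        self.input_size = input_size
        self.in_channels = in_channels
        w = base_width
        plan = [(in_channels, w, 1), (w, w, 2), (w, 2 * w, 1), (2 * w, 2 * w, 2),
                (2 * w, 4 * w, 1), (4 * w, 4 * w, 2), (4 * w, 8 * w, 1),
                (8 * w, 8 * w, 2)]
        self.convs = nn.ModuleList(
            [nn.Conv2d(ci, co, 3, rng, stride=s) for ci, co, s in plan])
        self.norms = nn.ModuleList(
            [nn.BatchNorm2d(co) for _, co, _ in plan[1:]])
        side = input_size // 16
        self.fc1 = nn.Linear(8 * w * side * side, 16 * w, rng)
        self.fc2 = nn.Linear(16 * w, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise InvalidInputError(
                f"discriminator expects {self.in_channels}-channel input")
        if h != self.input_size or w != self.input_size:
            raise InvalidInputError(
                f"discriminator was built for {self.input_size}² patches, "
                f"got {h}×{w}")
        x = F.leaky_relu(self.convs[0](x))
        for conv, norm in zip(list(self.convs)[1:], self.norms):
            x = F.leaky_relu(norm(conv(x)))
        x = x.reshape(n, -1)
        x = F.leaky_relu(self.fc1(x))
        return F.sigmoid(self.fc2(x)).reshape(n)


class FeatureDiscriminator(nn.Module):
    """Classifier over frozen VGG feature maps (structural discriminator).

    Four stride-2 3×3 convs (half-width, half-width, full-width, full-width
    relative to the tap channel count), LeakyReLU(0.2), global average
    pooling, dense sigmoid head.  Pooling makes it tap-size agnostic.
    """

    def __init__(self, rng: np.random.Generator, in_channels: int = 512):
        super().__init__()
        self.in_channels = in_channels
        half = max(in_channels // 2, 8)
        plan = [(in_channels, half), (half, half), (half, in_channels),
                (in_channels, in_channels)]
        self.convs = nn.ModuleList(
            [nn.Conv2d(ci, co, 3, rng, stride=2) for ci, co in plan])
        self.fc = nn.Linear(in_channels, 1, rng)

    def forward(self, feat: Tensor) -> Tensor:
        n, c, _, _ = feat.shape
        if c != self.in_channels:
            raise InvalidStateError(
                f"feature discriminator expects {self.in_channels} channels "
                f"(the tap width), got {c}")
        x = feat
        for conv in self.convs:
            x = F.leaky_relu(conv(x))
        x = F.global_avg_pool(x)
        return F.sigmoid(self.fc(x)).reshape(n)


def image_discriminator_forward(img: Tensor,
                                disc: ImageDiscriminator) -> Tensor:
    """Per-sample probability that each image in the batch is a real HR."""
    return disc(img)


def feature_discriminator_forward(feat: Tensor,
                                  disc: FeatureDiscriminator) -> Tensor:
    """Per-sample probability from the feature-map classifier."""
    return disc(feat)


@dataclass
class AdversarialBatch:
    """One batch of real/generated pairs plus their frozen feature maps."""

    real_hr: Tensor
    generated: Tensor
    real_features: Tensor | None = None
    generated_features: Tensor | None = None

    def __post_init__(self):
        if self.real_hr.shape != self.generated.shape:
            raise InvalidInputError(
                f"real and generated batches must match: "
                f"{self.real_hr.shape} vs {self.generated.shape}")

    @classmethod
    def build(cls, real_hr: Tensor, generated: Tensor,
              extractor: VGGFeatureExtractor | None = None
              ) -> "AdversarialBatch":
        batch = cls(real_hr, generated)
        if extractor is not None:
            batch.real_features = extractor(real_hr)
            batch.generated_features = extractor(generated)
        return batch
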