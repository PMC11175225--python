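"""The residual dense attention generator.

Architecture, LR → SR:

1. shallow feature extraction — a wide 9×9 conv (SRGAN-style head) producing
   F0 with ``base_channels`` (G0) channels, followed by a second 3×3 conv;
   F0 feeds the global residual skip,
2. a chain of D residual dense attention blocks (RDABs): each block runs C
   densely connected conv+ReLU layers (layer c sees the block input plus all
   previous layer outputs, adding ``growth_rate`` G channels each), fuses the
   concatenation back to G0 channels with a 1×1 conv (local feature fusion),
   optionally refines with CBAM, and adds the block input (local residual
   learning),
3. dense feature fusion — 1×1 then 3×3 convs over the concatenation of all D
   block outputs (global feature fusion), plus F0 (global residual learning),
4. reconstruction — one 3×3 conv + ×2 pixel shuffle + PReLU stage per factor
   of two, then a 9×9 conv back to RGB.

Defaults are calibrated so the generator carries 11.25 M trainable
parameters: D=16, C=6, G=58, G0=64, CBAM reduction 4; see
:func:`expected_parameter_count` and :func:`calibrate_growth_rate` for the
closed-form count and the calibration search.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

import numpy as np

from . import nn
from .attention import CBAM
from .errors import ConfigurationError, InvalidInputError, InvalidStateError
from .image import FeatureStack, RasterImage
from .nn import functional as F
from .nn.tensor import Tensor


@dataclass(frozen=True)
class GeneratorSpec:
    """All architectural hyperparameters of the generator."""

    num_blocks: int = 16          # D — RDABs in the chain
    convs_per_block: int = 6      # C — dense layers per block
    growth_rate: int = 58         # G — channels added per dense layer
    base_channels: int = 64       # G0 — width of F0 and all fused features
    scale: int = 2                # upsampling factor (power of two)
    kernel_size: int = 3
    head_kernel_size: int = 9     # first and last convs (SRGAN convention)
    second_shallow_conv: bool = True
    cbam_enabled: bool = True
    cbam_reduction: int = 4
    cbam_spatial_kernel: int = 7
    cbam_position: str = "pre_residual"  # or "post_residual"
    use_rdb: bool = True          # False → plain conv-ReLU-conv residual block
    in_channels: int = 3
    out_channels: int = 3
    mean_shift: float = 0.5       # EDSR-style input centering, added back at
                                  # the output; 0 disables
    residual_init_scale: float = 0.1  # ESRGAN-style down-scaling of the
                                      # residual-branch init

    def __post_init__(self):
        for name in ("num_blocks", "convs_per_block", "growth_rate",
                     "base_channels"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if self.kernel_size % 2 == 0 or self.head_kernel_size % 2 == 0:
            raise ConfigurationError("kernel sizes must be odd")
        if self.scale < 2 or self.scale & (self.scale - 1):
            raise ConfigurationError(
                f"scale must be a power of two >= 2, got {self.scale}")
        if self.cbam_position not in ("pre_residual", "post_residual"):
            raise ConfigurationError(
                f"unknown cbam_position {self.cbam_position!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorSpec":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "GeneratorSpec":
        return cls.from_dict(json.loads(s))

    def with_(self, **kwargs) -> "GeneratorSpec":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

class DenseBlock(nn.Module):
    """C densely connected conv+ReLU layers plus 1×1 local feature fusion."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        super().__init__()
        g0, g, c, k = (spec.base_channels, spec.growth_rate,
                       spec.convs_per_block, spec.kernel_size)
        self.g0 = g0
        self.convs = nn.ModuleList(
            [nn.Conv2d(g0 + i * g, g, k, rng) for i in range(c)])
        self.lff = nn.Conv2d(g0 + c * g, g0, 1, rng)

    def forward(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        if x.shape[1] != self.g0:
            raise InvalidStateError(
                f"dense block expects {self.g0} input channels, "
                f"got {x.shape[1]}")
        feats = [x]
        outputs: list[Tensor] = []
        for conv in self.convs:
            cat = feats[0] if len(feats) == 1 else F.concatenate(feats, axis=1)
            out = F.relu(conv(cat))
            outputs.append(out)
            feats.append(out)
        fused = self.lff(F.concatenate(feats, axis=1))
        return fused, outputs


class PlainResidualCore(nn.Module):
    """Ablation core: conv-ReLU-conv at constant width (no dense wiring)."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        super().__init__()
        g0, k = spec.base_channels, spec.kernel_size
        self.conv1 = nn.Conv2d(g0, g0, k, rng)
        self.conv2 = nn.Conv2d(g0, g0, k, rng)

    def forward(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        h = F.relu(self.conv1(x))
        return self.conv2(h), [h]


class RDAB(nn.Module):
    """Residual dense attention block: dense core + CBAM + local residual."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.core = (DenseBlock(spec, rng) if spec.use_rdb
                     else PlainResidualCore(spec, rng))
        self.cbam = (CBAM(spec.base_channels, rng,
                          reduction=spec.cbam_reduction,
                          spatial_kernel=spec.cbam_spatial_kernel)
                     if spec.cbam_enabled else None)

    def forward(self, x: Tensor) -> Tensor:
        fused, _ = self.core(x)
        if self.cbam is None:
            return x + fused
        if self.spec.cbam_position == "pre_residual":
            return x + self.cbam(fused)
        return self.cbam(x + fused)


class RDAGANGenerator(nn.Module):
    """Full LR→SR generator; deterministic given weights and input."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        g0, k, hk = spec.base_channels, spec.kernel_size, spec.head_kernel_size
        self.sfe1 = nn.Conv2d(spec.in_channels, g0, hk, rng)
        self.sfe2 = (nn.Conv2d(g0, g0, k, rng)
                     if spec.second_shallow_conv else None)
        self.blocks = nn.ModuleList(
            [RDAB(spec, rng) for _ in range(spec.num_blocks)])
        self.gff1 = nn.Conv2d(spec.num_blocks * g0, g0, 1, rng)
        self.gff2 = nn.Conv2d(g0, g0, k, rng)
        stages = int(np.log2(spec.scale))
        self.up_convs = nn.ModuleList(
            [nn.Conv2d(g0, 4 * g0, k, rng) for _ in range(stages)])
        self.up_acts = nn.ModuleList([nn.PReLU() for _ in range(stages)])
        self.tail = nn.Conv2d(g0, spec.out_channels, hk, rng)
        if spec.residual_init_scale != 1.0:
            # start the dense/fusion branches near pass-through so the
            # shallow head dominates early optimization
            for module in list(self.blocks) + [self.gff1, self.gff2]:
                for p in module.parameters():
                    p.data *= spec.residual_init_scale

    # stages of the forward pass, exposed for the op-level API -------------

    def extract_shallow(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.spec.in_channels:
            raise InvalidInputError(
                f"generator expects {self.spec.in_channels}-channel input, "
                f"got {x.shape[1]}")
        if self.spec.mean_shift:
            x = x - self.spec.mean_shift
        return self.sfe1(x)

    def fuse_blocks(self, f0: Tensor, block_outputs: list[Tensor]) -> Tensor:
        d = self.spec.num_blocks
        if len(block_outputs) != d:
            raise InvalidStateError(
                f"expected {d} block outputs, got {len(block_outputs)}")
        for b in block_outputs:
            if b.shape != f0.shape:
                raise InvalidStateError(
                    f"block output shape {b.shape} does not match F0 "
                    f"shape {f0.shape}")
        fgf = self.gff2(self.gff1(F.concatenate(block_outputs, axis=1)))
        return f0 + fgf

    def reconstruct(self, fdf: Tensor) -> Tensor:
        f = fdf
        for conv, act in zip(self.up_convs, self.up_acts):
            f = act(F.pixel_shuffle(conv(f), 2))
        out = self.tail(f)
        if self.spec.mean_shift:
            out = out + self.spec.mean_shift
        return out

    def forward(self, x: Tensor) -> Tensor:
        f0 = self.extract_shallow(x)
        f = self.sfe2(f0) if self.sfe2 is not None else f0
        outputs = []
        for block in self.blocks:
            f = block(f)
            outputs.append(f)
        return self.reconstruct(self.fuse_blocks(f0, outputs))


# ---------------------------------------------------------------------------
# op-level API on the domain containers
# ---------------------------------------------------------------------------

def build_generator(spec: GeneratorSpec | None = None,
                    seed: int = 0) -> RDAGANGenerator:
    return RDAGANGenerator(spec or GeneratorSpec(),
                           np.random.default_rng(seed))


def shallow_extract(lr: RasterImage, generator: RDAGANGenerator) -> FeatureStack:
    """F0: shallow features of the LR image at G0 channels, same spatial dims."""
    if lr.colorspace != "RGB":
        raise InvalidInputError("shallow_extract expects an RGB image")
    return FeatureStack.from_tensor(generator.extract_shallow(lr.to_tensor()))


def rdb_dense_forward(f_in: FeatureStack, block: RDAB
                      ) -> tuple[FeatureStack, list[FeatureStack]]:
    """The dense core of one block: C stacked layers + local feature fusion.

    Returns the fused G0-channel map and the C per-layer outputs (the latter
    so independent oracles can check the dense wiring).
    """
    fused, outputs = block.core(f_in.to_tensor())
    return (FeatureStack.from_tensor(fused),
            [FeatureStack.from_tensor(o) for o in outputs])


def rdab_forward(f_prev: FeatureStack, block: RDAB) -> FeatureStack:
    """One full block: dense core, optional CBAM, local residual addition."""
    return FeatureStack.from_tensor(block(f_prev.to_tensor()))


def dense_feature_fusion(f0: FeatureStack, block_outputs: list[FeatureStack],
                         generator: RDAGANGenerator) -> FeatureStack:
    """Global feature fusion over all block outputs, plus the F0 skip."""
    fused = generator.fuse_blocks(
        f0.to_tensor(), [b.to_tensor() for b in block_outputs])
    return FeatureStack.from_tensor(fused)


def upsample_reconstruct(fdf: FeatureStack, generator: RDAGANGenerator,
                         clip: bool = True) -> RasterImage:
    """Sub-pixel reconstruction to RGB at ``scale`` × the input dims."""
    out = generator.reconstruct(fdf.to_tensor())
    return RasterImage.from_tensor(out, clip=clip)


def generator_forward(lr: RasterImage,
                      generator: RDAGANGenerator) -> RasterImage:
    """End-to-end SR pass on one image; output clipped to [0, 1]."""
    return RasterImage.from_tensor(generator(lr.to_tensor()), clip=True)


# ---------------------------------------------------------------------------
# parameter accounting and calibration
# ---------------------------------------------------------------------------

def count_parameters(module: nn.Module) -> int:
    """Total trainable scalars (weights + biases)."""
    return sum(p.size for p in module.parameters() if p.requires_grad)


def parameter_millions(module: nn.Module) -> float:
    """Parameter count in millions, rounded to two decimals."""
    return round(count_parameters(module) / 1e6, 2)


def _conv_params(k: int, cin: int, cout: int, bias: bool = True) -> int:
    return k * k * cin * cout + (cout if bias else 0)


def expected_parameter_count(spec: GeneratorSpec) -> int:
    """Closed-form trainable-parameter count of the generator.

    Mirrors the architecture layer by layer; cross-checked in the test suite
    against the instantiated module.  Used by the calibration search.
    """
    g0, g, c, d = (spec.base_channels, spec.growth_rate,
                   spec.convs_per_block, spec.num_blocks)
    k, hk = spec.kernel_size, spec.head_kernel_size
    total = _conv_params(hk, spec.in_channels, g0)
    if spec.second_shallow_conv:
        total += _conv_params(k, g0, g0)
    if spec.use_rdb:
        block = sum(_conv_params(k, g0 + i * g, g) for i in range(c))
        block += _conv_params(1, g0 + c * g, g0)
    else:
        block = 2 * _conv_params(k, g0, g0)
    if spec.cbam_enabled:
        hidden = g0 // spec.cbam_reduction
        block += 2 * g0 * hidden                       # shared MLP, no biases
        block += _conv_params(spec.cbam_spatial_kernel, 2, 1)
    total += d * block
    total += _conv_params(1, d * g0, g0)               # global fusion 1×1
    total += _conv_params(k, g0, g0)                   # global fusion 3×3
    stages = int(np.log2(spec.scale))
    total += stages * (_conv_params(k, g0, 4 * g0) + 1)  # conv + PReLU slope
    total += _conv_params(hk, g0, spec.out_channels)
    return total


def calibrate_growth_rate(target_millions: float = 11.25,
                          spec: GeneratorSpec | None = None,
                          candidates: range = range(16, 97)) -> int:
    """Growth rate G whose closed-form budget is nearest ``target_millions``.

    The printed parameter budget is the only architectural constraint beyond
    the block count, so the per-layer growth is chosen to meet it.
    """
    base = spec or GeneratorSpec()
    best_g, best_err = None, np.inf
    for g in candidates:
        count = expected_parameter_count(base.with_(growth_rate=g))
        err = abs(count / 1e6 - target_millions)
        if err < best_err:
            best_g, best_err = g, err
    return best_g
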