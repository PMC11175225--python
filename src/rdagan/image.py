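"""Image and feature-map containers shared across the package.

A :class:`RasterImage` is the external currency: an H×W×3 float array in
[0, 1] with a colorspace tag.  A :class:`FeatureStack` is the internal
currency of the networks: a C×H×W activation array.  Conversion to and from
the NCHW tensors the compute core uses happens only at these boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import InvalidInputError
from .nn.tensor import Tensor


@dataclass
class RasterImage:
    values: np.ndarray          # (H, W, 3) float32 in [0, 1]
    colorspace: str = "RGB"     # "RGB" or "YCbCr"

    def __post_init__(self):
        arr = np.asarray(self.values)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise InvalidInputError(
                f"expected an H×W×3 array, got shape {arr.shape}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise InvalidInputError("image must be at least 1×1")
        self.values = arr.astype(np.float32, copy=False)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    # -- file IO --------------------------------------------------------------

    @classmethod
    def from_file(cls, path: str | Path) -> "RasterImage":
        """Read an 8- or 16-bit PNG/TIFF, normalize to [0, 1] RGB."""
        arr = iio.imread(path)
        if arr.ndim == 2:
            arr = np.stack([arr] * 3, axis=-1)
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.dtype == np.uint8:
            arr = arr.astype(np.float32) / 255.0
        elif arr.dtype == np.uint16:
            arr = arr.astype(np.float32) / 65535.0
        else:
            arr = arr.astype(np.float32)
        return cls(np.clip(arr, 0.0, 1.0))

    def to_file(self, path: str | Path) -> None:
        arr = np.clip(self.values, 0.0, 1.0)
        iio.imwrite(path, (arr * 255.0 + 0.5).astype(np.uint8))

    # -- tensor bridge --------------------------------------------------------

    def to_tensor(self) -> Tensor:
        """(H, W, 3) → NCHW tensor with batch size 1."""
        return Tensor(self.values.transpose(2, 0, 1)[None])

    @classmethod
    def from_tensor(cls, t: Tensor | np.ndarray, clip: bool = True,
                    colorspace: str = "RGB") -> "RasterImage":
        arr = t.data if isinstance(t, Tensor) else np.asarray(t)
        if arr.ndim == 4:
            if arr.shape[0] != 1:
                raise InvalidInputError("from_tensor expects batch size 1")
            arr = arr[0]
        arr = arr.transpose(1, 2, 0)
        if clip:
            arr = np.clip(arr, 0.0, 1.0)
        return cls(np.ascontiguousarray(arr), colorspace=colorspace)

    def clipped(self) -> "RasterImage":
        return RasterImage(np.clip(self.values, 0.0, 1.0), self.colorspace)


@dataclass
class FeatureStack:
    """C×H×W activation array with consistency checks."""

    values: np.ndarray
    channel_count: int = field(init=False)
    spatial_dims: tuple[int, int] = field(init=False)

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=np.float32)
        if arr.ndim != 3:
            raise InvalidInputError(
                f"FeatureStack expects a C×H×W array, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError("FeatureStack entries must be finite")
        self.values = arr
        self.channel_count = arr.shape[0]
        self.spatial_dims = (arr.shape[1], arr.shape[2])

    def to_tensor(self) -> Tensor:
        return Tensor(self.values[None])

    @classmethod
    def from_tensor(cls, t: Tensor | np.ndarray) -> "FeatureStack":
        arr = t.data if isinstance(t, Tensor) else np.asarray(t)
        if arr.ndim == 4:
            if arr.shape[0] != 1:
                raise InvalidInputError("from_tensor expects batch size 1")
            arr = arr[0]
        return cls(arr.copy())
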