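"""Evaluation protocol: Y-channel PSNR/SSIM in BT.601 YCbCr.

Fidelity is scored on the luma (Y) channel after an ITU-R BT.601
studio-swing conversion (Y ∈ [16, 235]/255 for inputs in [0, 1]) — the
convention of the MATLAB-derived super-resolution evaluation protocols —
with a configurable border shave (default: ``scale`` pixels).  PSNR uses
peak 1.0 and is capped at 100 dB for identical inputs; SSIM is the standard
11×11 Gaussian-windowed (σ = 1.5) index with k1 = 0.01, k2 = 0.03 on a unit
dynamic range.  LPIPS needs externally trained network weights and is a
strictly optional plug-in: pass any callable distance; when absent the
report marks it unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from time import perf_counter
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .data import PairedSample
from .errors import InvalidInputError
from .image import RasterImage

PSNR_CAP_DB = 100.0

# BT.601 studio-swing matrix for inputs scaled 0..255
_YCBCR_MATRIX = np.array([[65.481, 128.553, 24.966],
                          [-37.797, -74.203, 112.0],
                          [112.0, -93.786, -18.214]], dtype=np.float64)
_YCBCR_OFFSET = np.array([16.0, 128.0, 128.0], dtype=np.float64)


def rgb_to_ycbcr(img: RasterImage, full_swing: bool = False) -> RasterImage:
    """BT.601 RGB → YCbCr on [0, 1] data (studio swing by default)."""
    if img.colorspace != "RGB":
        raise InvalidInputError(
            f"expected an RGB image, got colorspace {img.colorspace!r}")
    rgb = img.values.astype(np.float64)
    if full_swing:
        y = rgb @ np.array([0.299, 0.587, 0.114])
        cb = 0.5 + (rgb[..., 2] - y) * 0.564
        cr = 0.5 + (rgb[..., 0] - y) * 0.713
        out = np.stack([y, cb, cr], axis=-1)
    else:
        out = (rgb @ _YCBCR_MATRIX.T + _YCBCR_OFFSET) / 255.0
    return RasterImage(out.astype(np.float32), colorspace="YCbCr")


def luma(img: RasterImage, full_swing: bool = False) -> np.ndarray:
    """The Y plane of an RGB image (H×W float array)."""
    return rgb_to_ycbcr(img, full_swing=full_swing).values[:, :, 0]


def psnr(a: np.ndarray, b: np.ndarray, peak: float = 1.0) -> float:
    """10·log10(peak²/MSE) in dB; identical inputs return the 100 dB cap."""
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise InvalidInputError(f"shape mismatch: {a.shape} vs {b.shape}")
    if peak <= 0:
        raise InvalidInputError("peak must be positive")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return PSNR_CAP_DB
    return min(10.0 * np.log10(peak * peak / mse), PSNR_CAP_DB)


def _gaussian_kernel(sigma: float = 1.5, radius: int = 5) -> np.ndarray:
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def ssim(a: np.ndarray, b: np.ndarray, data_range: float = 1.0,
         sigma: float = 1.5, k1: float = 0.01, k2: float = 0.03) -> float:
    """Gaussian-windowed structural similarity, mean over valid windows.

    The window is 11×11 (radius 5); the map is cropped by the window radius
    before averaging so padded borders never contribute.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise InvalidInputError(f"shape mismatch: {a.shape} vs {b.shape}")
    radius = 5
    if min(a.shape) < 2 * radius + 1:
        raise InvalidInputError(
            f"images of shape {a.shape} are smaller than the "
            f"{2 * radius + 1}×{2 * radius + 1} SSIM window")
    kernel = _gaussian_kernel(sigma, radius)

    def smooth(x):
        x = ndimage.correlate1d(x, kernel, axis=0, mode="nearest")
        return ndimage.correlate1d(x, kernel, axis=1, mode="nearest")

    ua, ub = smooth(a), smooth(b)
    vara = smooth(a * a) - ua * ua
    varb = smooth(b * b) - ub * ub
    cov = smooth(a * b) - ua * ub
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    s = ((2 * ua * ub + c1) * (2 * cov + c2) /
         ((ua * ua + ub * ub + c1) * (vara + varb + c2)))
    return float(s[radius:-radius, radius:-radius].mean())


def shave_border(plane: np.ndarray, pixels: int) -> np.ndarray:
    if pixels <= 0:
        return plane
    return plane[pixels:-pixels, pixels:-pixels]


@dataclass
class ImageScore:
    name: str
    psnr: float
    ssim: float
    identical: bool
    lpips: float | None = None
    seconds: float = 0.0


@dataclass
class MetricReport:
    """Per-image and aggregate fidelity scores for one model/dataset pair."""

    scores: list[ImageScore]
    dataset_tag: str = ""
    parameter_millions: float | None = None
    lpips_available: bool = False
    extras: dict = field(default_factory=dict)

    @property
    def mean_psnr(self) -> float:
        return float(np.mean([s.psnr for s in self.scores]))

    @property
    def mean_ssim(self) -> float:
        return float(np.mean([s.ssim for s in self.scores]))

    @property
    def mean_lpips(self) -> float | None:
        if not self.lpips_available:
            return None
        return float(np.mean([s.lpips for s in self.scores]))

    @property
    def mean_seconds(self) -> float:
        return float(np.mean([s.seconds for s in self.scores]))

    def rows(self) -> list[dict]:
        out = []
        for s in self.scores:
            out.append({"name": s.name, "psnr_db": s.psnr, "ssim": s.ssim,
                        "lpips": "" if s.lpips is None else s.lpips,
                        "identical": int(s.identical),
                        "seconds": s.seconds})
        return out


def score_pair(sr: RasterImage, hr: RasterImage, shave: int = 0,
               on_y: bool = True) -> tuple[float, float, bool]:
    """(PSNR, SSIM, identical-flag) for one SR/HR pair."""
    if sr.shape != hr.shape:
        raise InvalidInputError(
            f"SR shape {sr.shape} does not match HR shape {hr.shape}")
    if on_y:
        pa, pb = luma(sr), luma(hr)
    else:
        pa, pb = sr.values.mean(axis=2), hr.values.mean(axis=2)
    pa, pb = shave_border(pa, shave), shave_border(pb, shave)
    identical = bool(np.array_equal(pa, pb))
    return psnr(pa, pb), ssim(pa, pb), identical


def evaluate_model(sr_fn: Callable[[RasterImage], RasterImage],
                   dataset: Sequence[PairedSample],
                   shave: int | None = None,
                   lpips_fn: Callable[[RasterImage, RasterImage], float] | None = None,
                   dataset_tag: str = "",
                   parameter_millions: float | None = None) -> MetricReport:
    """Run ``sr_fn`` over every LR image and score against the paired HR.

    ``sr_fn`` is any LR→SR callable (a generator forward, a bicubic
    upsampler, ...).  ``shave`` defaults to the dataset's scale factor.
    """
    samples = list(dataset)
    if not samples:
        raise InvalidInputError("cannot evaluate on an empty dataset")
    if shave is None:
        shave = samples[0].scale
    scores = []
    for i, sample in enumerate(samples):
        t0 = perf_counter()
        sr = sr_fn(sample.lr)
        dt = perf_counter() - t0
        p, s, identical = score_pair(sr, sample.hr, shave=shave)
        lp = lpips_fn(sr, sample.hr) if lpips_fn is not None else None
        scores.append(ImageScore(name=sample.provenance or str(i), psnr=p,
                                 ssim=s, identical=identical, lpips=lp,
                                 seconds=dt))
    return MetricReport(scores=scores, dataset_tag=dataset_tag,
                        parameter_millions=parameter_millions,
                        lpips_available=lpips_fn is not None)
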