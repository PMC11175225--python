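"""Paired HR/LR data: bicubic degradation, cropping, augmentation, and a
synthetic bright-field cell-scene generator.

Real corpora for this task pair 1024×1024 HR fields with 512×512 LR fields
captured at half the magnification; since exact optical registration is
impractical, LR training inputs are produced by bicubic ×2 downsampling of
the HR images — the same degradation model is used here throughout.  The
synthetic generator emulates what a bright-field cell field looks like
(bright smoothly lit background, rounded cell bodies with darker nuclei,
intra-cell texture, mild optical blur, sensor noise) so the whole tool is
exercisable without any external data.

Bicubic resampling is delegated to Pillow's float-mode resize (Catmull-Rom
kernel a = −0.5 with support scaling when decimating, i.e. antialiased) —
the dialect conventional in the super-resolution literature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import InvalidInputError
from .image import RasterImage

IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def _resize(values: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Channelwise float bicubic resize via Pillow."""
    out = np.empty((out_h, out_w, values.shape[2]), dtype=np.float32)
    for c in range(values.shape[2]):
        im = Image.fromarray(values[:, :, c].astype(np.float32), mode="F")
        out[:, :, c] = np.asarray(
            im.resize((out_w, out_h), Image.Resampling.BICUBIC),
            dtype=np.float32)
    return out


def bicubic_downsample(hr: RasterImage, scale: int) -> RasterImage:
    """Antialiased bicubic decimation by an integer factor."""
    if hr.height % scale or hr.width % scale:
        raise InvalidInputError(
            f"image dims {hr.height}×{hr.width} not divisible by "
            f"scale {scale}")
    out = _resize(hr.values, hr.height // scale, hr.width // scale)
    return RasterImage(np.clip(out, 0.0, 1.0), hr.colorspace)


def bicubic_upsample(lr: RasterImage, scale: int) -> RasterImage:
    """Bicubic interpolation up by an integer factor (the SR baseline)."""
    out = _resize(lr.values, lr.height * scale, lr.width * scale)
    return RasterImage(np.clip(out, 0.0, 1.0), lr.colorspace)


# ---------------------------------------------------------------------------
# paired samples
# ---------------------------------------------------------------------------

@dataclass
class PairedSample:
    """An HR image and its aligned LR counterpart."""

    hr: RasterImage
    lr: RasterImage
    provenance: str = ""

    def __post_init__(self):
        if self.lr.height < 1 or self.hr.height % self.lr.height or \
                self.hr.width % self.lr.width:
            raise InvalidInputError(
                f"HR dims {self.hr.height}×{self.hr.width} are not an "
                f"integer multiple of LR dims {self.lr.height}×{self.lr.width}")
        sy = self.hr.height // self.lr.height
        sx = self.hr.width // self.lr.width
        if sy != sx:
            raise InvalidInputError(
                f"anisotropic HR/LR scale {sy}×{sx} is not supported")
        self.scale = sy


def paired_random_crop(sample: PairedSample, hr_size: int,
                       rng: np.random.Generator) -> PairedSample:
    """Aligned random crop: HR side ``hr_size``, LR side ``hr_size/scale``.

    The crop origin is drawn on the LR grid and scaled up, so alignment is
    exact by construction.
    """
    scale = sample.scale
    if hr_size % scale:
        raise InvalidInputError(
            f"hr_size {hr_size} must be divisible by scale {scale}")
    if hr_size > sample.hr.height or hr_size > sample.hr.width:
        raise InvalidInputError(
            f"hr_size {hr_size} exceeds HR dims "
            f"{sample.hr.height}×{sample.hr.width}")
    lr_size = hr_size // scale
    ly = int(rng.integers(0, sample.lr.height - lr_size + 1))
    lx = int(rng.integers(0, sample.lr.width - lr_size + 1))
    y, x = ly * scale, lx * scale
    hr = RasterImage(sample.hr.values[y:y + hr_size, x:x + hr_size].copy())
    lr = RasterImage(sample.lr.values[ly:ly + lr_size, lx:lx + lr_size].copy())
    return PairedSample(hr, lr, provenance=f"{sample.provenance}|crop({y},{x})")


def dihedral_augment(sample: PairedSample, code: int) -> PairedSample:
    """Apply one of the 8 square symmetries identically to HR and LR.

    Codes 0–3 rotate by 90°·code counterclockwise; codes 4–7 additionally
    flip horizontally first.
    """
    if not 0 <= code <= 7:
        raise InvalidInputError(f"dihedral code must be in 0..7, got {code}")
    if sample.hr.height != sample.hr.width:
        raise InvalidInputError("dihedral augmentation requires square crops")

    def apply(values: np.ndarray) -> np.ndarray:
        out = values[:, ::-1] if code >= 4 else values
        return np.ascontiguousarray(np.rot90(out, k=code % 4))

    return PairedSample(RasterImage(apply(sample.hr.values)),
                        RasterImage(apply(sample.lr.values)),
                        provenance=f"{sample.provenance}|d{code}")


# ---------------------------------------------------------------------------
# datasets on disk
# ---------------------------------------------------------------------------

@dataclass
class PairRejection:
    filename: str
    reason: str


class PairedImageDataset:
    """Order-stable, lazily decoded dataset of HR/LR pairs.

    With ``lr_dir=None`` the LR member is produced on load by bicubic
    downsampling (degrade-on-load).  Unpairable or inconsistent files are
    recorded in :attr:`rejections`, never silently dropped.
    """

    def __init__(self, hr_dir: str | Path, lr_dir: str | Path | None = None,
                 scale: int = 2):
        self.hr_dir = Path(hr_dir)
        self.lr_dir = Path(lr_dir) if lr_dir is not None else None
        self.scale = scale
        self.rejections: list[PairRejection] = []
        self._pairs: list[tuple[Path, Path | None]] = []
        if not self.hr_dir.is_dir():
            raise InvalidInputError(f"no such directory: {self.hr_dir}")
        hr_files = sorted(p for p in self.hr_dir.iterdir()
                          if p.suffix.lower() in IMAGE_SUFFIXES)
        if not hr_files:
            warnings.warn(f"no images found in {self.hr_dir}", stacklevel=2)
        for hr_path in hr_files:
            if self.lr_dir is None:
                with Image.open(hr_path) as im:
                    w, h = im.size
                if h % scale or w % scale:
                    self.rejections.append(PairRejection(
                        hr_path.name, f"dims {h}×{w} not divisible by {scale}"))
                    continue
                self._pairs.append((hr_path, None))
                continue
            lr_path = self.lr_dir / hr_path.name
            if not lr_path.exists():
                self.rejections.append(
                    PairRejection(hr_path.name, "no matching LR file"))
                continue
            with Image.open(hr_path) as im:
                hw, hh = im.size
            with Image.open(lr_path) as im:
                lw, lh = im.size
            if (hh, hw) != (lh * scale, lw * scale):
                self.rejections.append(PairRejection(
                    hr_path.name,
                    f"HR {hh}×{hw} vs LR {lh}×{lw} violates ×{scale}"))
                continue
            self._pairs.append((hr_path, lr_path))

    def __len__(self) -> int:
        return len(self._pairs)

    def __getitem__(self, idx: int) -> PairedSample:
        hr_path, lr_path = self._pairs[idx]
        hr = RasterImage.from_file(hr_path)
        if lr_path is None:
            lr = bicubic_downsample(hr, self.scale)
        else:
            lr = RasterImage.from_file(lr_path)
        return PairedSample(hr, lr, provenance=hr_path.name)

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]


def load_image_pairs(hr_dir: str | Path, lr_dir: str | Path | None = None,
                     scale: int = 2) -> PairedImageDataset:
    """Scan directories into a paired dataset (see PairedImageDataset)."""
    return PairedImageDataset(hr_dir, lr_dir, scale)


# ---------------------------------------------------------------------------
# synthetic bright-field scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSceneSpec:
    """Parameters of one synthetic bright-field cell field.

    The seed fully determines the output.  ``nucleus_contrast`` is the extra
    darkening of the nucleus relative to the cell body; ``texture_amplitude``
    the strength of multiplicative intra-cell texture; amplitudes are in
    image units on [0, 1], lengths in pixels.
    """

    canvas_side: int = 256
    cell_count: int = 12
    cell_radius: tuple[float, float] = (10.0, 24.0)
    nucleus_contrast: float = 0.25
    texture_amplitude: float = 0.06
    illumination_gradient: float = 0.06
    blur_sigma: float = 0.8
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.canvas_side < 8:
            raise InvalidInputError("canvas_side must be at least 8")
        if self.cell_radius[0] <= 0 or self.cell_radius[1] < self.cell_radius[0]:
            raise InvalidInputError("cell_radius must be a positive range")
        if 2 * self.cell_radius[1] + 2 > self.canvas_side:
            raise InvalidInputError(
                f"cells of radius up to {self.cell_radius[1]} cannot fit a "
                f"{self.canvas_side}px canvas")


@dataclass
class SyntheticScene:
    image: RasterImage
    cell_centers: list[tuple[float, float]]
    spec: SyntheticSceneSpec = field(repr=False, default=None)


_BG_TINT = np.array([0.94, 0.92, 0.89], dtype=np.float32)   # warm bright field
_CELL_TINT = np.array([0.80, 0.72, 0.78], dtype=np.float32)  # eosin-like body
_NUCLEUS_TINT = np.array([0.45, 0.35, 0.60], dtype=np.float32)  # hematoxylin


def synthesize_cell_scene(spec: SyntheticSceneSpec) -> SyntheticScene:
    """Render one seed-deterministic bright-field cell field in [0, 1] RGB."""
    rng = np.random.default_rng(spec.seed)
    side = spec.canvas_side
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float32)

    # smooth background illumination: a tilted plane with random direction
    theta = rng.uniform(0, 2 * np.pi)
    ramp = ((xx * np.cos(theta) + yy * np.sin(theta)) / side)
    ramp -= ramp.mean()
    shade = 1.0 - spec.illumination_gradient * ramp
    img = _BG_TINT[None, None] * shade[:, :, None]

    centers: list[tuple[float, float]] = []
    body_total = np.zeros((side, side), dtype=np.float32)
    for _ in range(spec.cell_count):
        r = rng.uniform(*spec.cell_radius)
        cy = rng.uniform(r, side - r)
        cx = rng.uniform(r, side - r)
        phi = rng.uniform(0, np.pi)
        a = r * rng.uniform(0.75, 1.25)
        b = r * rng.uniform(0.75, 1.25)
        centers.append((cy, cx))
        dy, dx = yy - cy, xx - cx
        u = (dx * np.cos(phi) + dy * np.sin(phi)) / a
        v = (-dx * np.sin(phi) + dy * np.cos(phi)) / b
        q = u * u + v * v
        body = np.clip((1.0 - q) / 0.25, 0.0, 1.0)       # soft-edged ellipse
        body_total = np.maximum(body_total, body)
        img = img * (1.0 - body[:, :, None]) + \
            body[:, :, None] * _CELL_TINT[None, None] * shade[:, :, None]
        # darker elliptical nucleus, offset inside the body
        ny = cy + rng.uniform(-0.25, 0.25) * b
        nx = cx + rng.uniform(-0.25, 0.25) * a
        nr = 0.4 * min(a, b)
        qn = ((xx - nx) ** 2 + (yy - ny) ** 2) / (nr * nr)
        nucleus = np.clip((1.0 - qn) / 0.35, 0.0, 1.0)
        blend = spec.nucleus_contrast * nucleus[:, :, None]
        img = img * (1.0 - blend) + blend * _NUCLEUS_TINT[None, None]

    if spec.texture_amplitude > 0:
        noise = rng.normal(0.0, 1.0, size=(side, side)).astype(np.float32)
        texture = ndimage.gaussian_filter(noise, sigma=1.2)
        texture /= max(np.abs(texture).max(), 1e-8)
        img = img * (1.0 + spec.texture_amplitude * texture[:, :, None]
                     * body_total[:, :, None])

    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(
            img, sigma=(spec.blur_sigma, spec.blur_sigma, 0))
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma,
                               size=img.shape).astype(np.float32)

    return SyntheticScene(
        image=RasterImage(np.clip(img, 0.0, 1.0).astype(np.float32)),
        cell_centers=centers, spec=spec)


def synthesize_paired_samples(n: int, seed: int, canvas_side: int = 256,
                              scale: int = 2,
                              **spec_overrides) -> list[PairedSample]:
    """n seed-derived scenes, each paired with its bicubic ×scale LR."""
    samples = []
    for i in range(n):
        spec = SyntheticSceneSpec(canvas_side=canvas_side,
                                  seed=seed * 100_003 + i, **spec_overrides)
        scene = synthesize_cell_scene(spec)
        samples.append(PairedSample(scene.image,
                                    bicubic_downsample(scene.image, scale),
                                    provenance=f"synthetic:{spec.seed}"))
    return samples


def edge_energy(img: RasterImage) -> float:
    """Mean gradient magnitude (a scalar proxy for high-frequency content)."""
    gray = img.values.mean(axis=2)
    gy, gx = np.gradient(gray)
    return float(np.mean(np.hypot(gy, gx)))
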