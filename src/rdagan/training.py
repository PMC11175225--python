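"""Alternating adversarial training, checkpointing and inference.

One optimization step is one full alternation: (1) the image discriminator
descends C_di on real patches vs detached SR output, (2) the feature
discriminator descends C_df on frozen VGG features of the same, (3) the
generator descends C_g = C_p + λ(C_ai + C_af) with both discriminators
held fixed.  All three use Adam (β₁ = 0.9, β₂ = 0.999) at a learning rate
of 2×10⁻⁴, halved once after epoch 200 by default.

During the generator phase the discriminators run in eval mode, so their
entire state — parameters and batch-norm statistics alike — is bitwise
unchanged by a generator update (and vice versa); the frozen VGG extractor
never changes at all.  Training is deterministic for a fixed seed and data
order; checkpoints carry the RNG state so a resumed run reproduces the
unbroken loss trace.
"""

from __future__ import annotations

import csv
import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .adversaries import (FeatureDiscriminator, FeatureExtractorSpec,
                          ImageDiscriminator, VGGFeatureExtractor)
from .data import (PairedSample, dihedral_augment, paired_random_crop,
                   synthesize_paired_samples)
from .errors import ConfigurationError, InvalidInputError, InvalidStateError
from .generator import GeneratorSpec, RDAGANGenerator
from .image import RasterImage
from .losses import (DEFAULT_LAMBDA, LossBundle, adversarial_generator_loss,
                     bundle, discriminator_loss, generator_total_loss,
                     perceptual_loss)
from .nn import Adam
from .nn.tensor import Tensor

CHECKPOINT_SCHEMA = "rdagan-checkpoint-v1"
LOG_COLUMNS = ["step", "Cp", "Cai", "Caf", "Cg", "Cdi", "Cdf", "lr"]


@dataclass(frozen=True)
class TrainConfig:
    """Everything a training run needs; hashable for provenance."""

    epochs: int = 400
    steps_per_epoch: int | None = None     # None → ceil(len(dataset)/batch)
    batch_size: int = 16
    hr_crop: int = 192
    scale: int = 2
    lam: float = DEFAULT_LAMBDA
    lambda_scope: str = "both"
    pixel_weight: float = 1.0
    feature_weight: float = 1.0
    lr: float = 2e-4
    disc_lr: float | None = None           # None → same as lr
    lr_decay_epoch: int = 200
    lr_decay_factor: float = 0.5
    lr_decay_every: int | None = None      # None → one-shot halving
    beta1: float = 0.9
    beta2: float = 0.999
    seed: int = 0
    pretrain_epochs: int = 0               # optional MSE-only warmup
    grad_clip: float | None = None         # global grad-norm ceiling per update
    feature_discriminator: bool = True
    disc_base_width: int = 64
    generator: GeneratorSpec = field(default_factory=GeneratorSpec)
    extractor: FeatureExtractorSpec = field(default_factory=FeatureExtractorSpec)
    checkpoint_every: int = 0              # epochs; 0 → final only

    def __post_init__(self):
        if self.lr <= 0 or self.lr_decay_factor <= 0:
            raise ConfigurationError("learning rates must be positive")
        if self.hr_crop % self.scale:
            raise ConfigurationError(
                f"hr_crop {self.hr_crop} must be divisible by "
                f"scale {self.scale}")
        if self.batch_size < 1 or self.epochs < 0:
            raise ConfigurationError("batch_size >= 1 and epochs >= 0 required")
        if self.scale != self.generator.scale:
            raise ConfigurationError(
                f"config scale {self.scale} disagrees with generator "
                f"spec scale {self.generator.scale}")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        if isinstance(d.get("generator"), dict):
            d["generator"] = GeneratorSpec.from_dict(d["generator"])
        if isinstance(d.get("extractor"), dict):
            d["extractor"] = FeatureExtractorSpec(**d["extractor"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def with_(self, **kwargs) -> "TrainConfig":
        return replace(self, **kwargs)

    @classmethod
    def tiny_overfit(cls, seed: int = 0) -> "TrainConfig":
        """Desk-scale smoke-test configuration.

        Eight 64×64 synthetic HR patches, 300 steps (10 epochs × 30) at
        batch 4.  The training *procedure* — three-phase alternation,
        aligned cropping, dihedral augmentation — is the real one; the
        networks are scaled down for CPU speed (small generator, thin
        discriminator, shallow conv2_2 feature tap) and the generator
        learning rate is raised to 5×10⁻³, which suits the small parameter
        count, while the discriminators keep the full-recipe 2×10⁻⁴.  The
        adversarial weight is zero here: a discriminator that has memorized
        eight images drives the generator away from fidelity, so the
        fidelity smoke test uses the pure perceptual objective while both
        discriminators still train in their own phases.
        """
        gen = GeneratorSpec(num_blocks=2, convs_per_block=3, growth_rate=16,
                            base_channels=32, cbam_reduction=4,
                            head_kernel_size=3, second_shallow_conv=False)
        ext = FeatureExtractorSpec(layer_tag="conv2_2",
                                   weights_source="seeded-random", seed=seed)
        return cls(epochs=10, steps_per_epoch=30, batch_size=4, hr_crop=64,
                   lam=0.0, pixel_weight=1.0, feature_weight=0.0,
                   lr=5e-3, disc_lr=2e-4, beta2=0.99, seed=seed,
                   disc_base_width=16, generator=gen, extractor=ext)


def tiny_overfit_dataset(seed: int = 0) -> list[PairedSample]:
    """The eight 64×64 patches of the smoke test: granule-dense scenes.

    Small, sharp cell bodies put substantial energy above the LR Nyquist
    frequency, so plain bicubic upsampling is a beatable baseline and the
    super-resolution task is non-degenerate at this patch size.
    """
    return synthesize_paired_samples(
        8, seed=seed, canvas_side=64, cell_count=80, cell_radius=(1.2, 2.5),
        blur_sigma=0.0, noise_sigma=0.003, texture_amplitude=0.15)


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Learning rate for a 1-based epoch (default: one halving after 200)."""
    if epoch < 1:
        raise InvalidInputError("epochs are 1-based")
    if config.lr_decay_every:
        halvings = (epoch - 1) // config.lr_decay_every
    else:
        halvings = 1 if epoch > config.lr_decay_epoch else 0
    return config.lr * config.lr_decay_factor ** halvings


@dataclass
class TrainState:
    epoch: int = 0
    global_step: int = 0
    current_lr: float = 0.0


class TrainingDiverged(RuntimeError):
    pass


def clip_grad_norm(params, max_norm: float) -> float:
    """Scale gradients so their global L2 norm is at most ``max_norm``."""
    grads = [p.grad for p in params if p.grad is not None]
    if not grads:
        return 0.0
    total = float(np.sqrt(sum(float((g * g).sum()) for g in grads)))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for g in grads:
            g *= scale
    return total


def stack_samples(samples: Sequence[PairedSample]) -> tuple[Tensor, Tensor]:
    """Batch HR and LR images into NCHW tensors."""
    hr = np.stack([s.hr.values.transpose(2, 0, 1) for s in samples])
    lr = np.stack([s.lr.values.transpose(2, 0, 1) for s in samples])
    return Tensor(hr), Tensor(lr)


class Trainer:
    """Owns the three networks, their optimizers and the RNG streams."""

    def __init__(self, config: TrainConfig,
                 dataset: Sequence[PairedSample] | None = None):
        self.config = config
        self.dataset = (list(dataset) if dataset is not None
                        else synthesize_paired_samples(
                            16, seed=config.seed, canvas_side=2 * config.hr_crop,
                            scale=config.scale))
        master = np.random.default_rng(config.seed)
        seeds = master.integers(0, 2 ** 31 - 1, size=4)
        self.generator = RDAGANGenerator(config.generator,
                                         np.random.default_rng(seeds[0]))
        self.disc_image = ImageDiscriminator(
            np.random.default_rng(seeds[1]), input_size=config.hr_crop,
            base_width=config.disc_base_width)
        need_vgg = config.feature_weight > 0 or config.feature_discriminator
        self.extractor = (VGGFeatureExtractor(config.extractor)
                          if need_vgg else None)
        self.disc_feature = (FeatureDiscriminator(
            np.random.default_rng(seeds[2]),
            in_channels=self.extractor.out_channels)
            if config.feature_discriminator else None)
        self.data_rng = np.random.default_rng(seeds[3])
        betas = (config.beta1, config.beta2)
        disc_lr = config.disc_lr if config.disc_lr is not None else config.lr
        self.opt_g = Adam(self.generator.parameters(), lr=config.lr, betas=betas)
        self.opt_di = Adam(self.disc_image.parameters(), lr=disc_lr,
                           betas=betas)
        self.opt_df = (Adam(self.disc_feature.parameters(), lr=disc_lr,
                            betas=betas)
                       if self.disc_feature is not None else None)
        self.state = TrainState(current_lr=config.lr)
        self.loss_log: list[dict] = []

    # -- one alternation ---------------------------------------------------

    def train_step(self, batch: Sequence[PairedSample],
                   pretrain: bool = False) -> LossBundle:
        """Di update, Df update, then generator update, on one batch."""
        cfg = self.config
        hr, lr = stack_samples(batch)
        self.generator.train()
        sr = self.generator(lr)                 # un-clipped during training
        sr_detached = sr.detach()

        # phase 1: image discriminator on detached SR
        self.disc_image.train()
        cdi_t = Tensor(np.zeros(()))
        if not pretrain:
            self.opt_di.zero_grad()
            d_real = self.disc_image(hr)
            d_fake = self.disc_image(sr_detached)
            cdi_t = discriminator_loss(d_real, d_fake)
            cdi_t.backward()
            if cfg.grad_clip:
                clip_grad_norm(self.disc_image.parameters(), cfg.grad_clip)
            self.opt_di.step()

        # phase 2: feature discriminator on frozen VGG features
        cdf_t = Tensor(np.zeros(()))
        if self.disc_feature is not None and not pretrain:
            self.opt_df.zero_grad()
            f_real = self.extractor(hr)
            f_fake = self.extractor(sr_detached)
            cdf_t = discriminator_loss(self.disc_feature(f_real),
                                       self.disc_feature(f_fake))
            cdf_t.backward()
            if cfg.grad_clip:
                clip_grad_norm(self.disc_feature.parameters(), cfg.grad_clip)
            self.opt_df.step()

        # phase 3: generator, with discriminators frozen (eval mode so even
        # their normalization statistics stay bitwise unchanged)
        self.opt_g.zero_grad()
        cp_t = perceptual_loss(sr, hr, self.extractor,
                               pixel_weight=cfg.pixel_weight,
                               feature_weight=cfg.feature_weight)
        cai_t = Tensor(np.zeros(()))
        caf_t = Tensor(np.zeros(()))
        if not pretrain:
            self.disc_image.eval()
            cai_t = adversarial_generator_loss(self.disc_image(sr))
            self.disc_image.train()
            if self.disc_feature is not None:
                self.disc_feature.eval()
                caf_t = adversarial_generator_loss(
                    self.disc_feature(self.extractor(sr)))
                self.disc_feature.train()
        cg_t = generator_total_loss(cp_t, cai_t, caf_t, cfg.lam,
                                    cfg.lambda_scope)
        cg_t.backward()
        if cfg.grad_clip:
            clip_grad_norm(self.generator.parameters(), cfg.grad_clip)
        self.opt_g.step()

        losses = bundle(cp_t, cai_t, caf_t, cdi_t, cdf_t, cfg.lam,
                        cfg.lambda_scope)
        if not np.isfinite([losses.cp, losses.cai, losses.caf, losses.cdi,
                            losses.cdf, losses.cg]).all():
            raise TrainingDiverged(
                f"non-finite loss at step {self.state.global_step}: {losses}; "
                f"batch provenance: {[s.provenance for s in batch]}")
        self.state.global_step += 1
        row = {"step": self.state.global_step, **losses.as_row(),
               "lr": self.state.current_lr}
        self.loss_log.append(row)
        return losses

    # -- data --------------------------------------------------------------

    def sample_batch(self) -> list[PairedSample]:
        idx = self.data_rng.integers(0, len(self.dataset),
                                     size=self.config.batch_size)
        batch = []
        for i in idx:
            s = paired_random_crop(self.dataset[int(i)], self.config.hr_crop,
                                   self.data_rng)
            batch.append(dihedral_augment(s, int(self.data_rng.integers(8))))
        return batch

    def _set_lr(self, lr: float) -> None:
        self.state.current_lr = lr
        self.opt_g.lr = lr
        base_disc = (self.config.disc_lr if self.config.disc_lr is not None
                     else self.config.lr)
        disc_lr = base_disc * (lr / self.config.lr)  # same decay factor
        self.opt_di.lr = disc_lr
        if self.opt_df is not None:
            self.opt_df.lr = disc_lr

    # -- epochs ------------------------------------------------------------

    def fit(self, out_dir: str | Path) -> Path:
        """Run the configured epochs; returns the final checkpoint path."""
        cfg = self.config
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        steps = cfg.steps_per_epoch or max(1, -(-len(self.dataset)
                                                // cfg.batch_size))
        while self.state.epoch < cfg.epochs:
            epoch = self.state.epoch + 1
            self._set_lr(lr_schedule(epoch, cfg))
            pretrain = epoch <= cfg.pretrain_epochs
            for _ in range(steps):
                self.train_step(self.sample_batch(), pretrain=pretrain)
            self.state.epoch = epoch
            if cfg.checkpoint_every and epoch % cfg.checkpoint_every == 0:
                self.save_checkpoint(out_dir / f"epoch{epoch:04d}.npz")
        final = out_dir / "final.npz"
        self.save_checkpoint(final)
        self.write_loss_log(out_dir / "losses.csv")
        return final

    def write_loss_log(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=LOG_COLUMNS)
            writer.writeheader()
            writer.writerows(self.loss_log)

    # -- persistence -------------------------------------------------------

    def save_checkpoint(self, path: str | Path) -> Path:
        path = Path(path)
        header = {
            "schema": CHECKPOINT_SCHEMA,
            "config": self.config.to_dict(),
            "config_hash": self.config.config_hash(),
            "epoch": self.state.epoch,
            "global_step": self.state.global_step,
            "current_lr": self.state.current_lr,
            "data_rng_state": self.data_rng.bit_generator.state,
            "seed": self.config.seed,
        }
        arrays = {"__header__": np.frombuffer(
            json.dumps(header, default=str).encode(), dtype=np.uint8)}
        for prefix, module in self._modules().items():
            for name, arr in module.state_dict().items():
                arrays[f"{prefix}/{name}"] = arr
        for prefix, opt in self._optimizers().items():
            st = opt.state_dict()
            arrays[f"{prefix}/t"] = np.array([st["t"]])
            for i, (m, v) in enumerate(zip(st["m"], st["v"])):
                arrays[f"{prefix}/m{i}"] = m
                arrays[f"{prefix}/v{i}"] = v
        np.savez(path, **arrays)
        return path

    def _modules(self) -> dict:
        mods = {"generator": self.generator, "disc_image": self.disc_image}
        if self.disc_feature is not None:
            mods["disc_feature"] = self.disc_feature
        return mods

    def _optimizers(self) -> dict:
        opts = {"opt_g": self.opt_g, "opt_di": self.opt_di}
        if self.opt_df is not None:
            opts["opt_df"] = self.opt_df
        return opts

    @classmethod
    def from_checkpoint(cls, path: str | Path,
                        dataset: Sequence[PairedSample] | None = None
                        ) -> "Trainer":
        header, arrays = read_checkpoint(path)
        config = TrainConfig.from_dict(header["config"])
        trainer = cls(config, dataset)
        for prefix, module in trainer._modules().items():
            state = {name[len(prefix) + 1:]: arr
                     for name, arr in arrays.items()
                     if name.startswith(prefix + "/")}
            module.load_state_dict(state)
        for prefix, opt in trainer._optimizers().items():
            n = len(opt.params)
            opt.load_state_dict({
                "t": int(arrays[f"{prefix}/t"][0]), "lr": header["current_lr"],
                "m": [arrays[f"{prefix}/m{i}"] for i in range(n)],
                "v": [arrays[f"{prefix}/v{i}"] for i in range(n)]})
        trainer.state = TrainState(epoch=int(header["epoch"]),
                                   global_step=int(header["global_step"]),
                                   current_lr=float(header["current_lr"]))
        trainer._set_lr(trainer.state.current_lr)
        rng_state = header["data_rng_state"]
        rng_state["state"] = {k: int(v) for k, v in rng_state["state"].items()}
        trainer.data_rng.bit_generator.state = rng_state
        return trainer


def read_checkpoint(path: str | Path) -> tuple[dict, dict]:
    """Header dict and raw arrays of a checkpoint; validates the schema."""
    with np.load(path) as archive:
        arrays = {k: archive[k] for k in archive.files}
    if "__header__" not in arrays:
        raise InvalidStateError(f"{path} is not a recognized checkpoint")
    header = json.loads(bytes(arrays.pop("__header__")).decode())
    if header.get("schema") != CHECKPOINT_SCHEMA:
        raise InvalidStateError(
            f"checkpoint schema {header.get('schema')!r} is not supported "
            f"(this build reads {CHECKPOINT_SCHEMA!r})")
    return header, arrays


def load_generator(path: str | Path) -> RDAGANGenerator:
    """Rebuild just the generator from a checkpoint."""
    header, arrays = read_checkpoint(path)
    spec = GeneratorSpec.from_dict(header["config"]["generator"])
    gen = RDAGANGenerator(spec, np.random.default_rng(0))
    state = {name[len("generator/"):]: arr for name, arr in arrays.items()
             if name.startswith("generator/")}
    gen.load_state_dict(state)
    gen.eval()
    return gen


def checkpoint_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def fit(config: TrainConfig, out_dir: str | Path,
        dataset: Sequence[PairedSample] | None = None,
        resume_from: str | Path | None = None) -> Path:
    """Train per ``config``; resumable from a saved checkpoint."""
    if resume_from is not None:
        trainer = Trainer.from_checkpoint(resume_from, dataset)
    else:
        trainer = Trainer(config, dataset)
    return trainer.fit(out_dir)


def infer(checkpoint: str | Path, input_dir: str | Path,
          output_dir: str | Path) -> list[Path]:
    """Upscale every PNG/TIFF in ``input_dir``; write ``*_sr.png`` + manifest."""
    from .data import IMAGE_SUFFIXES  # local import avoids a cycle at startup

    gen = load_generator(checkpoint)
    ck_hash = checkpoint_hash(checkpoint)
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    files = sorted(p for p in input_dir.iterdir()
                   if p.suffix.lower() in IMAGE_SUFFIXES)
    if not files:
        warnings.warn(f"no images found in {input_dir}", stacklevel=2)
    written = []
    manifest = output_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["input", "output", "checkpoint_hash"])
        for path in files:
            img = RasterImage.from_file(path)
            sr = RasterImage.from_tensor(gen(img.to_tensor()), clip=True)
            out_path = output_dir / f"{path.stem}_sr.png"
            sr.to_file(out_path)
            writer.writerow([path.name, out_path.name, ck_hash])
            written.append(out_path)
    return written
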