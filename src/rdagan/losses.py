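"""Loss terms for the adversarial super-resolution objective.

The generator minimizes

    C_g = C_p + λ (C_ai + C_af)

where C_p is the perceptual loss (pixel MSE plus MSE between frozen VGG
feature maps of SR and HR), C_ai = −log D_i(I_g) is the image-GAN term and
C_af = −log D_f(ϖ(I_g)) the feature-GAN term.  The discriminators minimize
the usual non-saturating cross-entropy

    C_d = −log D(real) − log(1 − D(fake)).

λ defaults to 10⁻³ and, per the stated reading of the composite objective,
scales BOTH adversarial terms; ``lambda_scope="image_only"`` keeps the
alternative reading.  Probabilities are clamped to [ε, 1−ε], ε = 1e-12,
before any logarithm, so all terms are finite even for saturated
discriminator outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .adversaries import VGGFeatureExtractor
from .errors import InvalidInputError
from .nn import functional as F
from .nn.tensor import Tensor, as_tensor

logger = logging.getLogger(__name__)

EPS = 1e-12
DEFAULT_LAMBDA = 1e-3


@dataclass
class LossBundle:
    """The five scalar loss terms, the adversarial weight and the composite."""

    cp: float
    cai: float
    caf: float
    cdi: float
    cdf: float
    lam: float
    cg: float

    def as_row(self) -> dict[str, float]:
        return {"Cp": self.cp, "Cai": self.cai, "Caf": self.caf,
                "Cg": self.cg, "Cdi": self.cdi, "Cdf": self.cdf}


_warned_clamp = False


def _safe_log(p: Tensor) -> Tensor:
    global _warned_clamp
    data = p.data
    if not _warned_clamp and (np.any(data <= EPS) or np.any(data >= 1.0 - EPS)):
        logger.warning("probability at the boundary clamped to [%g, %g] "
                       "(reported once)", EPS, 1.0 - EPS)
        _warned_clamp = True
    return F.log(F.clamp(p, EPS, 1.0 - EPS))


def mse(a: Tensor, b: Tensor) -> Tensor:
    if a.shape != b.shape:
        raise InvalidInputError(f"shape mismatch: {a.shape} vs {b.shape}")
    diff = a - b
    return (diff * diff).mean()


def perceptual_loss(sr: Tensor, hr: Tensor,
                    extractor: VGGFeatureExtractor | None,
                    pixel_weight: float = 1.0,
                    feature_weight: float = 1.0) -> Tensor:
    """Pixel MSE plus feature-space MSE at the extractor tap (batch mean)."""
    sr, hr = as_tensor(sr), as_tensor(hr)
    if sr.shape != hr.shape:
        raise InvalidInputError(
            f"sr/hr shape mismatch: {sr.shape} vs {hr.shape}")
    total = None
    if pixel_weight:
        total = mse(sr, hr) * pixel_weight
    if feature_weight and extractor is not None:
        feat = mse(extractor(sr), extractor(hr.detach())) * feature_weight
        total = feat if total is None else total + feat
    if total is None:
        total = Tensor(np.zeros((), dtype=np.float32))
    return total


def adversarial_generator_loss(d_fake: Tensor) -> Tensor:
    """Mean of −log D(fake): low when the discriminator is fooled."""
    return -(_safe_log(as_tensor(d_fake)).mean())


def discriminator_loss(d_real: Tensor, d_fake: Tensor) -> Tensor:
    """Mean of −log D(real) − log(1 − D(fake)); → 0 for a perfect D."""
    d_real, d_fake = as_tensor(d_real), as_tensor(d_fake)
    return -(_safe_log(d_real).mean()) - (_safe_log(1.0 - d_fake).mean())


def image_gan_losses(di_real, di_fake) -> tuple[Tensor, Tensor]:
    """(C_ai, C_di) from image-discriminator outputs on real/generated."""
    di_real, di_fake = as_tensor(di_real), as_tensor(di_fake)
    return (adversarial_generator_loss(di_fake),
            discriminator_loss(di_real, di_fake))


def feature_gan_losses(df_real, df_fake) -> tuple[Tensor, Tensor]:
    """(C_af, C_df); same functional form in the feature domain."""
    df_real, df_fake = as_tensor(df_real), as_tensor(df_fake)
    return (adversarial_generator_loss(df_fake),
            discriminator_loss(df_real, df_fake))


def generator_total_loss(cp, cai, caf, lam: float = DEFAULT_LAMBDA,
                         lambda_scope: str = "both"):
    """Composite generator objective.

    ``lambda_scope="both"`` (default): C_g = C_p + λ·(C_ai + C_af).
    ``lambda_scope="image_only"``:     C_g = C_p + λ·C_ai + C_af.
    """
    if lam < 0:
        raise InvalidInputError("lambda must be nonnegative")
    if lambda_scope == "both":
        return cp + lam * (cai + caf)
    if lambda_scope == "image_only":
        return cp + lam * cai + caf
    raise InvalidInputError(f"unknown lambda_scope {lambda_scope!r}")


def bundle(cp: Tensor, cai: Tensor, caf: Tensor, cdi: Tensor, cdf: Tensor,
           lam: float = DEFAULT_LAMBDA,
           lambda_scope: str = "both") -> LossBundle:
    """Collect scalar values of all terms plus the composite."""
    vals = {k: float(v.data) if isinstance(v, Tensor) else float(v)
            for k, v in dict(cp=cp, cai=cai, caf=caf, cdi=cdi, cdf=cdf).items()}
    cg = float(generator_total_loss(vals["cp"], vals["cai"], vals["caf"],
                                    lam, lambda_scope))
    return LossBundle(lam=lam, cg=cg, **vals)
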