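"""Stochastic view generation for contrastive pre-training and fine-tuning.

The chain mirrors OCT-appropriate photometric and geometric perturbations:
aspect-preserving random crops of 50-100% of the scan area resized to the
model resolution, horizontal flips (vertical flips are anatomically invalid
for retina), additive Gaussian noise with per-view parameters mu in
[-0.1, 0.15] and variance in [0, 0.2] clipped back to [0, 1], and additive
brightness / mean-anchored contrast jitter.  The order is fixed as
crop -> flip -> brightness/contrast -> noise so the noise model acts at the
final resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _skimage_resize

from .exceptions import ConfigurationError, DomainError

_INTERP_ORDER = {"nearest": 0, "bilinear": 1}


@dataclass
class AugmentationConfig:
    noise_mu_range: tuple[float, float] = (-0.1, 0.15)
    noise_var_range: tuple[float, float] = (0.0, 0.2)
    crop_area_range: tuple[float, float] = (0.5, 1.0)
    brightness_delta_range: tuple[float, float] = (-0.2, 0.2)
    contrast_factor_range: tuple[float, float] = (0.8, 1.2)
    hflip_prob: float = 0.5
    output_size: tuple[int, int] = (224, 224)
    interpolation: str = "bilinear"

    def validate(self) -> None:
        for name in (
            "noise_mu_range",
            "noise_var_range",
            "crop_area_range",
            "brightness_delta_range",
            "contrast_factor_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name}: lower bound {lo} exceeds upper {hi}")
        lo, hi = self.crop_area_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigurationError("crop_area_range must be within (0, 1]")
        if self.noise_var_range[0] < 0:
            raise ConfigurationError("noise variance cannot be negative")
        if not (0.0 <= self.hflip_prob <= 1.0):
            raise ConfigurationError("hflip_prob must be a probability")
        if self.interpolation not in _INTERP_ORDER:
            raise ConfigurationError(f"unknown interpolation {self.interpolation!r}")


def resize_image(image: np.ndarray, output_size: tuple[int, int],
                 interpolation: str = "bilinear") -> np.ndarray:
    """Deterministic resize to ``output_size`` with clipping back to [0, 1]."""
    if interpolation not in _INTERP_ORDER:
        raise DomainError(f"unknown interpolation {interpolation!r}")
    out = _skimage_resize(
        np.asarray(image, dtype=np.float64),
        output_size,
        order=_INTERP_ORDER[interpolation],
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return np.clip(out, 0.0, 1.0)


def add_gaussian_noise(image: np.ndarray, mu: float, var: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Per-pixel i.i.d. normal(mu, var) noise, clipped to [0, 1].

    ``var`` is a variance (the noise standard deviation is sqrt(var));
    ``var = 0`` degenerates to a constant shift by ``mu``.
    """
    if var < 0:
        raise DomainError(f"variance must be >= 0, got {var}")
    noise = mu + np.sqrt(var) * rng.standard_normal(np.shape(image))
    return np.clip(np.asarray(image, dtype=np.float64) + noise, 0.0, 1.0)


def random_crop_resize(
    image: np.ndarray,
    area_fraction: float,
    rng: np.random.Generator,
    output_size: tuple[int, int] = (224, 224),
    interpolation: str = "bilinear",
) -> np.ndarray:
    """Uniformly positioned aspect-preserving crop of the given area fraction.

    The window has the image's aspect ratio with side lengths
    ``round(H*sqrt(a))`` x ``round(W*sqrt(a))``, then is resized to
    ``output_size``.
    """
    if not (0.0 < area_fraction <= 1.0):
        raise DomainError(f"area_fraction must lie in (0, 1], got {area_fraction}")
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    scale = np.sqrt(area_fraction)
    ch, cw = int(round(h * scale)), int(round(w * scale))
    ch, cw = min(ch, h), min(cw, w)
    if ch < 2 or cw < 2:
        raise DomainError(f"crop window {ch}x{cw} smaller than 2x2")
    top = int(rng.integers(0, h - ch + 1))
    left = int(rng.integers(0, w - cw + 1))
    return resize_image(img[top : top + ch, left : left + cw], output_size, interpolation)


def adjust_brightness_contrast(image: np.ndarray, delta: float, factor: float) -> np.ndarray:
    """Contrast scaling about the image mean plus additive brightness.

    ``out = clip(factor * (image - m) + m + delta, 0, 1)`` with ``m`` the
    image mean, so constant images are unchanged by contrast and shifted by
    brightness alone.
    """
    if factor <= 0:
        raise DomainError(f"contrast factor must be > 0, got {factor}")
    img = np.asarray(image, dtype=np.float64)
    m = img.mean()
    return np.clip(factor * (img - m) + m + delta, 0.0, 1.0)


def hflip(image: np.ndarray) -> np.ndarray:
    """Horizontal (left-right) flip; an involution."""
    return np.asarray(image)[:, ::-1].copy()


def augment_view(image: np.ndarray, config: AugmentationConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """One stochastic view: crop -> flip -> brightness/contrast -> noise.

    Every per-view parameter is drawn uniformly from its config range; the
    output always has ``config.output_size`` and lies in [0, 1].
    """
    config.validate()
    area = float(rng.uniform(*config.crop_area_range))
    out = random_crop_resize(image, area, rng, config.output_size, config.interpolation)
    if rng.random() < config.hflip_prob:
        out = hflip(out)
    delta = float(rng.uniform(*config.brightness_delta_range))
    factor = float(rng.uniform(*config.contrast_factor_range))
    out = adjust_brightness_contrast(out, delta, factor)
    mu = float(rng.uniform(*config.noise_mu_range))
    var = float(rng.uniform(*config.noise_var_range))
    return add_gaussian_noise(out, mu, var, rng)
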