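"""Seeded two-class lesion-like image generator.

Real actinic keratoses (AK) differ from benign keratoses (BK) in surface
texture and in the erythema of the lesion: AK plaques sit on sun-damaged,
reddened skin and carry a finer "sandpaper" scale.  The generator emulates
exactly those two cues on a skin-toned background:

* additive band-limited texture — an oriented sinusoidal grating whose
  dominant spatial frequency is higher for the positive class, scaled by a
  ``separation`` knob in [0, 1];
* an elliptical central lesion whose hue shifts toward red (positive class)
  or toward yellow-brown (negative class) proportionally to ``separation``;
* i.i.d. Gaussian pixel noise, clipped to the 8-bit range.

At ``separation = 0`` the two class-conditional distributions coincide, so
no classifier can beat chance; at 1 the classes are far apart.  Every image
gets its own counter-derived random substream, so the dataset is a pure
function of the config and growing ``n_per_class`` never reshuffles earlier
images.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datasets import LabeledImageSet, Sample, write_manifest as _write_manifest

__all__ = ["SynthConfig", "generate_dataset", "write_manifest"]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic two-class dermoscopy-like dataset."""

    n_per_class: int = 200
    image_size: int = 64
    separation: float = 1.0
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ConfigurationError(f"n_per_class must be >= 1, got {self.n_per_class}")
        if self.image_size < 16:
            raise ConfigurationError(f"image_size must be >= 16, got {self.image_size}")
        if not 0.0 <= self.separation <= 1.0:
            raise ConfigurationError(f"separation must be in [0, 1], got {self.separation}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")


# background skin tone and signal scales, in 8-bit units
_BASE_COLOR = np.array([205.0, 172.0, 150.0])
_TEXTURE_AMPLITUDE = 18.0
_BASE_CYCLES = 3.0  # grating cycles per image side at separation 0
_EXTRA_CYCLES = 7.0  # additional cycles for the positive class at separation 1
# per-class lesion color shift at separation 1 (RGB); both vanish at separation 0
_LESION_SHIFT = {1: np.array([38.0, -18.0, -18.0]), 0: np.array([-12.0, 2.0, 14.0])}


def _render_image(cfg: SynthConfig, label: int, index: int) -> np.ndarray:
    # counter-style substream: one generator per (seed, class, image index)
    rng = np.random.default_rng([cfg.seed, label, index])
    n = cfg.image_size
    yy, xx = np.mgrid[0:n, 0:n].astype(float) / n

    img = np.tile(_BASE_COLOR, (n, n, 1))
    img += rng.normal(0.0, 5.0, size=3)  # per-image illumination jitter

    # oriented grating; positive class runs at higher spatial frequency
    cycles = _BASE_CYCLES + _EXTRA_CYCLES * cfg.separation * label
    theta = rng.uniform(0.0, np.pi)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    carrier = np.cos(2.0 * np.pi * cycles * (xx * np.cos(theta) + yy * np.sin(theta)) + phase)
    img += (_TEXTURE_AMPLITUDE * carrier)[:, :, None]

    # elliptical central lesion with class-dependent hue shift
    cx, cy = rng.uniform(0.4, 0.6, size=2)
    ax, ay = rng.uniform(0.18, 0.30, size=2)
    tilt = rng.uniform(0.0, np.pi)
    xr = (xx - cx) * np.cos(tilt) + (yy - cy) * np.sin(tilt)
    yr = -(xx - cx) * np.sin(tilt) + (yy - cy) * np.cos(tilt)
    r2 = (xr / ax) ** 2 + (yr / ay) ** 2
    mask = np.exp(-np.clip(r2, 0.0, 50.0))  # soft-edged ellipse
    img += mask[:, :, None] * (_LESION_SHIFT[label] * cfg.separation)
    img -= mask[:, :, None] * 25.0  # lesions are darker than surrounding skin

    if cfg.noise_sd > 0:
        img += rng.normal(0.0, cfg.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_dataset(config: SynthConfig) -> LabeledImageSet:
    """Render ``2 * n_per_class`` images, negatives (bkl-like) first.

    Deterministic: identical config (including seed) yields bit-identical
    pixel arrays.
    """
    samples = []
    for label, tag in ((0, "bkl"), (1, "akiec")):
        for i in range(config.n_per_class):
            samples.append(
                Sample(f"syn_{tag}_{i:05d}", _render_image(config, label, i), label)
            )
    return LabeledImageSet(samples)


def write_manifest(dataset: LabeledImageSet, directory: str | Path) -> Path:
    """Write PNGs plus a HAM10000-dialect ``image_id,dx`` manifest."""
    return _write_manifest(dataset, directory)
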