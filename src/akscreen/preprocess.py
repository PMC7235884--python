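"""Image preprocessing chain: augmentation, equalization, Lab conversion, resize.

The fixed pipeline order is augment -> histogram equalization -> RGB->CIELAB
-> standardize to the network's 64 x 64 x 3 input in [0, 1].  Every operation
here is deterministic; the only augmentations used are the 90-degree
rotation, horizontal flip and vertical flip (the original image is kept, so
each augmented source contributes exactly 4 samples).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from skimage import color as _skcolor
from skimage.transform import resize as _skresize
from sklearn.base import BaseEstimator, TransformerMixin

from .datasets import LabeledImageSet, Sample, _check_rgb8

__all__ = [
    "PreprocessPlan",
    "augment_set",
    "augment_image",
    "equalize_histogram",
    "rgb_to_lab",
    "lab_to_rgb",
    "standardize_to_input",
    "ImageStandardizer",
    "AUGMENT_SUFFIXES",
    "base_image_id",
]

EqualizationMode = Literal["per_channel_rgb", "luminance_only"]

#: derived-identifier suffixes, in output order after the original
AUGMENT_SUFFIXES = ("__rot90", "__hflip", "__vflip")


@dataclass(frozen=True)
class PreprocessPlan:
    """Configuration of the deterministic preprocessing chain.

    ``augment_minority_only`` expands only the class with the strictly
    smaller count (a no-op on exactly balanced data); otherwise every sample
    is augmented.  ``equalization_mode`` selects whether the CDF remap acts
    on each RGB channel independently or on a luma channel with
    proportionally rescaled chroma.  ``color_space`` selects the tensor the
    classifier consumes: CIELAB (training default) or plain RGB.
    """

    augment_minority_only: bool = True
    include_originals: bool = True
    equalization_mode: EqualizationMode = "per_channel_rgb"
    color_space: Literal["lab", "rgb"] = "lab"
    target_size: int = 64

    def __post_init__(self) -> None:
        if self.equalization_mode not in ("per_channel_rgb", "luminance_only"):
            raise ValueError(f"unknown equalization_mode {self.equalization_mode!r}")
        if self.color_space not in ("lab", "rgb"):
            raise ValueError(f"unknown color_space {self.color_space!r}")
        if self.target_size < 1:
            raise ValueError("target_size must be positive")


# ---------------------------------------------------------------------------
# augmentation

def augment_image(pixels: np.ndarray) -> list[np.ndarray]:
    """Original plus its 90-degree rotation, horizontal flip, vertical flip."""
    _check_rgb8(pixels, "<augment input>")
    return [
        pixels,
        np.ascontiguousarray(np.rot90(pixels)),
        np.ascontiguousarray(pixels[:, ::-1]),  # mirror about the vertical axis
        np.ascontiguousarray(pixels[::-1, :]),  # mirror about the horizontal axis
    ]


def augment_set(dataset: LabeledImageSet, plan: PreprocessPlan | None = None) -> LabeledImageSet:
    """Expand the selected class 4-fold (original + 3 transforms).

    Sources appear in input order, each immediately followed by its
    derivatives; derived identifiers get deterministic suffixes so augmented
    samples can always be traced back to their source image (used by the
    cross-validation harness to prove the absence of train/test leakage).
    """
    if len(dataset) == 0:
        raise ValueError("cannot augment an empty dataset")
    plan = plan or PreprocessPlan()
    if plan.augment_minority_only:
        n_neg, n_pos = dataset.class_counts()
        if n_pos < n_neg:
            selected = {1}
        elif n_neg < n_pos:
            selected = {0}
        else:  # balanced: no minority to expand
            selected = set()
    else:
        selected = {0, 1}

    out: list[Sample] = []
    for s in dataset:
        if s.label not in selected:
            out.append(s)
            continue
        variants = augment_image(s.pixels)
        if plan.include_originals:
            out.append(s)
        for suffix, img in zip(AUGMENT_SUFFIXES, variants[1:]):
            out.append(Sample(s.image_id + suffix, img, s.label))
    return LabeledImageSet(out)


def base_image_id(image_id: str) -> str:
    """Source identifier of a (possibly augmented) sample."""
    for suffix in AUGMENT_SUFFIXES:
        if image_id.endswith(suffix):
            return image_id[: -len(suffix)]
    return image_id


# ---------------------------------------------------------------------------
# histogram equalization

def _equalize_channel(channel: np.ndarray) -> np.ndarray:
    # classic CDF remap: round((cdf(v) - cdf_min) / (n - cdf_min) * 255),
    # which maps an already-uniform histogram exactly onto itself
    hist = np.bincount(channel.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    cdf_min = cdf[np.nonzero(hist)[0][0]]
    n = channel.size
    if n == cdf_min:  # constant image: leave untouched
        return channel.copy()
    lut = np.rint((cdf - cdf_min) / (n - cdf_min) * 255.0)
    lut = np.clip(lut, 0, 255).astype(np.uint8)
    return lut[channel]


def equalize_histogram(image: np.ndarray, mode: EqualizationMode = "per_channel_rgb") -> np.ndarray:
    """Cumulative-distribution histogram equalization of an 8-bit image.

    ``per_channel_rgb`` equalizes each channel independently;
    ``luminance_only`` equalizes the Rec.601 luma and rescales all channels
    by the per-pixel luma gain, preserving chromaticity.
    """
    if not isinstance(image, np.ndarray) or image.dtype != np.uint8:
        raise TypeError("equalize_histogram requires an 8-bit (uint8) image")
    if image.ndim == 2:
        return _equalize_channel(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise TypeError(f"expected H x W or H x W x 3 image, got shape {image.shape}")
    if mode == "per_channel_rgb":
        return np.stack([_equalize_channel(image[:, :, c]) for c in range(3)], axis=2)
    if mode == "luminance_only":
        fimg = image.astype(np.float64)
        luma = 0.299 * fimg[:, :, 0] + 0.587 * fimg[:, :, 1] + 0.114 * fimg[:, :, 2]
        luma8 = np.clip(np.floor(luma + 0.5), 0, 255).astype(np.uint8)
        eq = _equalize_channel(luma8).astype(np.float64)
        gain = np.where(luma > 0, eq / np.maximum(luma, 1e-12), 0.0)
        out = fimg * gain[:, :, None]
        return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)
    raise ValueError(f"unknown equalization mode {mode!r}")


# ---------------------------------------------------------------------------
# color space

def rgb_to_lab(image: np.ndarray) -> np.ndarray:
    """8-bit sRGB -> CIELAB (D65), float64; L in [0, 100]."""
    if not isinstance(image, np.ndarray) or image.dtype != np.uint8:
        raise TypeError("rgb_to_lab requires an 8-bit (uint8) sRGB image")
    if image.ndim != 3 or image.shape[2] != 3:
        raise TypeError(f"expected H x W x 3 image, got shape {image.shape}")
    return _skcolor.rgb2lab(image.astype(np.float64) / 255.0)


def lab_to_rgb(image: np.ndarray) -> np.ndarray:
    """CIELAB -> 8-bit sRGB (in-gamut values; out-of-gamut colors are clipped)."""
    rgb = _skcolor.lab2rgb(image)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# standardization to the network input

def standardize_to_input(image: np.ndarray, plan: PreprocessPlan | None = None) -> np.ndarray:
    """Resize to target_size^2 x 3 (bilinear) and rescale channels to [0, 1].

    Lab channels map through fixed affine ranges (L/100, (a+128)/255,
    (b+128)/255); RGB maps through v/255.  The input is a Lab float image
    when the plan says ``lab``, an 8-bit RGB image when it says ``rgb``.
    """
    plan = plan or PreprocessPlan()
    if image.ndim != 3 or image.shape[2] != 3:
        raise TypeError(f"expected H x W x 3 image, got shape {image.shape}")
    img = image.astype(np.float64)
    t = plan.target_size
    if img.shape[:2] != (t, t):
        img = _skresize(img, (t, t), order=1, mode="edge", anti_aliasing=False,
                        preserve_range=True)
    if plan.color_space == "lab":
        out = np.empty_like(img)
        out[:, :, 0] = img[:, :, 0] / 100.0
        out[:, :, 1] = (img[:, :, 1] + 128.0) / 255.0
        out[:, :, 2] = (img[:, :, 2] + 128.0) / 255.0
    else:
        out = img / 255.0
    return np.clip(out, 0.0, 1.0)


class ImageStandardizer(BaseEstimator, TransformerMixin):
    """Sklearn transformer: 8-bit RGB images -> standardized float tensors.

    Applies the deterministic tail of the preprocessing chain (equalization
    -> optional Lab conversion -> bilinear resize -> [0, 1] scaling) to each
    image.  Augmentation changes the number of samples and therefore lives
    outside the transformer, in :func:`augment_set` and the cross-validation
    harness.

    Parameters
    ----------
    equalization : {"per_channel_rgb", "luminance_only", None}
        Histogram-equalization mode; None skips equalization.
    color_space : {"lab", "rgb"}
        Channel encoding fed to the classifier.
    target_size : int
        Side length of the square output.
    """

    def __init__(self, equalization: str | None = "per_channel_rgb",
                 color_space: str = "lab", target_size: int = 64):
        self.equalization = equalization
        self.color_space = color_space
        self.target_size = target_size

    def fit(self, X, y=None):  # stateless
        self._plan()  # validate parameters early
        return self

    def transform(self, X) -> np.ndarray:
        plan = self._plan()
        out = np.empty((len(X), self.target_size, self.target_size, 3), dtype=np.float32)
        for i, img in enumerate(X):
            img = np.asarray(img)
            _check_rgb8(img, f"<sample {i}>")
            if self.equalization is not None:
                img = equalize_histogram(img, self.equalization)
            work = rgb_to_lab(img) if self.color_space == "lab" else img
            out[i] = standardize_to_input(work, plan)
        return out

    def _plan(self) -> PreprocessPlan:
        if self.equalization not in ("per_channel_rgb", "luminance_only", None):
            raise ValueError(f"unknown equalization {self.equalization!r}")
        return PreprocessPlan(equalization_mode=self.equalization or "per_channel_rgb",
                              color_space=self.color_space, target_size=self.target_size)
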