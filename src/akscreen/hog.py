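"""Histogram-of-oriented-gradients descriptor with the study geometry.

The classical pipeline resizes each lesion image to 200 x 200, converts to
grayscale, and pools gradient orientations into 32 x 32-pixel cells.  With
floor tiling that yields 6 x 6 whole cells (an 8-pixel margin on the right
and bottom is excluded), and 2 x 2-cell blocks at 1-cell stride give
5 x 5 = 25 block positions; 25 blocks x 4 cells x 9 unsigned orientation
bins = a 900-dimensional descriptor.

Conventions, fixed so the descriptor is bit-reproducible:

* grayscale = Rec.601 luma (0.299 R + 0.587 G + 0.114 B), rounded half up;
* central-difference gradients with replicated borders (one-sided at edges);
* unsigned orientations (mod 180 degrees), magnitude split linearly between
  the two nearest bin centers (centers at (k + 1/2) * 20 degrees, wrapping);
* block vectors L2-normalized as v / sqrt(|v|^2 + eps^2), eps = 1e-6, so a
  constant image maps to the zero descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _skresize
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["HOGConfig", "to_grayscale", "hog_descriptor", "HOGFeaturizer",
           "descriptor_length"]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class HOGConfig:
    """Descriptor geometry; defaults give the 900-dimensional layout."""

    resize_to: int = 200
    cell_size: int = 32
    block_cells: int = 2  # block side, in cells
    block_stride: int = 1  # block step, in cells
    orientation_bins: int = 9  # unsigned, spanning 0-180 degrees
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.cell_size < 1 or self.resize_to < self.cell_size:
            raise ConfigurationError(
                f"cell_size {self.cell_size} must fit inside resize_to {self.resize_to}")
        if self.block_cells < 1 or self.block_stride < 1:
            raise ConfigurationError("block_cells and block_stride must be >= 1")
        if self.cells_per_axis < self.block_cells:
            raise ConfigurationError("image too small for a single block")
        if self.orientation_bins < 2:
            raise ConfigurationError("need at least 2 orientation bins")

    @property
    def cells_per_axis(self) -> int:
        return self.resize_to // self.cell_size

    @property
    def blocks_per_axis(self) -> int:
        return (self.cells_per_axis - self.block_cells) // self.block_stride + 1

    @property
    def length(self) -> int:
        return (self.blocks_per_axis ** 2) * (self.block_cells ** 2) * self.orientation_bins


def descriptor_length(config: HOGConfig | None = None) -> int:
    return (config or HOGConfig()).length


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Rec.601 luma of an 8-bit RGB image, rounded half up to uint8."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise TypeError(f"expected H x W x 3 image, got shape {image.shape}")
    img = image.astype(np.float64)
    luma = 0.299 * img[:, :, 0] + 0.587 * img[:, :, 1] + 0.114 * img[:, :, 2]
    return np.clip(np.floor(luma + 0.5), 0, 255).astype(np.uint8)


def _gradients(gray: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central differences, one-sided at borders (np.gradient convention)."""
    g = gray.astype(np.float64)
    gy, gx = np.gradient(g)
    return gx, gy


def cell_histograms(gray: np.ndarray, config: HOGConfig) -> np.ndarray:
    """(cells_y, cells_x, bins) orientation histograms of a grayscale image."""
    cfg = config
    nc = cfg.cells_per_axis
    extent = nc * cfg.cell_size
    gx, gy = _gradients(gray)
    gx, gy = gx[:extent, :extent], gy[:extent, :extent]
    mag = np.hypot(gx, gy)
    ang = np.degrees(np.arctan2(gy, gx)) % 180.0

    bw = 180.0 / cfg.orientation_bins
    pos = ang / bw - 0.5  # bin centers at (k + 1/2) * bw
    lo = np.floor(pos).astype(np.int64)
    w_hi = pos - lo
    lo_bin = lo % cfg.orientation_bins
    hi_bin = (lo + 1) % cfg.orientation_bins

    rows, cols = np.indices(mag.shape)
    cell_idx = (rows // cfg.cell_size) * nc + (cols // cfg.cell_size)
    nbins = cfg.orientation_bins
    hist = np.zeros(nc * nc * nbins)
    np.add.at(hist, cell_idx.ravel() * nbins + lo_bin.ravel(), (mag * (1 - w_hi)).ravel())
    np.add.at(hist, cell_idx.ravel() * nbins + hi_bin.ravel(), (mag * w_hi).ravel())
    return hist.reshape(nc, nc, nbins)


def hog_descriptor(image: np.ndarray, config: HOGConfig | None = None) -> np.ndarray:
    """Descriptor of one color image: resize, grayscale, cells, blocks."""
    cfg = config or HOGConfig()
    if image.ndim != 3 or image.shape[2] != 3:
        raise TypeError(f"expected H x W x 3 image, got shape {image.shape}")
    img = image.astype(np.float64)
    if img.shape[:2] != (cfg.resize_to, cfg.resize_to):
        img = _skresize(img, (cfg.resize_to, cfg.resize_to), order=1, mode="edge",
                        anti_aliasing=False, preserve_range=True)
    gray = to_grayscale(np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8))
    hist = cell_histograms(gray, cfg)

    out = []
    nb, bc, stride = cfg.blocks_per_axis, cfg.block_cells, cfg.block_stride
    for by in range(nb):
        for bx in range(nb):
            block = hist[by * stride: by * stride + bc,
                         bx * stride: bx * stride + bc, :].ravel()
            out.append(block / np.sqrt(np.sum(block ** 2) + cfg.epsilon ** 2))
    return np.concatenate(out)


class HOGFeaturizer(BaseEstimator, TransformerMixin):
    """Sklearn transformer: 8-bit RGB images -> HOG feature matrix.

    Stateless; ``transform`` maps a list/array of images to an
    (n, descriptor_length) float matrix whose row order matches the input.
    By default the descriptor is computed on the original image, independent
    of the CNN's equalization/Lab chain.
    """

    def __init__(self, resize_to: int = 200, cell_size: int = 32,
                 block_cells: int = 2, block_stride: int = 1,
                 orientation_bins: int = 9, epsilon: float = 1e-6):
        self.resize_to = resize_to
        self.cell_size = cell_size
        self.block_cells = block_cells
        self.block_stride = block_stride
        self.orientation_bins = orientation_bins
        self.epsilon = epsilon

    def _config(self) -> HOGConfig:
        return HOGConfig(resize_to=self.resize_to, cell_size=self.cell_size,
                         block_cells=self.block_cells, block_stride=self.block_stride,
                         orientation_bins=self.orientation_bins, epsilon=self.epsilon)

    def fit(self, X, y=None):
        self._config()  # validate
        return self

    def transform(self, X) -> np.ndarray:
        cfg = self._config()
        rows = [hog_descriptor(np.asarray(img), cfg) for img in X]
        out = np.asarray(rows)
        if not np.isfinite(out).all():
            raise ValueError("non-finite entries in the feature matrix")
        return out
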