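"""Labeled dermoscopy image collections and HAM10000-dialect manifest I/O.

The binary task throughout the package is actinic keratosis (AK, diagnosis
code ``akiec``, the positive class) versus benign keratosis (BK, code
``bkl``, the negative class).  A dataset is an ordered list of
``(image_id, pixels, label)`` samples; pixels are 8-bit RGB arrays laid out
height x width x channel.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from PIL import Image

#: diagnosis-code -> binary label mapping; any other code is dropped on load
DX_TO_LABEL = {"akiec": 1, "bkl": 0}
LABEL_TO_DX = {1: "akiec", 0: "bkl"}


class ManifestFormatError(ValueError):
    """The manifest CSV violates the expected HAM10000-metadata dialect."""


class EmptyDatasetError(ValueError):
    """No samples survived loading/filtering."""


@dataclass(frozen=True)
class Sample:
    image_id: str
    pixels: np.ndarray  # H x W x 3, uint8
    label: int  # 1 = AK, 0 = BK


@dataclass
class LabeledImageSet:
    """Ordered collection of 8-bit RGB images with binary labels."""

    samples: list[Sample] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.image_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate image_id(s): {dupes[:5]}")
        for s in self.samples:
            _check_rgb8(s.pixels, s.image_id)
            if s.label not in (0, 1):
                raise ValueError(f"label of {s.image_id!r} must be 0 or 1, got {s.label}")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[Sample]:
        return iter(self.samples)

    @property
    def image_ids(self) -> list[str]:
        return [s.image_id for s in self.samples]

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=np.int64)

    @property
    def images(self) -> list[np.ndarray]:
        return [s.pixels for s in self.samples]

    def stacked_images(self) -> np.ndarray:
        """All images as one (n, H, W, 3) uint8 array; requires uniform size."""
        shapes = {s.pixels.shape for s in self.samples}
        if len(shapes) > 1:
            raise ValueError(f"images have mixed shapes {sorted(shapes)}; cannot stack")
        return np.stack([s.pixels for s in self.samples])

    def subset(self, indices: Sequence[int]) -> "LabeledImageSet":
        return LabeledImageSet([self.samples[int(i)] for i in indices])

    def class_counts(self) -> tuple[int, int]:
        """(n_negative, n_positive)."""
        y = self.labels
        return int(np.sum(y == 0)), int(np.sum(y == 1))


def _check_rgb8(pixels: np.ndarray, image_id: str) -> None:
    if not isinstance(pixels, np.ndarray) or pixels.dtype != np.uint8:
        raise TypeError(f"image {image_id!r} must be a uint8 array")
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise TypeError(
            f"image {image_id!r} must be H x W x 3 (got shape {pixels.shape}); "
            "grayscale or alpha-channel inputs are rejected, not coerced"
        )


def load_manifest(manifest: str | Path, image_dir: str | Path) -> LabeledImageSet:
    """Load a ``image_id,dx`` CSV manifest plus its image files.

    Keeps only rows with dx in {akiec, bkl} (akiec -> 1, bkl -> 0) in manifest
    row order; every other diagnosis code (nv, mel, bcc, ...) is dropped.
    """
    manifest = Path(manifest)
    image_dir = Path(image_dir)
    with open(manifest, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        cols = reader.fieldnames or []
        for required in ("image_id", "dx"):
            if required not in cols:
                raise ManifestFormatError(
                    f"manifest {manifest} lacks required column {required!r} (has {cols})"
                )
        rows = [(row["image_id"], row["dx"]) for row in reader]

    seen: set[str] = set()
    samples: list[Sample] = []
    for image_id, dx in rows:
        if dx not in DX_TO_LABEL:
            continue
        if image_id in seen:
            raise ManifestFormatError(f"duplicate image_id {image_id!r} in manifest")
        seen.add(image_id)
        path = _find_image(image_dir, image_id)
        if path is None:
            raise IOError(f"image file for image_id {image_id!r} not found under {image_dir}")
        with Image.open(path) as img:
            pixels = np.asarray(img.convert("RGB"), dtype=np.uint8)
        samples.append(Sample(image_id, pixels, DX_TO_LABEL[dx]))
    if not samples:
        raise EmptyDatasetError(
            f"no rows of {manifest} carry a keratosis diagnosis code ({sorted(DX_TO_LABEL)})"
        )
    return LabeledImageSet(samples)


def _find_image(image_dir: Path, image_id: str) -> Path | None:
    for ext in (".png", ".jpg", ".jpeg", ".PNG", ".JPG", ".JPEG"):
        candidate = image_dir / f"{image_id}{ext}"
        if candidate.exists():
            return candidate
    return None


def write_manifest(dataset: LabeledImageSet, directory: str | Path) -> Path:
    """Write one PNG per sample plus a ``image_id,dx`` CSV manifest.

    Returns the manifest path.  Refuses to write a rowless manifest.
    """
    if len(dataset) == 0:
        raise EmptyDatasetError("refusing to write a manifest with zero rows")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for s in dataset:
        Image.fromarray(s.pixels).save(directory / f"{s.image_id}.png")
    manifest = directory / "metadata.csv"
    with open(manifest, "w", newline="\n", encoding="utf-8") as fh:
        fh.write("image_id,dx\n")
        for s in dataset:
            fh.write(f"{s.image_id},{LABEL_TO_DX[s.label]}\n")
    return manifest
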