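"""Pixel datasets and label-stratified partitions.

The validation procedure never uses spatial information: an image and a
candidate binary mask are flattened (row-major, top-left origin) into a
dataset of ``N`` records, each pairing an RGB intensity triple with the
binary label the segmentation assigned to that pixel.  The dataset is
then partitioned into ``M`` mutually disjoint subsets whose foreground
proportion matches the whole image as tightly as integer arithmetic
allows.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .exceptions import (
    DimensionMismatchError,
    ImageFormatError,
    StratificationError,
)

__all__ = [
    "RGBImage",
    "BinaryMask",
    "PixelDataset",
    "Partition",
    "load_rgb_image",
    "load_binary_mask",
    "build_pixel_dataset",
    "stratified_partition",
]


@dataclass(frozen=True)
class RGBImage:
    """An RGB raster with channel intensities scaled to [0, 1].

    ``values`` has shape ``(height, width, 3)``.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[2] != 3:
            raise ImageFormatError(
                f"RGBImage needs shape (H, W, 3), got {v.shape}"
            )
        if v.size == 0:
            raise ImageFormatError("empty image")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ImageFormatError("RGB intensities must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.height * self.width


@dataclass(frozen=True)
class BinaryMask:
    """A binary label raster; 1 marks foreground, shape ``(height, width)``."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.size == 0:
            raise ImageFormatError(f"BinaryMask needs shape (H, W), got {v.shape}")
        u = np.unique(v)
        if not np.isin(u, [0, 1]).all():
            raise ImageFormatError("mask values must be 0 or 1")
        object.__setattr__(self, "values", v.astype(np.uint8))

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def foreground_fraction(self) -> float:
        return float(self.values.mean())


@dataclass(frozen=True)
class PixelDataset:
    """``N`` (RGB triple, binary label) records in one fixed pixel order.

    Record ``i`` corresponds to pixel ``i`` of the source image and mask
    under row-major, 0-based ordering.  No deduplication is performed:
    identical RGB triples stay as separate records.
    """

    features: np.ndarray  # (N, 3) float in [0, 1]
    labels: np.ndarray    # (N,) uint8 in {0, 1}

    def __post_init__(self) -> None:
        f = np.asarray(self.features, dtype=float)
        y = np.asarray(self.labels, dtype=np.uint8)
        if f.ndim != 2 or f.shape[1] != 3:
            raise ImageFormatError("features must have shape (N, 3)")
        if y.shape != (f.shape[0],):
            raise DimensionMismatchError(
                f"{f.shape[0]} feature rows vs {y.shape[0]} labels"
            )
        object.__setattr__(self, "features", f)
        object.__setattr__(self, "labels", y)

    @property
    def n(self) -> int:
        return self.features.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pixel_index": np.arange(self.n),
                "R": self.features[:, 0],
                "G": self.features[:, 1],
                "B": self.features[:, 2],
                "label": self.labels,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        """Debug export: pixel_index,R,G,B,label."""
        self.to_dataframe().to_csv(path, index=False)


@dataclass(frozen=True)
class Partition:
    """``M`` disjoint, label-stratified index subsets covering a dataset."""

    subsets: tuple
    n_total: int

    def __post_init__(self) -> None:
        subsets = tuple(np.asarray(s, dtype=np.intp) for s in self.subsets)
        object.__setattr__(self, "subsets", subsets)

    @property
    def M(self) -> int:
        return len(self.subsets)

    @property
    def n(self) -> int:
        """Nominal subset cardinality, ``N // M``."""
        return self.n_total // self.M

    def sizes(self) -> list[int]:
        return [len(s) for s in self.subsets]


def _rescale(raw: np.ndarray, path: str | Path) -> np.ndarray:
    if raw.dtype == np.uint8:
        return raw / 255.0
    if raw.dtype == np.uint16:
        return raw / 65535.0
    if np.issubdtype(raw.dtype, np.floating):
        if raw.size and (raw.min() < 0.0 or raw.max() > 1.0):
            raise ImageFormatError(
                f"{path}: float raster outside [0, 1]; cannot infer bit depth"
            )
        return raw.astype(float)
    raise ImageFormatError(f"{path}: unsupported dtype {raw.dtype}")


def load_rgb_image(path: str | Path) -> RGBImage:
    """Read a PNG/TIFF raster as an :class:`RGBImage`.

    Intensities are rescaled to [0, 1] by the bit-depth maximum
    (255 for 8-bit, 65535 for 16-bit).
    """
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - decoding backends vary
        raise ImageFormatError(f"cannot decode image {path}: {exc}") from exc
    if raw.ndim != 3 or raw.shape[2] != 3:
        got = 1 if raw.ndim == 2 else raw.shape[2]
        raise ImageFormatError(
            f"{path}: expected 3 channels, got {got}"
        )
    return RGBImage(_rescale(raw, path))


def load_binary_mask(path: str | Path) -> BinaryMask:
    """Read a mask raster; nonzero pixels become foreground (1).

    A 3-channel mask is accepted only when all channels agree per pixel.
    """
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise ImageFormatError(f"cannot decode mask {path}: {exc}") from exc
    if raw.ndim == 3:
        if raw.shape[2] != 3:
            raise ImageFormatError(
                f"{path}: masks must be 1- or 3-channel, got {raw.shape[2]}"
            )
        if not ((raw[..., 0] == raw[..., 1]) & (raw[..., 1] == raw[..., 2])).all():
            raise ImageFormatError(f"{path}: ambiguous mask pixel (channels disagree)")
        raw = raw[..., 0]
    elif raw.ndim != 2:
        raise ImageFormatError(f"{path}: masks must be 2-D rasters")
    return BinaryMask((raw != 0).astype(np.uint8))


def build_pixel_dataset(image: RGBImage, mask: BinaryMask) -> PixelDataset:
    """Join an image with a candidate mask into the validation dataset."""
    if (image.height, image.width) != (mask.height, mask.width):
        raise DimensionMismatchError(
            f"image {image.height}x{image.width} vs mask {mask.height}x{mask.width}"
        )
    features = image.values.reshape(-1, 3)
    labels = mask.values.reshape(-1)
    return PixelDataset(features, labels)


def stratified_partition(
    data: PixelDataset,
    M: int,
    seed: int | np.random.Generator,
) -> Partition:
    """Split the dataset into ``M`` disjoint subsets stratified by label.

    Each label class is shuffled and dealt round-robin across the
    subsets, so every subset's foreground proportion matches the global
    one to within the integer-rounding bound.  The background deal is
    offset by the foreground remainder so subset sizes differ by at
    most one.  Deterministic given the seed.
    """
    if M < 1:
        raise StratificationError("M must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    members: list[list[np.ndarray]] = [[] for _ in range(M)]
    offset = 0
    # foreground first so its remainder sets the background deal offset
    for cls in (1, 0):
        idx = np.flatnonzero(data.labels == cls)
        if len(idx) < M:
            raise StratificationError(
                f"cannot stratify: label class {cls} has {len(idx)} members < M={M}"
            )
        idx = rng.permutation(idx)
        for j in range(M):
            members[(j + offset) % M].append(idx[j::M])
        offset += len(idx) % M
    subsets = tuple(np.sort(np.concatenate(parts)) for parts in members)
    return Partition(subsets, data.n)
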