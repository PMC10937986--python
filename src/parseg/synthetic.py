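"""Synthetic seed-like scenes with known ground truth.

Generates RGB images of elliptical "seeds" on a dark background, with
class-conditional Gaussian colors plus pixel noise — the simplest
model under which the RGB triple carries all the label information,
matching the working assumption of the validation procedure that the
color-to-label pattern is identical everywhere in the image.  Candidate
masks of controllable quality are produced by corrupting the truth
with independent per-pixel label flips and optional boundary dilation
(systematic over-segmentation).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.morphology import dilation, disk

from ._rng import substream
from .exceptions import ParsegError
from .pixel_data import BinaryMask, RGBImage

__all__ = [
    "SceneSpec",
    "CorruptionSpec",
    "generate_scene",
    "corrupt_mask",
    "write_fixture",
]


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic seed scene.

    Defaults emulate a capture of a few dozen seeds on a dark board:
    a 256x256 frame, 12 ellipses with 10-20 px semi-axes (foreground
    fraction around 0.1-0.2), warm yellow-brown seed color against a
    near-black background with well-separated channel means, and mild
    per-pixel noise.
    """

    height: int = 256
    width: int = 256
    n_objects: int = 12
    axis_range: tuple = (10, 20)
    fg_color_mean: tuple = (0.75, 0.62, 0.25)
    fg_color_sd: float = 0.05
    bg_color_mean: tuple = (0.08, 0.08, 0.10)
    bg_color_sd: float = 0.03
    pixel_noise_sd: float = 0.02
    seed: int = 0


@dataclass(frozen=True)
class CorruptionSpec:
    """Label-flip corruption of a mask.

    ``flip_01``: probability a background pixel flips to foreground;
    ``flip_10``: probability a foreground pixel flips to background;
    ``boundary_dilate``: disc radius of systematic over-segmentation
    applied before the flips.
    """

    flip_01: float = 0.0
    flip_10: float = 0.0
    boundary_dilate: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("flip_01", "flip_10"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ParsegError(f"{name}={p} outside [0, 1]")
        if self.boundary_dilate < 0:
            raise ParsegError("boundary_dilate must be >= 0")


def _rasterize_ellipses(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.height, spec.width
    mask = np.zeros((h, w), dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    a_lo, a_hi = spec.axis_range
    if a_hi >= min(h, w) / 2:
        raise ParsegError("axis range too large for the frame")
    for _ in range(spec.n_objects):
        a = rng.uniform(a_lo, a_hi)
        b = rng.uniform(a_lo, a_hi)
        margin = max(a, b) + 1
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        theta = rng.uniform(0, np.pi)
        c, s = np.cos(theta), np.sin(theta)
        u = (xx - cx) * c + (yy - cy) * s
        v = -(xx - cx) * s + (yy - cy) * c
        mask |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask


def generate_scene(spec: SceneSpec) -> tuple[RGBImage, BinaryMask]:
    """Render a scene and its true mask; deterministic given the seed."""
    rng = substream(spec.seed, "scene")
    truth = _rasterize_ellipses(spec, rng)
    h, w = spec.height, spec.width
    img = np.empty((h, w, 3), dtype=float)
    for ch in range(3):
        base = np.where(truth, spec.fg_color_mean[ch], spec.bg_color_mean[ch])
        sd = np.where(truth, spec.fg_color_sd, spec.bg_color_sd)
        img[..., ch] = base + rng.normal(0.0, 1.0, (h, w)) * sd
    img += rng.normal(0.0, spec.pixel_noise_sd, (h, w, 3))
    return RGBImage(np.clip(img, 0.0, 1.0)), BinaryMask(truth.astype(np.uint8))


def corrupt_mask(mask: BinaryMask, spec: CorruptionSpec) -> BinaryMask:
    """Dilate (optional) then flip labels independently per pixel."""
    rng = substream(spec.seed, "corrupt")
    out = mask.values.astype(bool)
    if spec.boundary_dilate > 0:
        out = dilation(out, disk(spec.boundary_dilate)).astype(bool)
    u = rng.random(out.shape)
    flipped = np.where(
        out, u >= spec.flip_10, u < spec.flip_01
    )
    return BinaryMask(flipped.astype(np.uint8))


def write_fixture(
    out_dir: str | Path,
    scene: SceneSpec,
    corruptions: dict | None = None,
) -> Path:
    """Save scene + truth + corrupted candidate masks as PNGs.

    Returns the path of a manifest CSV (algorithm_label, mask_path)
    listing the candidate masks, consumable by the CLI.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    image, truth = generate_scene(scene)
    iio.imwrite(out / "image.png", (image.values * 255).round().astype(np.uint8))
    iio.imwrite(out / "truth.png", truth.values * 255)
    rows = [("truth", "truth.png")]
    for label, cspec in (corruptions or {}).items():
        m = corrupt_mask(truth, cspec)
        name = f"mask_{label}.png"
        iio.imwrite(out / name, m.values * 255)
        rows.append((label, name))
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["algorithm_label", "mask_path"])
        writer.writerows(rows)
    return manifest
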