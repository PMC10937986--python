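"""Candidate mask production: grayscale conversion and global thresholding.

Thresholding turns a grayscale image ``f`` into a binary image ``o``
via ``o = 1`` where ``f >= T`` and ``o = 0`` where ``f < T`` (equality
maps to foreground).  Six classic global estimators for ``T`` are built
in — Otsu, Mean, Percentile, Intermodes, Minimum and Triangle — all
operating on a 256-bin histogram over [0, 1].  Further methods (Huang,
RenyiEntropy, Sauvola, ...) attach through :func:`register_method`:
the validation procedure, not the thresholding, is the point of this
package, so any user-supplied estimator is a first-class candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from skimage.morphology import closing, disk, opening

from .exceptions import DimensionMismatchError, ImageFormatError, ThresholdError
from .pixel_data import BinaryMask, RGBImage

__all__ = [
    "GrayImage",
    "ThresholdRule",
    "to_grayscale",
    "apply_threshold",
    "estimate_threshold",
    "register_method",
    "available_methods",
    "morphological_cleanup",
    "N_BINS",
    "REC709_WEIGHTS",
]

N_BINS = 256
REC709_WEIGHTS = (0.2126, 0.7152, 0.0722)


@dataclass(frozen=True)
class GrayImage:
    """A grayscale raster with intensities in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.size == 0:
            raise ImageFormatError(f"GrayImage needs shape (H, W), got {v.shape}")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ImageFormatError("gray intensities must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ThresholdRule:
    """A global scalar threshold or a local per-pixel threshold map."""

    kind: str  # "global" | "local"
    T: float | np.ndarray
    method: str = "user"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("global", "local"):
            raise ThresholdError(f"unknown rule kind {self.kind!r}")
        if self.kind == "local":
            object.__setattr__(self, "T", np.asarray(self.T, dtype=float))


def to_grayscale(image: RGBImage, weights: tuple = REC709_WEIGHTS) -> GrayImage:
    """Luminance conversion; Rec. 709 weights by default.

    Weighted channel sum with weights summing to 1, so achromatic
    pixels map to their common intensity.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,):
        raise ValueError("weights must be a length-3 sequence")
    gray = image.values @ w
    return GrayImage(np.clip(gray, 0.0, 1.0))


def apply_threshold(gray: GrayImage, rule: ThresholdRule) -> BinaryMask:
    """Binarize: foreground where intensity >= threshold (ties included)."""
    if rule.kind == "local":
        t = np.asarray(rule.T, dtype=float)
        if t.shape != gray.values.shape:
            raise DimensionMismatchError(
                f"threshold map {t.shape} vs image {gray.values.shape}"
            )
    else:
        t = float(rule.T)
    return BinaryMask((gray.values >= t).astype(np.uint8))


# --------------------------------------------------------------------------
# histogram machinery shared by the built-in estimators

def _histogram(values: np.ndarray) -> np.ndarray:
    counts, _ = np.histogram(values, bins=N_BINS, range=(0.0, 1.0))
    return counts.astype(float)


def _bin_edge(k: int) -> float:
    return k / N_BINS


_CENTERS = (np.arange(N_BINS) + 0.5) / N_BINS


def _otsu(values: np.ndarray, **_: object) -> float:
    """Split point maximizing between-class variance of the histogram."""
    counts = _histogram(values)
    total = counts.sum()
    w0 = np.cumsum(counts)
    mu = np.cumsum(counts * _CENTERS)
    mu_total = mu[-1]
    best_k, best_var = 1, -1.0
    for k in range(1, N_BINS):
        n0, n1 = w0[k - 1], total - w0[k - 1]
        if n0 == 0 or n1 == 0:
            continue
        m0 = mu[k - 1] / n0
        m1 = (mu_total - mu[k - 1]) / n1
        var = n0 * n1 * (m0 - m1) ** 2
        if var > best_var:
            best_var, best_k = var, k
    if best_var < 0:
        raise ThresholdError("otsu: image has a single occupied bin")
    return _bin_edge(best_k)


def _mean(values: np.ndarray, **_: object) -> float:
    return float(values.mean())


def _percentile(values: np.ndarray, p: float = 0.5, **_: object) -> float:
    """Gray level where the cumulative histogram first reaches ``p``."""
    if not 0.0 < p <= 1.0:
        raise ThresholdError("percentile: p must be in (0, 1]")
    counts = _histogram(values)
    cum = np.cumsum(counts) / counts.sum()
    k = int(np.argmax(cum >= p))
    return _bin_edge(k)


def _smooth_until_bimodal(counts: np.ndarray, max_iter: int = 10_000) -> np.ndarray:
    kernel = np.ones(3) / 3.0
    h = counts.copy()
    for _ in range(max_iter):
        peaks = np.flatnonzero((h[1:-1] > h[:-2]) & (h[1:-1] > h[2:])) + 1
        if len(peaks) == 2:
            return h
        if len(peaks) < 2:
            raise ThresholdError("histogram never becomes bimodal")
        h = np.convolve(h, kernel, mode="same")
    raise ThresholdError("histogram never becomes bimodal (smoothing cap reached)")


def _intermodes(values: np.ndarray, **_: object) -> float:
    h = _smooth_until_bimodal(_histogram(values))
    peaks = np.flatnonzero((h[1:-1] > h[:-2]) & (h[1:-1] > h[2:])) + 1
    return _bin_edge(int(round((peaks[0] + peaks[1]) / 2)))


def _minimum(values: np.ndarray, **_: object) -> float:
    h = _smooth_until_bimodal(_histogram(values))
    peaks = np.flatnonzero((h[1:-1] > h[:-2]) & (h[1:-1] > h[2:])) + 1
    valley = peaks[0] + int(np.argmin(h[peaks[0] : peaks[1] + 1]))
    return _bin_edge(int(valley))


def _triangle(values: np.ndarray, **_: object) -> float:
    """Maximal perpendicular distance between histogram and peak-to-tail chord."""
    counts = _histogram(values)
    nz = np.flatnonzero(counts)
    lo, hi = int(nz[0]), int(nz[-1])
    peak = int(np.argmax(counts))
    if hi == lo:
        raise ThresholdError("triangle: image has a single occupied bin")
    # chord runs from the peak to the farther tail end
    tail = hi if (hi - peak) >= (peak - lo) else lo
    if tail == peak:
        tail = hi if tail == lo else lo
    span = np.arange(min(peak, tail), max(peak, tail) + 1)
    # perpendicular distance is proportional to the 2-D cross product
    dist = np.abs(
        (counts[tail] - counts[peak]) * (span - peak)
        - (tail - peak) * (counts[span] - counts[peak])
    )
    return _bin_edge(int(span[np.argmax(dist)]))


_REGISTRY: dict[str, Callable[..., float | np.ndarray]] = {
    "otsu": _otsu,
    "mean": _mean,
    "percentile": _percentile,
    "intermodes": _intermodes,
    "minimum": _minimum,
    "triangle": _triangle,
}


def register_method(name: str, fn: Callable[..., float | np.ndarray]) -> None:
    """Register a threshold estimator ``fn(values, **params) -> T``.

    ``T`` may be a scalar (global rule) or an array matching the image
    shape (local rule, e.g. Sauvola-style adaptive thresholds).
    """
    _REGISTRY[name] = fn


def available_methods() -> list[str]:
    return sorted(_REGISTRY)


def estimate_threshold(gray: GrayImage, method: str, **params: object) -> ThresholdRule:
    """Estimate a threshold rule with a registered method."""
    try:
        fn = _REGISTRY[method]
    except KeyError:
        raise ThresholdError(
            f"unknown threshold method {method!r}; known: {available_methods()}"
        ) from None
    t = fn(gray.values, **params)
    if np.ndim(t) == 0:
        return ThresholdRule("global", float(t), method=method, params=dict(params))
    return ThresholdRule("local", np.asarray(t, float), method=method, params=dict(params))


def morphological_cleanup(mask: BinaryMask, radius: int) -> BinaryMask:
    """Binary opening then closing with a disc structuring element.

    Opening removes speckle smaller than the disc; closing fills
    comparably small holes.  ``radius=0`` is the identity.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return BinaryMask(mask.values.copy())
    # non-strict radius: a radius-1 disc is the full 3x3 neighborhood, so
    # cleanup at the smallest radius leaves solid shapes intact
    selem = disk(radius, strict_radius=False)
    out = closing(opening(mask.values.astype(bool), selem), selem)
    return BinaryMask(out.astype(np.uint8))
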