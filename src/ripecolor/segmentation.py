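"""Foreground extraction: Otsu background removal and mean fruit color.

The fruit sits inside a rectangular crop (from an external detector, or the
whole frame).  A global Otsu threshold on the grayscale crop splits fruit
from backdrop; the surviving pixels are averaged per channel to a single RGB
triple, the image-side analogue of a single-point spectrometer reading.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterator

import numpy as np

from .errors import DegenerateInputError, EmptyForegroundError, InvalidInputError

__all__ = [
    "BoundingBox",
    "ForegroundMask",
    "whole_image_box",
    "otsu_threshold",
    "binarize",
    "foreground_mean_rgb",
]

#: Rec. 601 luma weights used for the grayscale conversion.
LUMA_WEIGHTS = (0.2989, 0.5870, 0.1140)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned crop, 0-based, half-open: [x0, x1) × [y0, y1)."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self):
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise InvalidInputError(f"degenerate bounding box {self}")
        if min(self.x0, self.y0) < 0:
            raise InvalidInputError(f"negative bounding-box corner {self}")

    def crop(self, image: np.ndarray) -> np.ndarray:
        h, w = image.shape[:2]
        if self.x1 > w or self.y1 > h:
            raise InvalidInputError(
                f"bounding box {self} exceeds image bounds {w}×{h}")
        return image[self.y0:self.y1, self.x0:self.x1]


def whole_image_box(image) -> BoundingBox:
    """The trivial bounding-box provider: the full frame."""
    arr = np.asarray(image)
    return BoundingBox(0, 0, arr.shape[1], arr.shape[0])


#: Contract for pluggable detectors: image -> iterator of
#: (box, label, confidence).  Any callable with this shape can replace the
#: whole-frame provider in the pipeline.
BoxProvider = Callable[[np.ndarray], Iterator[tuple[BoundingBox, str, float]]]


@dataclass(frozen=True)
class ForegroundMask:
    """Binary {0,1} mask over a crop, with the threshold that produced it."""

    mask: np.ndarray
    threshold: float
    bright_foreground: bool = True

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())


def _grayscale(crop: np.ndarray) -> np.ndarray:
    arr = np.asarray(crop, dtype=float)
    if arr.ndim == 2:
        return arr
    w = np.array(LUMA_WEIGHTS)
    return arr[:, :, :3] @ w


def otsu_threshold(gray) -> int:
    """Global Otsu threshold over the 256-bin intensity histogram.

    Returns the integer T maximizing the between-class variance of the split
    {≤ T} / {> T}; ties break toward the lowest T.  A constant image has no
    split and raises :class:`DegenerateInputError`.
    """
    arr = np.asarray(gray)
    if arr.size == 0:
        raise InvalidInputError("empty raster")
    levels = np.clip(np.rint(arr), 0, 255).astype(np.int64).ravel()
    hist = np.bincount(levels, minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise DegenerateInputError("constant image: no threshold separates it")

    p = hist / hist.sum()
    omega = np.cumsum(p)                      # class-0 probability for T = 0..255
    mu = np.cumsum(p * np.arange(256))        # class-0 first moment
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b = np.nan_to_num(sigma_b[:255], nan=-1.0, posinf=-1.0)
    return int(np.argmax(sigma_b))            # argmax takes the lowest tie


def binarize(crop, threshold: float, *, bright_foreground: bool = True,
             polarity: str | None = None) -> ForegroundMask:
    """Threshold a crop into a {0,1} foreground mask.

    Grayscale intensity (Rec. 601 luma) strictly above ``threshold`` is
    foreground when ``bright_foreground`` (the lightbox case: fruit on a dark
    backdrop); pass ``bright_foreground=False`` — or ``polarity="auto"`` to
    pick the class whose pixels lie nearer the crop center — for dark fruit
    on a bright background.
    """
    if not (0 <= threshold <= 255):
        raise InvalidInputError(f"threshold {threshold} outside [0, 255]")
    # quantize to 8-bit levels, matching the histogram Otsu thresholded
    gray = np.clip(np.rint(_grayscale(crop)), 0, 255)
    above = gray > threshold

    if polarity == "auto":
        bright_foreground = _bright_class_is_central(above)
    elif polarity is not None:
        raise InvalidInputError(f"unknown polarity {polarity!r}")

    mask = above if bright_foreground else ~above
    return ForegroundMask(mask=mask.astype(np.uint8), threshold=float(threshold),
                          bright_foreground=bright_foreground)


def _bright_class_is_central(above: np.ndarray) -> bool:
    h, w = above.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    yy, xx = np.nonzero(above)
    yn, xn = np.nonzero(~above)
    if len(yy) == 0:
        return False
    if len(yn) == 0:
        return True
    # mean pixel distance to center (robust to symmetric layouts, where both
    # class centroids coincide with the center)
    d_bright = np.hypot(yy - center[0], xx - center[1]).mean()
    d_dark = np.hypot(yn - center[0], xn - center[1]).mean()
    return d_bright <= d_dark


def foreground_mean_rgb(crop, mask: ForegroundMask | np.ndarray) -> np.ndarray:
    """Per-channel mean over foreground pixels only.

    Background pixel values never influence the result; an all-background
    mask raises :class:`EmptyForegroundError`.
    """
    arr = np.asarray(crop, dtype=float)
    m = mask.mask if isinstance(mask, ForegroundMask) else np.asarray(mask)
    if m.shape != arr.shape[:2]:
        raise InvalidInputError(
            f"mask shape {m.shape} does not match crop {arr.shape[:2]}")
    sel = m.astype(bool)
    if not sel.any():
        raise EmptyForegroundError("mask selects no foreground pixels")
    return arr[sel].mean(axis=0)
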