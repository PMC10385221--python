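"""Reference-standard illumination normalization (APLT).

Photographs arrive under uncontrolled light, so before any color is read the
image is pushed toward the brightness of a *reference set* shot in a lightbox.
An image's brightness is summarised by ten components: an overall brightness
(the Minkowski p-mean of intensities, p = 2, averaged over channels) plus the
per-channel mean (brightness), population standard deviation (contrast) and
mean gradient magnitude.  The element-wise average of these components over
the reference set is the Standard Brightness (SB).

The Automatic Power-Law Transformation (APLT) searches a 10 × 10 grid of
power-law (gamma) transforms ``c · v^γ`` — γ chosen from a brightening or a
darkening set depending on whether the image is darker or brighter than the
SB — and keeps the candidate whose components are closest to the SB in
city-block (L1) distance, the Brightness Difference (BD).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "BrightnessComponents",
    "StandardBrightness",
    "CandidateResult",
    "DEFAULT_STANDARD_BRIGHTNESS",
    "overall_brightness",
    "brightness_components",
    "standard_brightness",
    "power_law_transform",
    "brightness_difference",
    "aplt_adjust",
    "adjustment_accuracy",
    "GAMMA_BRIGHT_BRANCH",
    "GAMMA_DARK_BRANCH",
    "C_GRID",
]

#: γ grid used when the image is at least as bright as the standard
#: (γ > 1 darkens on the normalized [0, 1] scale).
GAMMA_BRIGHT_BRANCH: tuple[float, ...] = tuple(float(g) for g in range(1, 11))
#: γ grid used when the image is darker than the standard (γ < 1 brightens).
GAMMA_DARK_BRANCH: tuple[float, ...] = tuple(round(0.1 * g, 1) for g in range(10))
#: multiplicative constants searched in either branch.
C_GRID: tuple[float, ...] = tuple(float(c) for c in range(1, 11))

_COMPONENT_NAMES = ("ob", "br", "bg", "bb", "cr", "cg", "cb", "gr", "gg", "gb")


@dataclass(frozen=True)
class BrightnessComponents:
    """The 10-component brightness signature of an RGB image.

    ``ob`` is the overall brightness; ``br/bg/bb`` per-channel means,
    ``cr/cg/cb`` per-channel contrasts (population std-dev), ``gr/gg/gb``
    per-channel mean gradient magnitudes — all on the 0–255 intensity scale.
    """

    ob: float
    br: float
    bg: float
    bb: float
    cr: float
    cg: float
    cb: float
    gr: float
    gg: float
    gb: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in _COMPONENT_NAMES], dtype=float)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BrightnessComponents":
        return cls(**{n: float(d[n]) for n in _COMPONENT_NAMES})


@dataclass(frozen=True)
class StandardBrightness:
    """Reference brightness: component-wise mean over a lightbox image set."""

    components: BrightnessComponents
    n_images: int = 1

    def __post_init__(self):
        if self.n_images < 1:
            raise InvalidInputError("a brightness standard needs ≥ 1 reference image")

    def to_dict(self) -> dict:
        return {"components": self.components.to_dict(), "n_images": self.n_images}

    @classmethod
    def from_dict(cls, d: dict) -> "StandardBrightness":
        return cls(BrightnessComponents.from_dict(d["components"]),
                   int(d.get("n_images", 1)))


#: Brightness standard shipped with the package, measured on the authors' rig
#: of lightbox reference photographs.  The overall-brightness entry is kept
#: verbatim for completeness but is a composite value on an unspecified scale;
#: the accuracy metric therefore never uses it.
DEFAULT_STANDARD_BRIGHTNESS = StandardBrightness(
    components=BrightnessComponents(
        ob=6.14,
        br=117.91, bg=117.44, bb=67.88,
        cr=45.44, cg=45.70, cb=71.96,
        gr=18.02, gg=18.54, gb=19.35,
    ),
    n_images=1,
)


def _as_rgb_float(image) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3 or arr.shape[0] == 0 or arr.shape[1] == 0:
        raise InvalidInputError(f"expected a non-empty H×W×3 raster, got shape {arr.shape}")
    return arr


def overall_brightness(image, p: float = 2.0) -> float:
    """Overall brightness: per-channel Minkowski p-mean of intensities,
    averaged with weight 1/3 per channel, on the 0–255 scale.

    For a constant image this equals the constant for any p.
    """
    arr = _as_rgb_float(image)
    if p <= 0:
        raise InvalidInputError("p must be positive")
    means = (arr ** p).mean(axis=(0, 1)) ** (1.0 / p)
    return float(means.mean())


def _gradient_mean(channel: np.ndarray) -> float:
    # central differences with replicated edges
    p = np.pad(channel, 1, mode="edge")
    gx = (p[1:-1, 2:] - p[1:-1, :-2]) / 2.0
    gy = (p[2:, 1:-1] - p[:-2, 1:-1]) / 2.0
    return float(np.hypot(gx, gy).mean())


def brightness_components(image) -> BrightnessComponents:
    """Measure the 10-component brightness signature of an RGB image."""
    arr = _as_rgb_float(image)
    means = arr.mean(axis=(0, 1))
    stds = arr.std(axis=(0, 1))  # population std-dev
    grads = [_gradient_mean(arr[:, :, k]) for k in range(3)]
    return BrightnessComponents(
        ob=overall_brightness(arr),
        br=float(means[0]), bg=float(means[1]), bb=float(means[2]),
        cr=float(stds[0]), cg=float(stds[1]), cb=float(stds[2]),
        gr=grads[0], gg=grads[1], gb=grads[2],
    )


def standard_brightness(images: Sequence) -> StandardBrightness:
    """Build a Standard Brightness from a reference image set
    (component-wise arithmetic mean of each image's signature)."""
    images = list(images)
    if not images:
        raise InvalidInputError("reference image set is empty")
    stack = np.stack([brightness_components(im).as_array() for im in images])
    mean = stack.mean(axis=0)
    comps = BrightnessComponents(*(float(v) for v in mean))
    return StandardBrightness(components=comps, n_images=len(images))


def power_law_transform(image, c: float, gamma: float) -> np.ndarray:
    """Power-law (gamma) transform ``c · v^γ`` on [0, 1]-normalized
    intensities, clipped to [0, 1] and rescaled to a 0–255 uint8 raster.

    On the normalized scale γ > 1 darkens and γ < 1 brightens, which is what
    the APLT branch rule relies on.  ``c = 1, γ = 1`` is the identity up to
    rounding.
    """
    arr = _as_rgb_float(image)
    if c <= 0:
        raise InvalidInputError("c must be positive")
    if gamma < 0:
        raise InvalidInputError("gamma must be ≥ 0")
    v = arr / 255.0
    out = np.clip(c * np.power(v, gamma), 0.0, 1.0) * 255.0
    return np.rint(out).astype(np.uint8)


def brightness_difference(candidate: BrightnessComponents,
                          sb: StandardBrightness) -> float:
    """Brightness Difference: city-block (L1) distance between the candidate's
    ten components and the Standard Brightness, equal weights."""
    return float(np.abs(candidate.as_array() - sb.components.as_array()).sum())


@dataclass(frozen=True)
class CandidateResult:
    """The winning candidate of an APLT search."""

    c: float
    gamma: float
    bd: float
    adjusted_image: np.ndarray
    components: BrightnessComponents


def aplt_adjust(image, sb: StandardBrightness) -> CandidateResult:
    """Automatic Power-Law Transformation.

    Compares the image's overall brightness with the standard's to pick the
    darkening (γ ∈ {1..10}) or brightening (γ ∈ {0, 0.1, …, 0.9}) branch,
    generates all 100 (c, γ) candidates, and returns the one minimizing the
    Brightness Difference.  Ties prefer the least aggressive transform:
    smaller |γ − 1| first, then smaller c.

    An image exactly at the standard's overall brightness goes to the
    darkening branch so the identity candidate (c=1, γ=1) stays reachable.
    """
    arr = _as_rgb_float(image)
    ob_ui = overall_brightness(arr)
    gammas = GAMMA_BRIGHT_BRANCH if ob_ui >= sb.components.ob else GAMMA_DARK_BRANCH

    best = None
    best_key = None
    v = arr / 255.0
    for gamma in gammas:
        vg = np.power(v, gamma)
        for c in C_GRID:
            adjusted = np.rint(np.clip(c * vg, 0.0, 1.0) * 255.0).astype(np.uint8)
            comps = brightness_components(adjusted)
            bd = brightness_difference(comps, sb)
            key = (bd, abs(gamma - 1.0), c)
            if best_key is None or key < best_key:
                best_key = key
                best = CandidateResult(c=c, gamma=gamma, bd=bd,
                                       adjusted_image=adjusted, components=comps)
    return best


def aplt_candidate_grid(image, sb: StandardBrightness) -> list[tuple[float, float]]:
    """The (c, γ) pairs an APLT search would evaluate for this image."""
    ob_ui = overall_brightness(image)
    gammas = GAMMA_BRIGHT_BRANCH if ob_ui >= sb.components.ob else GAMMA_DARK_BRANCH
    return [(c, g) for g in gammas for c in C_GRID]


def adjustment_accuracy(adjusted: BrightnessComponents,
                        sb: StandardBrightness) -> float:
    """Adjustment accuracy (%): 100 × (1 − mean over the nine per-channel
    components of |Δ|/255).

    The overall-brightness component is excluded — it is a composite of the
    others and lives on its own scale.
    """
    diffs = np.abs(adjusted.as_array()[1:] - sb.components.as_array()[1:])
    return float(100.0 * (1.0 - (diffs / 255.0).mean()))
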