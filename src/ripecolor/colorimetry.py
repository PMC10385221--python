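"""Hue-angle colorimetry for banana ripeness.

The ripeness statistic is the *angle of ripening* θ, the acute angle of the
right triangle drawn in the green–yellow quadrant of CIE L*a*b* space:

    tan(θ) = b* / |a*|

With unripe (green) fruit, a* is strongly negative and b* moderate, so θ is
small; as chlorophyll breaks down, a* shrinks and b* (yellowness) grows, and
θ sweeps toward 90°.  θ is mapped onto nine ripeness stages via a
:class:`StageTable`, which also yields edibility and the remaining days for
consumption (RDFC, counted inclusive of the current day).

A fixed angular *error constant* (default 2.8°) can be added to θ computed
from camera images to align them with spectrometer readings; see
:func:`adjusted_ripening_angle`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage import color as _skcolor

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "LabColor",
    "RipeningAngle",
    "StageTable",
    "RipenessResult",
    "DAYS_TO_RIPE_UNDEFINED",
    "ripening_angle",
    "adjusted_ripening_angle",
    "rgb_to_lab",
    "lab_to_rgb",
    "stage_from_angle",
]

#: Sentinel ``days_to_ripe`` for fruit below stage 1: picked before the
#: ripening program starts, it shrivels instead of ripening, so no finite
#: day count applies.
DAYS_TO_RIPE_UNDEFINED = 999


@dataclass(frozen=True)
class LabColor:
    """One CIE L*a*b* reading (spectrometer point or image-average color).

    ``L`` is lightness in [0, 100]; ``a`` (green↔red) and ``b`` (blue↔yellow)
    are signed chromaticities, in practice within roughly ±128.
    """

    L: float
    a: float
    b: float


@dataclass(frozen=True)
class RipeningAngle:
    """An angle of ripening in degrees.

    ``adjusted`` records whether the camera-vs-spectrometer error constant
    has been folded in.
    """

    theta_deg: float
    adjusted: bool = False


@dataclass(frozen=True)
class RipenessResult:
    """Staging outcome for one fruit.

    ``stage`` runs 0–10: 0 means θ below the stage-1 interval (pre-ripening),
    10 means past the last stage (overripe).  ``rdfc_days`` is the remaining
    days for consumption, inclusive of the current day; ``days_to_ripe``
    counts days until the first edible stage (0 once edible,
    :data:`DAYS_TO_RIPE_UNDEFINED` for stage 0).
    """

    theta_deg: float
    stage: int
    edible: bool
    rdfc_days: int
    days_to_ripe: int


def _default_boundaries() -> tuple[tuple[int, float, float], ...]:
    # nine contiguous 5° intervals covering θ ∈ [45°, 90°)
    return tuple((s, 40.0 + 5.0 * s, 45.0 + 5.0 * s) for s in range(1, 10))


@dataclass(frozen=True)
class StageTable:
    """Ordered θ intervals defining ripeness stages 1–9.

    Intervals are left-closed, right-open and must be contiguous and strictly
    increasing.  The default table spans [45°, 90°) in nine 5° steps, matching
    the observed 4–5° per-stage span; rigs with their own calibration can load
    a different table from a config file.

    ``error_constant`` is the angular correction (degrees) applied to
    image-derived angles, with ``error_sign`` setting its direction.
    """

    boundaries: tuple[tuple[int, float, float], ...] = field(
        default_factory=_default_boundaries
    )
    error_constant: float = 2.8
    error_sign: int = 1
    first_edible_stage: int = 5
    last_edible_stage: int = 9

    def __post_init__(self):
        bounds = tuple((int(s), float(lo), float(hi)) for s, lo, hi in self.boundaries)
        object.__setattr__(self, "boundaries", bounds)
        if not bounds:
            raise ConfigurationError("stage table has no intervals")
        stages = [s for s, _, _ in bounds]
        if stages != list(range(stages[0], stages[0] + len(stages))):
            raise ConfigurationError("stage indices must be consecutive")
        for i, (s, lo, hi) in enumerate(bounds):
            if not lo < hi:
                raise ConfigurationError(f"stage {s}: empty interval [{lo}, {hi})")
            if i and not math.isclose(lo, bounds[i - 1][2]):
                raise ConfigurationError(f"stage {s}: gap/overlap at θ={lo}")
        if self.error_constant < 0:
            raise ConfigurationError("error_constant must be ≥ 0")
        if self.error_sign not in (-1, 1):
            raise ConfigurationError("error_sign must be ±1")
        if not (stages[0] <= self.first_edible_stage <= self.last_edible_stage <= stages[-1]):
            raise ConfigurationError("edible window must lie within the staged range")

    # -- convenience ------------------------------------------------------
    @property
    def theta_min(self) -> float:
        return self.boundaries[0][1]

    @property
    def theta_max(self) -> float:
        return self.boundaries[-1][2]

    def midpoint(self, stage: int) -> float:
        """Midpoint θ of the given stage's interval."""
        for s, lo, hi in self.boundaries:
            if s == stage:
                return 0.5 * (lo + hi)
        raise ConfigurationError(f"stage {stage} not in table")

    def to_dict(self) -> dict:
        return {
            "boundaries": [list(b) for b in self.boundaries],
            "error_constant": self.error_constant,
            "error_sign": self.error_sign,
            "first_edible_stage": self.first_edible_stage,
            "last_edible_stage": self.last_edible_stage,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StageTable":
        return cls(
            boundaries=tuple(tuple(b) for b in d["boundaries"]),
            error_constant=d.get("error_constant", 2.8),
            error_sign=d.get("error_sign", 1),
            first_edible_stage=d.get("first_edible_stage", 5),
            last_edible_stage=d.get("last_edible_stage", 9),
        )


def ripening_angle(color: LabColor) -> RipeningAngle:
    """Angle of ripening θ = arctan(b* / |a*|), in degrees.

    Negative b* (outside the green–yellow quadrant where the triangle is
    constructed) is clamped to 0.  ``a* = 0`` is treated as the 90° limit
    when b* > 0, and 0° when b* = 0, keeping the map total.
    """
    a, b = color.a, color.b
    if not (math.isfinite(a) and math.isfinite(b)):
        raise InvalidInputError(f"non-finite chromaticity: a={a}, b={b}")
    b = max(b, 0.0)
    if a == 0.0:
        theta = 90.0 if b > 0 else 0.0
    else:
        theta = math.degrees(math.atan(b / abs(a)))
    return RipeningAngle(theta_deg=theta, adjusted=False)


def adjusted_ripening_angle(color: LabColor, table: StageTable) -> RipeningAngle:
    """Image-side angle of ripening with the error constant applied.

    The correction is additive in the angle domain — θ_adj = θ + sign·E_θ —
    because E_θ is estimated as a mean absolute angular difference in degrees
    between spectrometer- and image-derived θ series.
    """
    base = ripening_angle(color)
    theta = base.theta_deg + table.error_sign * table.error_constant
    return RipeningAngle(theta_deg=theta, adjusted=True)


def rgb_to_lab(rgb) -> LabColor:
    """Convert one mean-color sRGB triple (0–255 per channel) to CIE L*a*b*.

    Uses sRGB primaries with the D65 illuminant and 2° observer.
    """
    arr = np.asarray(rgb, dtype=float)
    if arr.shape != (3,):
        raise InvalidInputError(f"expected an RGB triple, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)) or arr.min() < 0 or arr.max() > 255:
        raise InvalidInputError(f"RGB channels must be in [0, 255], got {rgb}")
    lab = _skcolor.rgb2lab(arr[None, None, :] / 255.0)[0, 0]
    return LabColor(L=float(lab[0]), a=float(lab[1]), b=float(lab[2]))


def lab_to_rgb(lab: LabColor) -> np.ndarray:
    """Render a Lab color as an sRGB triple on 0–255 (gamut-clipped)."""
    arr = np.array([[[lab.L, lab.a, lab.b]]], dtype=float)
    rgb = _skcolor.lab2rgb(arr)[0, 0]
    return np.clip(rgb, 0.0, 1.0) * 255.0


def stage_from_angle(theta: RipeningAngle | float, table: StageTable) -> RipenessResult:
    """Map an angle of ripening onto a stage, edibility, RDFC and days-to-ripe.

    Intervals are left-closed, right-open; θ exactly at the last stage's
    upper bound is overripe.  RDFC counts the current day: stage 5 of the
    default table has five remaining days, stage 9 one, overripe zero.
    """
    t = theta.theta_deg if isinstance(theta, RipeningAngle) else float(theta)
    if not math.isfinite(t):
        raise InvalidInputError(f"non-finite θ: {t}")

    first, last = table.first_edible_stage, table.last_edible_stage
    window = last - first + 1
    if t < table.theta_min:
        return RipenessResult(t, stage=0, edible=False, rdfc_days=0,
                              days_to_ripe=DAYS_TO_RIPE_UNDEFINED)
    if t >= table.theta_max:
        over = table.boundaries[-1][0] + 1
        return RipenessResult(t, stage=over, edible=False, rdfc_days=0, days_to_ripe=0)

    stage = next(s for s, lo, hi in table.boundaries if lo <= t < hi)
    edible = first <= stage <= last
    if stage < first:
        rdfc, to_ripe = window, first - stage
    elif edible:
        rdfc, to_ripe = last - stage + 1, 0
    else:
        rdfc, to_ripe = 0, 0
    return RipenessResult(t, stage=stage, edible=edible, rdfc_days=rdfc,
                          days_to_ripe=to_ripe)
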