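"""End-to-end procedures.

Two extraction routes produce an angle of ripening θ:

* **CEFCD** (colorimetric extraction from color data): spectrometer Lab
  readings, averaged, straight into the hue-angle formula.  The reference
  route — no illumination correction, no error constant.
* **CEFI** (colorimetric extraction from image): photograph → crop →
  illumination normalization (APLT) → Otsu background removal → mean
  foreground RGB → Lab → θ with the error constant → stage/RDFC.

Comparing the two routes on the same fruit, day by day, yields the error
constant E_θ (mean absolute angular difference over all pairs), which is how
the packaged default of 2.8° was obtained and how other camera rigs can
re-calibrate it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import synthetic
from .colorimetry import (LabColor, RipenessResult, RipeningAngle, StageTable,
                          adjusted_ripening_angle, rgb_to_lab, ripening_angle,
                          stage_from_angle)
from .errors import (DegenerateInputError, EmptyForegroundError,
                     InvalidInputError, PipelineError)
from .illumination import (CandidateResult, StandardBrightness, adjustment_accuracy,
                           aplt_adjust, brightness_components, standard_brightness)
from .segmentation import (BoundingBox, ForegroundMask, binarize,
                           foreground_mean_rgb, otsu_threshold, whole_image_box)

__all__ = [
    "CefiTrace",
    "ValidationSummary",
    "cefcd",
    "cefi",
    "cefi_trace",
    "error_rate",
    "calibrate_error_constant",
    "run_validation_experiment",
]


def cefcd(readings: Sequence[LabColor], table: StageTable | None = None) -> RipeningAngle:
    """Spectrometer route: average a* and b* over the readings (typically the
    three measurement points along one fruit; L* is discarded) and take the
    hue angle.  No error constant — this is the reference method."""
    readings = list(readings)
    if not readings:
        raise InvalidInputError("need at least one Lab reading")
    a = float(np.mean([r.a for r in readings]))
    b = float(np.mean([r.b for r in readings]))
    return ripening_angle(LabColor(L=0.0, a=a, b=b))


@dataclass(frozen=True)
class CefiTrace:
    """Every intermediate artifact of one image analysis, for inspection."""

    box: BoundingBox
    crop: np.ndarray
    candidate: CandidateResult
    threshold: float
    mask: ForegroundMask
    mean_rgb: np.ndarray
    lab: LabColor
    angle: RipeningAngle
    result: RipenessResult


def cefi_trace(image, box: BoundingBox | None = None,
               sb: StandardBrightness | None = None,
               table: StageTable | None = None,
               polarity: str | None = None,
               apply_error_constant: bool = True) -> CefiTrace:
    """Image route with full artifact trace.

    Stages: crop → APLT illumination normalization → Otsu threshold →
    binarize → mean foreground RGB → Lab → θ (+ error constant unless
    disabled, e.g. during calibration) → stage.  Failures raise
    :class:`PipelineError` naming the stage.
    """
    table = table or StageTable()
    arr = np.asarray(image)
    try:
        box = box or whole_image_box(arr)
        crop = box.crop(arr)
    except InvalidInputError as e:
        raise PipelineError("crop", str(e)) from e

    if sb is None:
        candidate = CandidateResult(c=1.0, gamma=1.0, bd=0.0,
                                    adjusted_image=crop,
                                    components=brightness_components(crop))
    else:
        try:
            candidate = aplt_adjust(crop, sb)
        except InvalidInputError as e:
            raise PipelineError("aplt", str(e)) from e
    adjusted = candidate.adjusted_image

    try:
        t = otsu_threshold(_luma(adjusted))
        mask = binarize(adjusted, t, polarity=polarity)
    except (DegenerateInputError, InvalidInputError) as e:
        raise PipelineError("segmentation", str(e)) from e
    try:
        mean_rgb = foreground_mean_rgb(adjusted, mask)
    except EmptyForegroundError as e:
        raise PipelineError("foreground-mean", str(e)) from e

    lab = rgb_to_lab(mean_rgb)
    angle = (adjusted_ripening_angle(lab, table) if apply_error_constant
             else ripening_angle(lab))
    result = stage_from_angle(angle, table)
    return CefiTrace(box=box, crop=crop, candidate=candidate, threshold=t,
                     mask=mask, mean_rgb=mean_rgb, lab=lab, angle=angle,
                     result=result)


def _luma(crop: np.ndarray) -> np.ndarray:
    from .segmentation import LUMA_WEIGHTS
    return np.asarray(crop, dtype=float)[:, :, :3] @ np.array(LUMA_WEIGHTS)


def cefi(image, box: BoundingBox | None = None,
         sb: StandardBrightness | None = None,
         table: StageTable | None = None,
         polarity: str | None = None) -> RipenessResult:
    """Photograph to ripeness verdict (see :func:`cefi_trace` for artifacts)."""
    return cefi_trace(image, box=box, sb=sb, table=table, polarity=polarity).result


def error_rate(series: pd.DataFrame) -> float:
    """Error rate E_θ between the two extraction routes: the mean over all
    paired records of |θ_CEFCD − θ_CEFI|, in degrees.

    ``series`` needs columns ``theta_cefcd`` and ``theta_cefi``; the divisor
    is the number of pairs (half the total θ count across both methods).
    """
    if len(series) == 0:
        raise InvalidInputError("paired θ series is empty")
    d = np.abs(np.asarray(series["theta_cefcd"], dtype=float)
               - np.asarray(series["theta_cefi"], dtype=float))
    return float(d.mean())


def calibrate_error_constant(spec: synthetic.FixtureSpec, seed: int,
                             fruit_per_group: int = 2) -> tuple[float, pd.DataFrame]:
    """Re-derive E_θ on synthetic data: paired spectrometer/image θ series.

    For each (group, day, fruit) cell a fixture image and the matching
    spectrometer reading are generated from the same true angle; the image is
    pushed through CEFI *without* the error constant, and the mean absolute
    paired difference is returned together with the per-record series.
    """
    rng = np.random.default_rng(seed)
    table = spec.table
    stages = [s for s, _, _ in table.boundaries]
    rows = []
    for group in spec.groups:
        for fruit in range(1, fruit_per_group + 1):
            for day in range(1, spec.n_days + 1):
                stage = stages[min(day, len(stages)) - 1]
                fx = synthetic.generate_fruit_image(
                    spec, stage, int(rng.integers(0, 2**31 - 1)))
                theta_cefcd = fx.theta_true_deg
                trace = cefi_trace(fx.image, table=table,
                                   apply_error_constant=False)
                rows.append((group, day, fruit, theta_cefcd,
                             trace.angle.theta_deg))
    df = pd.DataFrame(rows, columns=["group", "day", "fruit",
                                     "theta_cefcd", "theta_cefi"])
    return error_rate(df), df


@dataclass(frozen=True)
class ValidationSummary:
    """Outcome of the illumination-adjustment validation experiment."""

    n_base: int
    n_validation: int
    mean_accuracy: float
    sd_accuracy: float
    selections: pd.DataFrame  # per-VI: corruption γ, selected c/γ, BD, accuracy


def run_validation_experiment(base_images: Sequence,
                              corruption_gammas: Iterable[float] = (0.5, 1.5),
                              sb: StandardBrightness | None = None) -> ValidationSummary:
    """Validate APLT by corrupt-and-recover.

    The Standard Brightness is built from the clean base set (unless given);
    every base image is copied once per corruption gamma, each corrupted copy
    is run through APLT, and the nine-component adjustment accuracy against
    the SB is averaged over all validation images.
    """
    base_images = list(base_images)
    if not base_images:
        raise InvalidInputError("base image set is empty")
    sb = sb or standard_brightness(base_images)

    rows = []
    for i, img in enumerate(base_images):
        for g in corruption_gammas:
            vi = synthetic.corrupt_brightness(img, g)
            cand = aplt_adjust(vi, sb)
            acc = adjustment_accuracy(cand.components, sb)
            rows.append((i, g, cand.c, cand.gamma, cand.bd, acc))
    sel = pd.DataFrame(rows, columns=["base_index", "corruption_gamma",
                                      "c", "gamma", "bd", "accuracy"])
    return ValidationSummary(
        n_base=len(base_images),
        n_validation=len(sel),
        mean_accuracy=float(sel["accuracy"].mean()),
        sd_accuracy=float(sel["accuracy"].std(ddof=0)),
        selections=sel,
    )
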