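"""Synthetic lightbox fixtures: fruit images and spectrometer-style series.

No public image set accompanies the staging method, so tests and validation
runs are driven by generated data emulating the acquisition design: four
experimental groups (paper-wrapped / unwrapped × 25 °C / 30 °C), 20 fruit per
group, photographed and spectrometer-read daily over a nine-day ripening
program.

An image fixture is an elliptical fruit on a dark uniform backdrop whose base
color is the sRGB rendering of a Lab color with an angle of ripening drawn
from the requested stage's interval midpoint (± jitter), plus stage-dependent
dark freckles, mild shading and sensor noise.  The rendered color sits
``camera_bias_deg`` below the true (spectrometer-frame) angle, emulating the
systematic offset between camera- and spectrometer-derived hue that the
pipeline's error constant corrects; set it to 0 for bias-free fixtures.

Everything is a pure function of (spec, seed): the same inputs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import color as _skcolor

from .colorimetry import StageTable
from .errors import InvalidInputError

__all__ = [
    "FixtureSpec",
    "FruitFixture",
    "generate_fruit_image",
    "corrupt_brightness",
    "generate_spectrometer_series",
]

#: Lightness trajectory over stages 1–9: green fruit brightens into yellow,
#: then browning pulls L back down.
L_BY_STAGE = (60.0, 62.0, 64.0, 66.0, 68.0, 69.0, 68.0, 65.0, 61.0)

#: chroma (√(a*²+b*²)) of the fruit base color
FRUIT_CHROMA = 55.0

GROUPS = ("P25", "P30", "N25", "N30")

#: fractional per-day ripening-rate shifts per group (warmer → faster;
#: wrapping slows moisture loss slightly).  Qualitative only.
GROUP_RATE_SHIFT = {"P25": 0.0, "P30": 0.06, "N25": -0.06, "N30": 0.03}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic acquisition design.

    Defaults reproduce the study layout: 4 groups × 20 fruit × 9 days,
    256×256 images, 5°-per-stage hue trajectory starting near 47.5°,
    per-fruit jitter SD 0.8° (keeps a draw inside its stage interval in
    ≥ 99% of cases).
    """

    groups: tuple[str, ...] = GROUPS
    fruit_per_group: int = 20
    n_days: int = 9
    image_size: int = 256
    theta_jitter_sd: float = 0.8
    camera_bias_deg: float = -2.8
    freckle_density: float = 0.8
    background_rgb: tuple[int, int, int] = (30, 28, 26)
    noise_sd: float = 2.0
    reading_noise_sd: float = 0.3
    table: StageTable = field(default_factory=StageTable)

    def __post_init__(self):
        if self.fruit_per_group < 1 or self.n_days < 1 or self.image_size < 16:
            raise InvalidInputError("counts must be ≥ 1 and image_size ≥ 16")


@dataclass(frozen=True)
class FruitFixture:
    """A generated fruit image with its ground truth."""

    image: np.ndarray          # H×W×3 uint8
    stage: int
    theta_true_deg: float      # spectrometer-frame angle the fixture encodes
    mean_rgb: np.ndarray       # mean fruit color of the rendered image
    mask: np.ndarray           # {0,1} fruit mask


def _lab_from_theta(theta_deg: float, L: float, chroma: float = FRUIT_CHROMA):
    t = np.deg2rad(theta_deg)
    return L, -chroma * np.cos(t), chroma * np.sin(t)


def _render_rgb(L: float, a: float, b: float) -> np.ndarray:
    lab = np.array([[[L, a, b]]], dtype=float)
    rgb = np.clip(_skcolor.lab2rgb(lab)[0, 0], 0.0, 1.0)
    return rgb * 255.0


def generate_fruit_image(spec: FixtureSpec, stage: int, seed: int) -> FruitFixture:
    """Render one lightbox-style fruit image for a ripeness stage.

    The true angle is drawn from the stage interval midpoint ± jitter; the
    painted color additionally carries the camera bias.  Freckle count grows
    with stage but the covered area is capped so the foreground mean color
    stays within ~2° of the base hue.
    """
    table = spec.table
    if not any(s == stage for s, _, _ in table.boundaries):
        raise InvalidInputError(f"stage {stage} not in the stage table")
    rng = np.random.default_rng(seed)
    n = spec.image_size

    theta_true = table.midpoint(stage) + rng.normal(0.0, spec.theta_jitter_sd)
    theta_img = theta_true + spec.camera_bias_deg
    L = L_BY_STAGE[min(stage, 9) - 1] + rng.normal(0.0, 1.0)
    base_rgb = _render_rgb(*_lab_from_theta(theta_img, L))

    # elliptical fruit, slightly rotated, centred in the frame
    yy, xx = np.mgrid[0:n, 0:n]
    cy = cx = (n - 1) / 2.0
    angle = np.deg2rad(20.0 + rng.normal(0.0, 5.0))
    u = (xx - cx) * np.cos(angle) + (yy - cy) * np.sin(angle)
    v = -(xx - cx) * np.sin(angle) + (yy - cy) * np.cos(angle)
    a_ax, b_ax = 0.40 * n, 0.20 * n
    mask = (u / a_ax) ** 2 + (v / b_ax) ** 2 <= 1.0

    img = np.empty((n, n, 3), dtype=float)
    img[:] = np.asarray(spec.background_rgb, dtype=float)
    # mild longitudinal shading so the fruit is not perfectly flat
    shade = 1.0 + 0.04 * np.cos(np.pi * u / a_ax)
    img[mask] = np.clip(base_rgb * shade[mask, None], 0.0, 255.0)

    # dark freckles, more numerous with advancing stage
    n_freckles = rng.poisson(spec.freckle_density * max(stage - 2, 0) * 2.0)
    freckle_rgb = np.array([62.0, 44.0, 28.0])
    r_max = max(2, n // 64)
    for _ in range(n_freckles):
        fy, fx = rng.uniform(0, n, size=2)
        if not ((fx - cx) / a_ax) ** 2 + ((fy - cy) / b_ax) ** 2 <= 0.85:
            continue
        r = rng.uniform(1.0, r_max)
        spot = (yy - fy) ** 2 + (xx - fx) ** 2 <= r ** 2
        img[spot & mask] = freckle_rgb

    img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    mean_rgb = img[mask].mean(axis=0)
    return FruitFixture(image=img, stage=stage, theta_true_deg=float(theta_true),
                        mean_rgb=mean_rgb, mask=mask.astype(np.uint8))


def corrupt_brightness(image, gamma: float) -> np.ndarray:
    """Gamma-corrupt an image: per-channel ``v ↦ v^γ`` on [0, 1]-normalized
    intensities over the full input/output range, back to 0–255 uint8.

    γ = 0.5 brightens (the "darkened by the curve's eye" validation copy in
    MATLAB imadjust terms), γ = 1.5 darkens; γ = 1 is the identity up to
    rounding.
    """
    if gamma <= 0:
        raise InvalidInputError("gamma must be positive")
    arr = np.asarray(image, dtype=float)
    out = np.power(arr / 255.0, gamma) * 255.0
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def generate_spectrometer_series(spec: FixtureSpec, seed: int) -> pd.DataFrame:
    """Spectrometer-style Lab series over the full acquisition design.

    One row per (group, fruit, day) — 720 rows at the default design.  Each
    fruit follows the stage-table hue trajectory (~5°/day from stage 1's
    midpoint) at a group-shifted rate, with per-fruit offsets and per-reading
    noise; the trajectory saturates softly below 90° so the angle stays
    strictly increasing in day even for fast groups.

    Columns: ``group, day, fruit, L, a, b``.
    """
    rng = np.random.default_rng(seed)
    table = spec.table
    theta0 = table.midpoint(table.boundaries[0][0])
    step = table.boundaries[0][2] - table.boundaries[0][1]

    rows = []
    for group in spec.groups:
        rate = 1.0 + GROUP_RATE_SHIFT.get(group, 0.0)
        for fruit in range(1, spec.fruit_per_group + 1):
            offset = rng.normal(0.0, spec.theta_jitter_sd)
            for day in range(1, spec.n_days + 1):
                theta = theta0 + offset + (day - 1) * step * rate
                # soft cap: keep θ < 90° while preserving strict increase
                theta = min(theta, 88.5 + 0.05 * day)
                theta += rng.normal(0.0, spec.reading_noise_sd)
                stage_idx = min(int(np.clip(round((theta - theta0) / step), 0, 8)), 8)
                L = L_BY_STAGE[stage_idx] + rng.normal(0.0, 0.8)
                _, a, b = _lab_from_theta(theta, L)
                rows.append((group, day, fruit, float(L), float(a), float(b)))
    return pd.DataFrame(rows, columns=["group", "day", "fruit", "L", "a", "b"])


def generate_fixture_set(spec: FixtureSpec, n_images: int, seed: int) -> list[FruitFixture]:
    """Generate ``n_images`` fixtures cycling through stages 1–9."""
    stages = [s for s, _, _ in spec.table.boundaries]
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_images)
    return [generate_fruit_image(spec, stages[i % len(stages)], int(seeds[i]))
            for i in range(n_images)]
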