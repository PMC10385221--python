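# Methods

## The colorimetric model

A fruit's skin color is summarised by the angle of ripening
θ = arctan(b\*/|a\*|), the acute angle of the right triangle that the Lab
chromaticity point spans with the −a\* and +b\* axes. The construction
assumes the color sits in the green–yellow quadrant (a\* < 0, b\* ≥ 0), which
holds for banana skin throughout ripening; inputs outside it are projected
onto the quadrant edge (negative b\* is clamped to 0) and a\* = 0 is treated
as the 90° limit so the map is total. θ ignores lightness entirely: L\* is
discarded on the spectrometer route and only enters the image route through
segmentation.

### Stage table

Stages 1–9 are contiguous, left-closed/right-open θ intervals; the packaged
default is nine 5° intervals covering [45°, 90°), consistent with the
observed 4–5° per-stage span, with stage s occupying [40+5s, 45+5s). The
exact physiological boundaries depend on cultivar and rig, so the table is a
config value (JSON) with this documented default, and a calibration path
exists: fit per-stage θ ranges from a spectrometer time series and load them.
θ below stage 1 maps to stage 0 (pre-ripening; such fruit shrivels rather
than ripens, so `days_to_ripe` is the sentinel 999), and θ at or beyond the
stage-9 upper bound maps to stage 10 (overripe, RDFC 0). RDFC includes the
current day: 5 at stage 5 down to 1 at stage 9. For stages 1–4 the package
reports the full 5-day edible window still ahead and `days_to_ripe = 5 − s`.

### Error constant

Image-derived θ sits systematically below spectrometer θ on a given camera
rig. The correction is a constant added *in the angle domain*:
θ_adj = arctan(b\*/|a\*|) + E_θ, default E_θ = 2.8°. An alternative printed
form places the constant inside the tangent, but E_θ is estimated as a mean
absolute angular difference in degrees, so adding it to the tangent's value
would mix units; the angle-domain sum is the dimensionally consistent
reading and is what this package implements. The sign is configurable
(`StageTable.error_sign`, default +) because the correction's direction is a
property of the rig. `pipeline.calibrate_error_constant` re-derives E_θ as
the mean of |θ_CEFCD − θ_CEFI| over paired per-fruit, per-day records.

## Illumination normalization (APLT)

An image's brightness signature has ten components, all on the 0–255 scale:

* **OB** — overall brightness: the per-channel Minkowski p-mean
  (Σ I^p / MN)^(1/p) with p = 2, averaged over the three channels with
  weight 1/3 each;
* **BR, BG, BB** — per-channel means;
* **CR, CG, CB** — per-channel population standard deviations ("contrast");
* **GR, GG, GB** — per-channel mean gradient magnitude √(Gx²+Gy²), central
  differences with replicated edges.

Contrast and gradient are fixed to these definitions for reproducibility;
any monotone-equivalent choice would serve, but tests pin this one. The
Standard Brightness (SB) is the component-wise mean signature over a
reference set photographed in a lightbox. The packaged default SB stores the
constants measured on the original reference rig; its OB entry (6.14) is on
an unspecified scale inconsistent with the per-channel means and is kept
verbatim as a stored constant only — the accuracy metric excludes OB in any
case, as a composite value.

Given an unadjusted image, APLT compares its OB with the standard's to pick
a gamma branch — γ ∈ {1, …, 10} (darkening on the normalized scale) when the
image is at least as bright as the standard, γ ∈ {0, 0.1, …, 0.9}
(brightening) otherwise — and evaluates all 100 combinations with
c ∈ {1, …, 10} of the transform clip(c·v^γ)·255 on [0, 1]-normalized
intensities. The candidate with the smallest city-block distance over the
ten components wins; ties prefer the least aggressive transform (smallest
|γ−1|, then smallest c). Equality of the two OBs is assigned to the
darkening branch so the identity candidate (c = 1, γ = 1) stays reachable.
γ = 0 (all pixels to saturation) is kept in the grid for fidelity to the
printed grid; it cannot win for any non-pathological standard.

The transform is computed on [0, 1] with clipping before rescaling because
the branch rule's direction (γ > 1 darkens, γ < 1 brightens) only holds
there. Outputs are rounded to uint8, so the identity is exact up to one
count and the γ = 0.5 ↔ γ = 2 corruption/recovery pair closes to within two
counts per pixel.

The validation metric scores an adjusted image against the SB as
100 × (1 − mean of |Δcomponent|/255 over the nine non-OB components).

## Segmentation

The fruit crop (from a pluggable detector contract, or the whole frame) is
converted to grayscale with Rec. 601 luma weights (0.2989, 0.5870, 0.1140) —
the choice is conventional; the method itself only asks for "a grayscale
version". A global Otsu threshold is computed on the 256-bin histogram as
the exact between-class-variance maximizer (ties to the lowest threshold; a
constant crop raises a degenerate-input error), and pixels strictly above
the threshold are foreground. This polarity assumes a fruit brighter than
the backdrop, true for lightbox scenes; a polarity flag inverts it, and
`polarity="auto"` picks the class whose pixels lie nearer the crop center.
Dark freckles that fall below the threshold are simply excluded from the
foreground — no compensation is applied. Foreground pixels are averaged per
channel to one RGB triple, converted to Lab under sRGB/D65/2° (the white
point is not dictated by the method; this is the standard choice and is
documented here), and handed to the colorimetric equation.

## Synthetic fixtures

No image set is distributed with the method, so tests and validation runs
generate their own. A fixture is an elliptical fruit (about 40% × 20% of the
frame, slightly rotated) on a dark uniform backdrop (RGB ≈ 30), painted with
the sRGB rendering of a Lab color whose θ is drawn from the requested
stage's interval midpoint ± jitter (SD 0.8°, which keeps a draw inside its
5° interval in ≥ 99% of cases), with a stage-dependent lightness trajectory
(green ≈ 60 rising to ≈ 69 at full yellow, dipping to ≈ 61 with browning),
mild longitudinal shading (±4%), dark elliptical freckles whose count grows
with stage but whose area is capped so the foreground mean hue shifts by
less than 2°, and Gaussian sensor noise (SD 2 counts). The painted color
sits `camera_bias_deg` (default −2.8°) below the true spectrometer-frame
angle, emulating the systematic camera offset that the error constant
corrects; setting it to 0 gives bias-free fixtures for exact round-trip
oracles. The spectrometer-series generator follows the same trajectory at
~5°/day with per-group rate shifts (wrapped/unwrapped × 25/30 °C, ±6% —
qualitative only, since no per-group rates are published) and saturates
softly below 90° so θ stays strictly increasing per fruit.

What the fixtures do *not* emulate: perspective and specular highlights,
non-uniform backgrounds, detector (bounding-box) noise, peel texture, and
cultivar variation. Passing tests therefore demonstrate the internal
consistency and illumination-robustness of the pipeline, not field accuracy
on real photographs; the packaged SB and E_θ defaults carry the original
rig's calibration for that purpose.

## Problem sizes and numerical choices

The shipped validation run uses 200 base fixtures at 128 × 128 (400
corrupted copies, each searched over 100 candidates), a scale at which the
corrupt-and-recover accuracy is stable to well under a percentage point
across seeds. Angles are held in degrees throughout; uint8 quantization
bounds every image round trip (≤ 1 count identity, ≤ 2 counts γ-inversion);
Otsu ties break low; APLT ties break toward the least aggressive transform.

## Known limitations

* The default stage-table boundaries are a documented convention, not a
  physiological calibration; recalibrate per cultivar and rig.
* E_θ is rig-specific; the packaged 2.8° belongs to the reference rig.
* The brightened-corruption recovery (γ = 1.5) has no exact grid inverse
  (1/1.5 ≈ 0.67 falls between 0.6 and 0.7), leaving a few counts of residual
  channel error — visible as the accuracy gap between the two corruption
  directions.
* Object detection is out of scope: the pipeline accepts any bounding-box
  provider but ships only the whole-frame one.
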