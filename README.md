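# ripecolor

Colorimetric ripeness staging of lady finger bananas (*Musa* AA, ‘Kluai
Khai’) from ordinary photographs or spectrometer color readings — for
postharvest researchers, distributors and growers who need to know, fruit by
fruit, how many days remain before a banana ripens and how long it stays
edible.

## The method

Skin color is reduced to a single hue statistic in CIE L\*a\*b\* space, the
**angle of ripening**

    θ = arctan( b* / |a*| )   (degrees)

constructed as the acute angle of the right triangle spanned by the −a\*
(green) and +b\* (yellow) axes. Unripe fruit (strongly negative a\*) gives a
small θ; as chlorophyll degrades, θ sweeps toward 90°. A stage table maps θ
onto ripeness stages 1–9 (by default nine contiguous 5° intervals covering
[45°, 90°)); stages 5–9 are edible, and the **remaining days for consumption
(RDFC)** counts down from 5 to 1 across them, current day included, under the
usual one-stage-per-day ripening rate.

Two extraction routes produce θ:

* **CEFCD** — colorimetric extraction from color data: spectrometer Lab
  readings (three points per fruit, averaged; L\* discarded). The reference
  route.
* **CEFI** — colorimetric extraction from image: crop → illumination
  normalization → Otsu background removal → mean foreground RGB → Lab → θ,
  plus a calibrated **error constant** E_θ (default 2.8°) correcting the
  systematic camera-vs-spectrometer hue offset.

Because photographs arrive under uncontrolled light, CEFI first applies the
**Automatic Power-Law Transformation (APLT)**: the image's brightness is
summarised by ten components (a Minkowski p-mean overall brightness plus
per-channel mean, contrast and mean gradient magnitude), and a 10 × 10 grid
of power-law transforms `c · v^γ` is searched — brightening gammas
{0, 0.1, …, 0.9} or darkening gammas {1, …, 10} depending on which side of
the lightbox reference standard the image falls — keeping the candidate with
the smallest city-block distance (Brightness Difference) to the standard.

## Worked example

`python examples/analyze_photograph.py` renders a synthetic lightbox photo
of a stage-6 fruit, builds a brightness standard from a clean reference set,
and runs the full image route:

```
generated stage:     6
mean foreground RGB: [162.4 175.1  68. ]
theta (adjusted):    72.46 deg
ripeness stage:      6
edible:              True
remaining days:      4
```

θ = 72.46° falls in the stage-6 interval [70°, 75°): the fruit is edible
today and for three more days. The other examples demonstrate the
spectrometer route (`spectrometer_staging.py`), the corrupt-and-recover
behaviour of APLT (`illumination_normalization.py` — a γ = 0.5 corruption is
exactly inverted by the grid member γ = 2), and re-deriving the error
constant from paired series (`calibrate_error_constant.py`, which recovers
E_θ ≈ 2.8°).

There is also a thin CLI:

```
ripecolor analyze photo.png --sb-file sb.json
ripecolor calibrate-sb images/ --out sb.json
ripecolor calibrate-error --seed 0
ripecolor validate --n-images 20 --seed 0
ripecolor generate-fixtures out/ --n-images 9
```

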