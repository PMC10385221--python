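"""Photograph → ripeness verdict.

Renders a synthetic lightbox photo of a stage-6 fruit, builds a brightness
standard from a small clean reference set, and runs the full image route
(CEFI): illumination normalization → background removal → mean color →
angle of ripening → stage and remaining days for consumption.
"""

from ripecolor import FixtureSpec, generate_fixture_set, standard_brightness
from ripecolor.pipeline import cefi_trace

spec = FixtureSpec(image_size=128)
fixtures = generate_fixture_set(spec, 18, seed=42)
sb = standard_brightness([f.image for f in fixtures])

fx = next(f for f in fixtures if f.stage == 6)
trace = cefi_trace(fx.image, sb=sb)
r = trace.result

print(f"generated stage:     {fx.stage}")
print(f"mean foreground RGB: {trace.mean_rgb.round(1)}")
print(f"theta (adjusted):    {r.theta_deg:.2f} deg")
print(f"ripeness stage:      {r.stage}")
print(f"edible:              {r.edible}")
print(f"remaining days:      {r.rdfc_days}")
# θ lands in the stage-6 interval [70°, 75°): the fruit is edible and will
# stay so for rdfc_days more days, counting today.
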