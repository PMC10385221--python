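"""Spectrometer readings → angle of ripening → stage (the CEFCD route).

Three Lab readings along one fruit are averaged (L* is discarded), the hue
angle θ = arctan(b*/|a*|) is taken, and the stage table maps θ to a ripeness
stage and remaining days for consumption.  No error constant is applied:
the spectrometer is the reference instrument.
"""

from ripecolor import LabColor, StageTable, cefcd, stage_from_angle

readings = [
    LabColor(L=51.23, a=-19.97, b=56.35),
    LabColor(L=51.10, a=-20.10, b=56.20),
    LabColor(L=51.40, a=-19.80, b=56.50),
]

table = StageTable()
angle = cefcd(readings)
result = stage_from_angle(angle, table)

print(f"theta:          {angle.theta_deg:.2f} deg")
print(f"stage:          {result.stage}")
print(f"edible:         {result.edible}")
print(f"rdfc_days:      {result.rdfc_days}")
print(f"days_to_ripe:   {result.days_to_ripe}")
# θ ≈ 70.5° falls in stage 6 of the default table ([70°, 75°)): edible,
# with four remaining days for consumption including today.
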