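"""Convert fitted device areas into islet-equivalent (IEQ) doses.

One IEQ is the volume of a 150 um sphere; devices are 0.6 mm thick and
filled at 10% islet volume fraction, giving ~33.95 IEQ per mm^2 of device
footprint. Two devices (left + right) per patient are compared against the
therapeutic threshold of 10 000 IEQ per kg.
"""

from morphofit import DoseParams, area_dose_density, patient_dose

print(f"footprint dose density: {area_dose_density():.2f} IEQ/mm^2")

for area, weight in [(10_000.0, 70.0), (12_000.0, 70.0), (12_000.0, 55.0)]:
    d = patient_dose("demo", "ellipse", area, area, weight)
    print(f"two {area:.0f} mm^2 devices, {weight:.0f} kg patient -> "
          f"{d.ieq_per_kg:,.0f} IEQ/kg, therapeutic: {d.meets_threshold}")
# Dose scales linearly with area and inversely with body weight; the
# threshold flag uses the unrounded IEQ/kg value.
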