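"""Build one patient's PRSP volumes and cut the frontal slice stack.

Each side's plane is the convex hull of its boundary landmarks; the stack
of 1 mm frontal sections runs perpendicular to the thinnest axis of the
minimal oriented bounding box.
"""

from morphofit import (CohortParams, build_prsp, generate_cohort,
                       largest_slice, minimal_bounding_box, slice_volume)

_, landmarks = generate_cohort(CohortParams(n=1, seed=7))
patient = landmarks[0]

for side in ("left", "right"):
    vol = build_prsp(patient, side)
    box = minimal_bounding_box(vol)
    secs = slice_volume(vol, box, spacing=1.0)
    best = largest_slice(secs)
    print(f"{side:5s}: volume {vol.volume / 1e3:7.1f} cm^3 x 10^-3 -> "
          f"box extents {box.extents[0]:.0f} x {box.extents[1]:.0f} x "
          f"{box.extents[2]:.1f} mm, {len(secs)} slices, "
          f"largest slice {best.area:.0f} mm^2 (index {best.slice_index})")
# The smallest box extent is the dorsoventral thickness of the lens-like
# plane; the largest slice is the cross-section the polygon device uses.
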