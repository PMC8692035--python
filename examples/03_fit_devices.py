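"""Fit maximal circular, rectangular, elliptical and polygonal devices.

The circle is the Chebyshev-centre linear program, the ellipse the log-det
convex program, the rectangle a multi-start orientation search with exact
fixed-angle subproblems, and the polygon the largest slice reduced to at
most nine vertices.
"""

from morphofit import (CohortParams, build_prsp, fit_patient,
                       generate_cohort, minimal_bounding_box, slice_volume)

_, landmarks = generate_cohort(CohortParams(n=1, seed=7))
vol = build_prsp(landmarks[0], "left")
secs = slice_volume(vol, minimal_bounding_box(vol))
fits = fit_patient(secs, n_starts=8, seed=0)

for shape, area in fits.areas().items():
    idx = fits.slice_indices()[shape]
    print(f"{shape:10s} area {area:8.0f} mm^2  (best in slice {idx})")
print(f"rectangle aspect ratio: {fits.rectangle.aspect_ratio:.2f}")
print(f"ellipse semi-axes: {fits.ellipse.semi_major:.1f} x "
      f"{fits.ellipse.semi_minor:.1f} mm")
# Expect circle << rectangle < ellipse <= polygon: tapering lens-shaped
# sections reward shapes that can hug the boundary.
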