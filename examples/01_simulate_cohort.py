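"""Generate a synthetic study cohort and summarise its demographics.

The generator draws per-sex truncated-normal demographics (anchored to the
published reference-cohort means ± SDs) through a Gaussian copula, and
builds each patient's PRSP boundary landmarks.
"""

import numpy as np

from morphofit import CohortParams, generate_cohort

records, landmarks = generate_cohort(CohortParams(n=200, seed=1))

females = [r for r in records if r.sex == "female"]
males = [r for r in records if r.sex == "male"]
print(f"n = {len(records)}, female fraction = {len(females) / len(records):.3f}")
for name, grp in (("female", females), ("male", males)):
    h = np.mean([r.height for r in grp])
    w = np.mean([r.weight for r in grp])
    b = np.mean([r.bmi for r in grp])
    print(f"  {name:6s} height {h:.2f} m, weight {w:.1f} kg, BMI {b:.1f}")
ls = landmarks[0]
print(f"first patient: {len(ls.stations)} landmark stations, "
      f"trunk length {ls.xiphoid_tip[2] - ls.pubis_tip[2]:.0f} mm")
# Expect: female fraction near 0.47, sex-specific height/weight gaps, and
# station counts ~10-12 at the default 30 mm craniocaudal spacing.
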