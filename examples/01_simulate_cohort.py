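"""Generate a small synthetic fetal-lung cohort and inspect its structure.

Each case is a speckled ultrasound-like image with three ROI delineations
(two free-hand polygons, one 40x40 square), a gestational age, a
pregnancy-complication flag and an NRM label drawn from a calibrated
logistic model.
"""

import numpy as np

from fetalrad import CohortConfig, generate_cohort

cases = generate_cohort(CohortConfig(n_cases=50, seed=1))

labels = np.array([c.label for c in cases])
comp = np.array([c.complication for c in cases])
ga = np.array([c.ga_weeks for c in cases])

print(f"cases:                 {len(cases)}")
print(f"NRM prevalence:        {labels.mean():.2f}  (target 0.234)")
print(f"complication rate:     {comp.mean():.2f}  (target 0.332)")
print(f"GA range:              {ga.min()}-{ga.max()} weeks")
print(f"image shape:           {cases[0].image.shape}, 8-bit")
print(f"square-mask pixels:    {cases[0].mask_square.n_pixels}")
# Small cohorts fluctuate binomially around the configured rates; the
# calibration test in the suite checks convergence at n = 2000.
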