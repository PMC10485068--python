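"""Metacognitive sensitivity: confidence-accuracy slopes and contrasts.

Fits a penalized logistic regression of accuracy on standardized
confidence per subject x task, then contrasts mean slopes between groups
with a bias-corrected bootstrap and a JZS Bayes factor.
"""

import metaconf as mc
from metaconf.sensitivity import contrast_slopes, fit_all_slopes

cfg = mc.CohortConfig(
    control=mc.GroupSpec(n_subjects=30),
    patient=mc.GroupSpec(n_subjects=30, sigma_c_value=3.0),  # planted deficit
    master_seed=2,
)
trials, _ = mc.simulate_cohort(cfg)

slopes = fit_all_slopes(trials)
print(slopes.groupby(["task", "group"])["slope"].mean().round(3))

for c in contrast_slopes(slopes, n_boot=2000, seed=0):
    print(f"{c.label}: {c.estimate:+.2f} [{c.interval_low:+.2f}, {c.interval_high:+.2f}] "
          f"BF10={c.bf10:.2f}")
print(
    "\nThe slope is the log-odds of a correct response per SD of confidence.\n"
    "The patient group was simulated with tripled confidence noise: its\n"
    "slopes are consistently flatter (negative contrasts in every task),\n"
    "though intervals at this cohort size remain wide — one reason the\n"
    "confidence-efficiency model pools all of a population's trials instead."
)
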