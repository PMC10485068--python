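"""Confidence efficiency: generative confidence-model fit with bootstrap.

Fits the confidence-noise / confidence-boost model to one task x group
population (per-subject type-1 parameters, shared sigma_c and alpha),
computes efficiency eta against the ideal confidence observer, and
quantifies dispersion by resampling subjects with replacement.
"""

import metaconf as mc
from metaconf.cohort import BetweenSubjectSD

cfg = mc.CohortConfig(
    control=mc.GroupSpec(
        n_subjects=20, sigma_c_value=1.0, alpha_value=0.2,
        between_subject_sd=BetweenSubjectSD(sigma_c=0.0, alpha=0.0),
    ),
    patient=mc.GroupSpec(n_subjects=2),
    master_seed=3,
)
trials, _ = mc.simulate_cohort(cfg)
population = trials[(trials.group == "control") & (trials.task == "detection")]

est = mc.bootstrap_efficiency(population, B=200, seed=0)
print(f"fitted confidence noise sigma_c = {est.sigma_c_hat:.2f} (true 1.0)")
print(f"fitted confidence boost alpha  = {est.alpha_hat:.2f} (true 0.2)")
print(f"type-2 AUC observer/ideal      = {est.auc2_observer:.3f} / {est.auc2_ideal:.3f}")
print(f"confidence efficiency eta      = {est.eta:.2f}  95% CI [{est.ci95[0]:.2f}, {est.ci95[1]:.2f}]")
print(
    "\neta = 1 marks the ideal confidence observer; confidence noise pulls\n"
    "it below 1, extra stimulus information (boost) pushes it back up.\n"
    "eta depends only on the fitted metacognitive parameters, so groups\n"
    "with different task performance remain directly comparable."
)
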