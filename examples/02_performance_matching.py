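"""Session-1 performance matching: psychometric fit and inversion.

Fits the detection psychometric curve from calibration counts (3 contrast
levels x 80 trials plus catch trials), then inverts it at the four memory
hit rates to pick contrast levels that equalize detection and memory
performance within the participant.
"""

import numpy as np
from scipy.special import ndtr

from metaconf import fit_psychometric, match_contrasts, psychometric_yes_rate

rng = np.random.default_rng(0)
contrasts = np.array([0.02, 0.05, 0.12])
true_p = 0.2 + (1 - 0.2 - 0.01) * ndtr((np.log(contrasts) - np.log(0.05)) / 0.7)
yes_counts = rng.binomial(80, true_p)

fit = fit_psychometric(contrasts, yes_counts, [80] * 3, catch_yes=12, catch_total=60)
print(f"fitted curve: guess={fit.guess:.3f} location={fit.location:.3f} width={fit.width:.3f}")

memory_hits = np.array([0.62, 0.72, 0.82, 0.90])  # lags 1..4 from session 1
matched = match_contrasts(fit, memory_hits)
for lag, (rate, c) in enumerate(zip(memory_hits, matched), start=1):
    print(f"lag {lag}: memory hit rate {rate:.2f} -> contrast {c:.4f} "
          f"(predicted detection hit rate {psychometric_yes_rate(fit, c):.2f})")
print(
    "\nEach contrast is the point where the fitted curve equals the memory\n"
    "hit rate, so session 2 presents detection at the participant's own\n"
    "memory performance level."
)
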