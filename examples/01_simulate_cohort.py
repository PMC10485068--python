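"""Simulate a case-control cohort and inspect first-order performance.

Builds the default two-group cohort (36 controls, 34 patients; patients
carry a first-order deficit and elevated recollection false alarms but the
same confidence noise/boost) and prints hit and false-alarm rates per task
and group — the structure of a typical descriptive table.
"""

import metaconf as mc

trials, manifest = mc.simulate_cohort(mc.default_cohort_config(master_seed=1))
summaries = mc.performance_summary(trials)

table = (
    summaries.groupby(["task", "group"])[["hit_rate", "fa_rate", "accuracy"]]
    .mean()
    .round(3)
)
print(f"{len(manifest)} subjects, {len(trials)} trials")
print(table)
print(
    "\nHit rate = P(yes | strength > 0); FA rate = P(yes | strength 0).\n"
    "Patients show lower hits everywhere and a raised recollection FA rate\n"
    "(false recognitions), mirroring the planted group-level deficits."
)
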