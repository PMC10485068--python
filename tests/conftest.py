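import numpy as np
import pytest

import metaconf as mc
from metaconf.cohort import BetweenSubjectSD


def make_observer(
    mu=(1.2, 1.5, 1.9, 2.2),
    criterion=0.8,
    foil=0.0,
    sigma_c=1.0,
    alpha=0.2,
    subject_id="s0",
    group="control",
    task_foils=None,
):
    """Hand-built observer with identical parameters across tasks."""
    mu = np.asarray(mu, float)
    foils = task_foils or {t: foil for t in mc.schema.TASKS}
    return mc.ObserverParams(
        subject_id=subject_id,
        group=group,
        mu={t: mu for t in mc.schema.TASKS},
        criterion=criterion,
        foil_mu=foils,
        sigma_c=sigma_c,
        alpha=alpha,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """8 + 8 subject cohort with the default (study-like) group structure."""
    cfg = mc.CohortConfig(
        control=mc.GroupSpec(n_subjects=8),
        patient=mc.GroupSpec(n_subjects=8, mu_shift=-0.3, foil_shift_recollection=0.6),
        master_seed=42,
    )
    trials, manifest = mc.simulate_cohort(cfg)
    return trials, manifest


@pytest.fixture(scope="session")
def homogeneous_population():
    """20 subjects sharing (sigma_c, alpha) = (1.0, 0.2), detection task."""
    cfg = mc.CohortConfig(
        control=mc.GroupSpec(
            n_subjects=20,
            between_subject_sd=BetweenSubjectSD(sigma_c=0.0, alpha=0.0),
        ),
        patient=mc.GroupSpec(n_subjects=2),
        master_seed=7,
    )
    trials, manifest = mc.simulate_cohort(cfg)
    sub = trials[(trials["group"] == "control") & (trials["task"] == "detection")]
    return sub.reset_index(drop=True), manifest
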