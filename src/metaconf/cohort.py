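"""Generative SDT cohorts: two groups, three tasks, confidence ratings.

Each simulated observer is an equal-variance signal-detection observer.  On
a trial of strength s the decision evidence is x ~ N(mu_s, 1) (mu_0 is the
"foil" mean of strength-0 trials); the observer answers "yes" iff x exceeds
its criterion c.  Confidence is built from a second evidence variable

    z = (1 - alpha) * x + alpha * x2 + eps,

where x2 ~ N(mu_s, 1) is an independent second stimulus sample (the
"confidence boost": alpha = 0 reuses the decision sample, alpha = 1 fully
re-samples the stimulus) and eps ~ N(0, sigma_c^2) is metacognitive
("confidence") noise.  The rating on the 0-100 scale is the observer's own
posterior probability of being correct given (z, response), computed under
a veridical internal model that knows (mu, c, sigma_c, alpha) and the
design's strength priors.

Group-level deficits are planted through `GroupSpec`: an additive
first-order shift of all evidence means, a different confidence-noise /
boost level, and an elevated recollection foil mean (false recognitions).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import special, stats

from .schema import GROUPS, STRENGTHS, TASKS, SessionDesign, build_session_design

#: Nominal Michelson contrasts attached to detection strengths 1..4; pure
#: metadata for the trial table (evidence means, not contrast, drive the
#: simulation).
NOMINAL_CONTRASTS = (0.02, 0.04, 0.08, 0.16)

#: Evidence means (strengths 1..4) and criterion giving ~65/75/85/92% hits
#: and a 20% false-alarm rate — the control group's operating range.
DEFAULT_MU_BASE = (1.23, 1.51, 1.88, 2.25)
DEFAULT_CRITERION = 0.84
#: Recollection strength-0 trials are re-paired contexts, not new faces, so
#: even controls sit above a zero foil (FA ~ 28%).
DEFAULT_FOIL_RECOLLECTION = 0.25


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one simulated observer."""

    subject_id: str
    group: str
    mu: Mapping[str, np.ndarray]  # task -> evidence means for strengths 1..4
    criterion: float
    foil_mu: Mapping[str, float]  # task -> strength-0 evidence mean (>= 0)
    sigma_c: float
    alpha: float
    rng_seed: int | None = None

    def class_means(self, task: str) -> np.ndarray:
        """Evidence means for strength classes 0..4 of one task."""
        return np.concatenate([[self.foil_mu[task]], np.asarray(self.mu[task], float)])

    def validate(self) -> None:
        if self.sigma_c < 0:
            raise ValueError("sigma_c must be >= 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        for task in self.mu:
            m = np.asarray(self.mu[task], float)
            if m.shape != (4,) or np.any(np.diff(m) < -1e-12):
                raise ValueError(f"mu must be 4 nondecreasing values ({task})")
            if self.foil_mu[task] < 0:
                raise ValueError("foil_mu must be >= 0")


@dataclass(frozen=True)
class BetweenSubjectSD:
    """Between-subject SDs of the observer parameters."""

    mu: float = 0.3
    criterion: float = 0.25
    sigma_c: float = 0.25
    alpha: float = 0.08
    foil: float = 0.15

    def validate(self) -> None:
        if min(dataclasses.astuple(self)) < 0:
            raise ValueError("between-subject SDs must be >= 0")


@dataclass(frozen=True)
class GroupSpec:
    """Population-level parameters of one group of observers."""

    n_subjects: int
    mu_base: tuple = DEFAULT_MU_BASE
    criterion: float = DEFAULT_CRITERION
    mu_shift: float = 0.0  # additive first-order deficit on all mu_s
    sigma_c_value: float = 1.0
    alpha_value: float = 0.2
    foil_recollection: float = DEFAULT_FOIL_RECOLLECTION
    foil_shift_recollection: float = 0.0
    between_subject_sd: BetweenSubjectSD = field(default_factory=BetweenSubjectSD)

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        self.between_subject_sd.validate()


@dataclass(frozen=True)
class CohortConfig:
    """Two-group cohort specification plus the session design."""

    control: GroupSpec
    patient: GroupSpec
    design: SessionDesign = field(default_factory=SessionDesign)
    master_seed: int = 0

    def validate(self) -> None:
        self.control.validate()
        self.patient.validate()
        self.design.validate()


def default_cohort_config(master_seed: int = 0) -> CohortConfig:
    """Cohort emulating the case-control study's structure.

    36 controls vs 34 patients; patients carry a first-order deficit
    (mu_shift −0.3, dropping hits from ~80% to ~71%) and elevated
    recollection false recognitions (foil shift +0.6, FA ~28% → ~50%), but
    the SAME confidence noise and boost as controls — i.e., intact
    metacognition behind degraded task performance.
    """
    return CohortConfig(
        control=GroupSpec(n_subjects=36),
        patient=GroupSpec(
            n_subjects=34, mu_shift=-0.3, foil_shift_recollection=0.6
        ),
        master_seed=master_seed,
    )


def _truncated_normal(rng, mean: float, sd: float, lower: float = 0.0) -> float:
    if sd == 0:
        return max(mean, lower)
    a = (lower - mean) / sd
    return float(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


def truncated_normal_mean(mean: float, sd: float, lower: float = 0.0) -> float:
    """Mean of a normal truncated below at ``lower`` (sampling oracle)."""
    if sd == 0:
        return max(mean, lower)
    a = (lower - mean) / sd
    return float(stats.truncnorm.mean(a, np.inf, loc=mean, scale=sd))


def sample_observer(
    spec: GroupSpec,
    rng: np.random.Generator,
    subject_id: str = "s0",
    group: str = "control",
) -> ObserverParams:
    """Draw one observer from the group's between-subject distributions.

    mu receives one normal offset per task (shared across strengths, so the
    nondecreasing ordering is preserved); sigma_c and foil means are
    truncated at 0; alpha is clipped to [0, 1].
    """
    spec.validate()
    sd = spec.between_subject_sd
    base = np.asarray(spec.mu_base, float) + spec.mu_shift
    mu = {task: base + rng.normal(0.0, sd.mu) for task in TASKS}
    criterion = float(rng.normal(spec.criterion, sd.criterion))
    foil = {}
    for task in TASKS:
        center = spec.foil_recollection + spec.foil_shift_recollection if task == "recollection" else 0.0
        foil[task] = _truncated_normal(rng, center, sd.foil)
    sigma_c = _truncated_normal(rng, spec.sigma_c_value, sd.sigma_c)
    alpha = float(np.clip(rng.normal(spec.alpha_value, sd.alpha), 0.0, 1.0))
    return ObserverParams(
        subject_id=subject_id,
        group=group,
        mu=mu,
        criterion=criterion,
        foil_mu=foil,
        sigma_c=sigma_c,
        alpha=alpha,
    )


def posterior_confidence(
    z,
    response_yes,
    class_means,
    criterion: float,
    sigma_c: float,
    alpha: float,
    priors,
):
    """0-100 confidence: the veridical posterior P(correct | z, response).

    (x, z) are jointly Gaussian given the strength class, so the posterior
    over classes given (z, response) has a closed form mixing the marginal
    density of z with the conditional response probability P(x > c | z).
    Computed in log space for tail stability.  Vectorized over ``z``.
    """
    z = np.asarray(z, float)
    if not np.all(np.isfinite(z)):
        raise ValueError("confidence evidence z must be finite")
    yes = np.broadcast_to(np.asarray(response_yes, bool), z.shape)
    means = np.asarray(class_means, float)
    priors = np.asarray(priors, float)
    var_z = (1.0 - alpha) ** 2 + alpha**2 + sigma_c**2
    extra = alpha**2 + sigma_c**2  # var(z | x)
    zc = z[..., None]
    logf = -0.5 * (zc - means) ** 2 / var_z
    if extra < 1e-14:
        # Degenerate case z == x: the response is a deterministic function
        # of z and carries no information beyond it.
        logw = np.log(priors) + logf
    else:
        cov = 1.0 - alpha
        cond_mean = means + (cov / var_z) * (zc - means)
        cond_sd = np.sqrt(extra / var_z)
        u = (cond_mean - criterion) / cond_sd
        logw = np.log(priors) + logf + np.where(yes[..., None], special.log_ndtr(u), special.log_ndtr(-u))
    log_all = special.logsumexp(logw, axis=-1)
    log_signal = special.logsumexp(logw[..., 1:], axis=-1)
    p_signal = np.exp(log_signal - log_all)
    conf = np.where(yes, p_signal, 1.0 - p_signal)
    return 100.0 * conf


def confidence_from_evidence(
    z,
    response: str,
    params: ObserverParams,
    task: str,
    task_priors=None,
) -> float | np.ndarray:
    """Map internal confidence evidence z to a 0-100 rating.

    Monotone nondecreasing in z for response "yes" and nonincreasing for
    response "no" (higher z always signals "stimulus present").
    """
    if response not in ("yes", "no"):
        raise ValueError("response must be 'yes' or 'no'")
    if task_priors is None:
        task_priors = np.full(len(STRENGTHS), 1.0 / len(STRENGTHS))
    return posterior_confidence(
        z,
        response == "yes",
        params.class_means(task),
        params.criterion,
        params.sigma_c,
        params.alpha,
        task_priors,
    )


def _simulate_vectors(
    params: ObserverParams,
    task: str,
    strengths: np.ndarray,
    rng: np.random.Generator,
    priors,
):
    """Vectorized trial simulation for one observer on one task."""
    means = params.class_means(task)
    mu = means[strengths]
    x = rng.normal(mu, 1.0)
    x2 = rng.normal(mu, 1.0)
    eps = rng.normal(0.0, params.sigma_c, size=mu.shape) if params.sigma_c > 0 else 0.0
    yes = x > params.criterion
    z = (1.0 - params.alpha) * x + params.alpha * x2 + eps
    conf = posterior_confidence(
        z, yes, means, params.criterion, params.sigma_c, params.alpha, priors
    )
    accuracy = (yes == (strengths > 0)).astype(int)
    return yes, accuracy, conf


def simulate_trials(
    params: ObserverParams,
    task: str,
    strengths,
    rng: np.random.Generator,
    priors=None,
) -> pd.DataFrame:
    """Vectorized simulation of many trials of one observer on one task.

    Returns a frame with columns strength, response, accuracy, confidence
    (no session bookkeeping) — the workhorse behind the session simulator
    and the closed-form-rate checks.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    strengths = np.asarray(strengths, int)
    if strengths.size and (strengths.min() < 0 or strengths.max() > 4):
        raise ValueError("strength must lie in 0..4")
    if priors is None:
        priors = np.full(len(STRENGTHS), 1.0 / len(STRENGTHS))
    yes, accuracy, conf = _simulate_vectors(params, task, strengths, rng, priors)
    return pd.DataFrame(
        {
            "strength": strengths,
            "response": np.where(yes, "yes", "no"),
            "accuracy": accuracy,
            "confidence": conf,
        }
    )


def simulate_trial(
    params: ObserverParams,
    task: str,
    strength: int,
    rng: np.random.Generator,
    priors=None,
) -> dict:
    """Simulate a single trial; returns a TrialRecord-shaped dict."""
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    if strength not in STRENGTHS:
        raise ValueError("strength must lie in 0..4")
    if priors is None:
        priors = np.full(len(STRENGTHS), 1.0 / len(STRENGTHS))
    s = np.array([strength])
    yes, accuracy, conf = _simulate_vectors(params, task, s, rng, priors)
    is_det = task == "detection"
    return {
        "subject_id": params.subject_id,
        "group": params.group,
        "task": task,
        "block": 1,
        "trial_index": 1,
        "strength": strength,
        "contrast": NOMINAL_CONTRASTS[strength - 1] if is_det and strength > 0 else np.nan,
        "lag": strength if not is_det and strength > 0 else np.nan,
        "response": "yes" if yes[0] else "no",
        "accuracy": int(accuracy[0]),
        "confidence": float(conf[0]),
    }


def simulate_session(
    params: ObserverParams, design: SessionDesign, seed: int
) -> pd.DataFrame:
    """Simulate one full session (design slots + responses + confidence)."""
    slots = build_session_design(design, seed)
    rng = np.random.default_rng(seed + 1)
    priors = design.strength_priors()
    frames = []
    for task in design.tasks:
        sub = slots[slots["task"] == task]
        strengths = sub["strength"].to_numpy()
        yes, accuracy, conf = _simulate_vectors(params, task, strengths, rng, priors)
        is_det = task == "detection"
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": params.subject_id,
                    "group": params.group,
                    "task": task,
                    "block": sub["block"].to_numpy(),
                    "trial_index": sub["trial_index"].to_numpy(),
                    "strength": strengths,
                    "contrast": np.where(
                        is_det & (strengths > 0),
                        np.array((np.nan,) + NOMINAL_CONTRASTS)[strengths],
                        np.nan,
                    ),
                    "lag": np.where(~is_det & (strengths > 0), strengths, np.nan),
                    "response": np.where(yes, "yes", "no"),
                    "accuracy": accuracy,
                    "confidence": conf,
                }
            )
        )
    out = pd.concat(frames).sort_values("trial_index").reset_index(drop=True)
    out["lag"] = out["lag"].astype("Int64")
    return out


def simulate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate the full two-group cohort.

    Returns the pooled trial table and a manifest mapping subject_id to the
    true generative parameters (for parameter-recovery checks).  Byte-for-
    byte reproducible given ``config.master_seed``.
    """
    config.validate()
    ss = np.random.SeedSequence(config.master_seed)
    specs = [("control", config.control), ("scz", config.patient)]
    frames, manifest = [], {}
    children = ss.spawn(sum(spec.n_subjects for _, spec in specs))
    k = 0
    for group, spec in specs:
        for i in range(spec.n_subjects):
            child = children[k]
            k += 1
            rng = np.random.default_rng(child)
            subject_id = f"{group}{i + 1:03d}"
            session_seed = int(child.generate_state(1, np.uint32)[0] % 2**31)
            params = dataclasses.replace(
                sample_observer(spec, rng, subject_id=subject_id, group=group),
                rng_seed=session_seed,
            )
            frames.append(simulate_session(params, config.design, session_seed))
            manifest[subject_id] = {
                "group": group,
                "criterion": params.criterion,
                "sigma_c": params.sigma_c,
                "alpha": params.alpha,
                "mu": {t: list(map(float, params.mu[t])) for t in TASKS},
                "foil_mu": {t: float(params.foil_mu[t]) for t in TASKS},
                "rng_seed": session_seed,
            }
    return pd.concat(frames, ignore_index=True), manifest
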