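"""Metacognitive sensitivity as confidence-accuracy regression slopes.

A two-stage hierarchical approximation: per subject x task, a penalized
logistic regression of first-order accuracy on within-subject standardized
confidence yields a slope (log-odds of being correct per SD of
confidence); slopes are then contrasted between groups or tasks with a
bias-corrected subject-level bootstrap and a JZS Bayes factor.  The weak
quadratic penalty on the slope guarantees finite estimates under
separation (e.g., a subject whose errors all carry low confidence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

from .bayes import jzs_bf, two_sample_t
from .schema import TASKS


@dataclass(frozen=True)
class MetaSlopeEstimate:
    subject_id: str
    task: str
    slope: float
    intercept: float
    se: float
    n_trials: int
    penalty_used: float
    flagged: bool = False
    flag_reason: str = ""


@dataclass(frozen=True)
class GroupContrast:
    label: str
    estimate: float
    interval_low: float
    interval_high: float
    bf10: float
    n_boot: int


def standardize_confidence(trials: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Add a per-subject z-scored confidence column ``zconf``.

    Standardization is within subject across all of that subject's trials
    (tasks pooled), making slopes invariant to each subject's confidence
    scale use.  Subjects with zero confidence variance get NaN and are
    returned as flagged.
    """
    df = trials.copy()
    grp = df.groupby("subject_id")["confidence"]
    mean = grp.transform("mean")
    sd = grp.transform(lambda s: s.std(ddof=0))
    flagged = sorted(df.loc[sd == 0, "subject_id"].unique())
    with np.errstate(invalid="ignore", divide="ignore"):
        df["zconf"] = np.where(sd > 0, (df["confidence"] - mean) / sd, np.nan)
    return df, flagged


def fit_subject_slope(
    trials: pd.DataFrame, penalty: float = 0.5, min_trials: int = 20
) -> MetaSlopeEstimate:
    """Penalized logistic fit accuracy ~ b0 + b1 * zconf for one subject x task.

    Minimizes the negative Bernoulli log-likelihood plus
    ``0.5 * penalty * b1**2``; the SE comes from the curvature of the
    penalized objective.  Subjects with too few trials, a single accuracy
    class, or missing standardized confidence are flagged rather than
    fitted.
    """
    sid = str(trials["subject_id"].iloc[0])
    task = str(trials["task"].iloc[0])
    y = trials["accuracy"].to_numpy(float)
    x = trials["zconf"].to_numpy(float)
    flag = ""
    if len(y) < min_trials:
        flag = f"too_few_trials:{len(y)}"
    elif np.any(~np.isfinite(x)):
        flag = "constant_confidence"
    elif y.min() == y.max():
        flag = "single_accuracy_class"
    if flag:
        return MetaSlopeEstimate(sid, task, np.nan, np.nan, np.nan, len(y), penalty, True, flag)

    def negll_grad(beta):
        eta = beta[0] + beta[1] * x
        p = special.expit(eta)
        nll = -np.sum(y * special.log_expit(eta) + (1 - y) * special.log_expit(-eta))
        nll += 0.5 * penalty * beta[1] ** 2
        resid = p - y
        grad = np.array([resid.sum(), resid @ x + penalty * beta[1]])
        return nll, grad

    res = optimize.minimize(negll_grad, np.zeros(2), jac=True, method="L-BFGS-B")
    b0, b1 = res.x
    p = special.expit(b0 + b1 * x)
    w = p * (1 - p)
    hess = np.array(
        [[w.sum(), w @ x], [w @ x, w @ (x * x) + penalty]]
    )
    se = float(np.sqrt(np.linalg.inv(hess)[1, 1]))
    return MetaSlopeEstimate(sid, task, float(b1), float(b0), se, len(y), penalty)


def fit_all_slopes(trials: pd.DataFrame, penalty: float = 0.5) -> pd.DataFrame:
    """Slope table over every subject x task (flagged rows have NaN slope)."""
    df, _ = standardize_confidence(trials)
    rows = []
    for (sid, task), sub in df.groupby(["subject_id", "task"], sort=True):
        est = fit_subject_slope(sub, penalty=penalty)
        rows.append(
            {
                "subject_id": est.subject_id,
                "group": sub["group"].iloc[0],
                "task": est.task,
                "slope": est.slope,
                "intercept": est.intercept,
                "se": est.se,
                "n_trials": est.n_trials,
                "flagged": est.flagged,
                "flag_reason": est.flag_reason,
            }
        )
    return pd.DataFrame(rows)


def _bc_interval(boot: np.ndarray, estimate: float, level: float = 0.95) -> tuple:
    """Bias-corrected percentile interval."""
    boot = boot[np.isfinite(boot)]
    prop = np.clip(np.mean(boot < estimate), 1e-6, 1 - 1e-6)
    z0 = special.ndtri(prop)
    zcrit = special.ndtri(0.5 + level / 2)
    lo = special.ndtr(2 * z0 - zcrit)
    hi = special.ndtr(2 * z0 + zcrit)
    return float(np.quantile(boot, lo)), float(np.quantile(boot, hi))


def contrast_slopes(
    slope_table: pd.DataFrame,
    by: str = "group_within_task",
    n_boot: int = 2000,
    seed: int = 0,
    r_scale: float = 0.7,
) -> list[GroupContrast]:
    """Group or task contrasts of mean slopes with bootstrap 95% intervals.

    ``by='group_within_task'`` yields scz - control per task (negative =
    metacognitive deficit in patients); ``by='task_within_group'`` yields
    pairwise task differences within each group, bootstrapped over the
    shared subjects (paired).  BF10 applies the two-sample JZS test to the
    two slope samples at the given prior scale.
    """
    tab = slope_table[~slope_table["flagged"] & np.isfinite(slope_table["slope"])]
    rng = np.random.default_rng(seed)
    out = []
    if by == "group_within_task":
        for task in TASKS:
            sub = tab[tab["task"] == task]
            a = sub.loc[sub["group"] == "scz", "slope"].to_numpy()
            b = sub.loc[sub["group"] == "control", "slope"].to_numpy()
            if len(a) < 2 or len(b) < 2:
                raise ValueError(f"empty or singleton cell: task={task}")
            est = a.mean() - b.mean()
            boot = (
                a[rng.integers(0, len(a), (n_boot, len(a)))].mean(axis=1)
                - b[rng.integers(0, len(b), (n_boot, len(b)))].mean(axis=1)
            )
            lo, hi = _bc_interval(boot, est)
            bf = jzs_bf(two_sample_t(a, b).t, len(a), len(b), r_scale=r_scale).bf10
            out.append(GroupContrast(f"scz-control ({task})", float(est), lo, hi, bf, n_boot))
    elif by == "task_within_group":
        for group in sorted(tab["group"].unique()):
            sub = tab[tab["group"] == group]
            wide = sub.pivot(index="subject_id", columns="task", values="slope")
            for t1, t2 in [(TASKS[1], TASKS[0]), (TASKS[2], TASKS[0]), (TASKS[2], TASKS[1])]:
                pair = wide[[t1, t2]].dropna()
                if len(pair) < 2:
                    raise ValueError(f"empty cell: group={group}, tasks={t1}/{t2}")
                d = (pair[t1] - pair[t2]).to_numpy()
                est = d.mean()
                boot = d[rng.integers(0, len(d), (n_boot, len(d)))].mean(axis=1)
                lo, hi = _bc_interval(boot, est)
                bf = jzs_bf(
                    two_sample_t(pair[t1].to_numpy(), pair[t2].to_numpy()).t,
                    len(pair),
                    len(pair),
                    r_scale=r_scale,
                ).bf10
                out.append(
                    GroupContrast(f"{t1}-{t2} ({group})", float(est), lo, hi, bf, n_boot)
                )
    else:
        raise ValueError("by must be 'group_within_task' or 'task_within_group'")
    return out
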