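"""Psychometric fitting and inversion for performance matching.

The calibration session measures memory hit rates at the four encoding
lags, fits a detection psychometric function

    P(yes | contrast) = gamma + (1 - gamma - lambda) * Phi((log C - m) / w)

and inverts it to pick the four contrast levels at which detection hit
rates match the memory hit rates — equating first-order performance across
tasks within each participant.  The guess rate gamma is estimated from
catch trials with add-one (Laplace) smoothing; the lapse rate lambda is
held fixed (a free lapse is not identifiable from three contrast levels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special


class PsychometricError(ValueError):
    """Degenerate data or infeasible inversion target."""


@dataclass(frozen=True)
class PsychometricFit:
    guess: float  # gamma: yes-rate floor (catch-trial false alarms)
    lapse: float  # lambda: miss floor at high contrast (fixed, not fitted)
    location: float  # m: log-contrast at the curve's inflection
    width: float  # w: slope scale (> 0)
    loglik: float = np.nan

    def __post_init__(self):
        if not (0 <= self.guess < 1 and 0 <= self.lapse < 1):
            raise PsychometricError("guess and lapse must lie in [0, 1)")
        if self.guess + self.lapse >= 1:
            raise PsychometricError("guess + lapse must be < 1")
        if self.width <= 0:
            raise PsychometricError("width must be > 0")


def psychometric_yes_rate(fit: PsychometricFit, contrast) -> np.ndarray:
    """Evaluate the fitted curve at one or more contrasts."""
    c = np.asarray(contrast, float)
    if np.any(c <= 0):
        raise PsychometricError("contrast must be > 0")
    z = (np.log(c) - fit.location) / fit.width
    return fit.guess + (1.0 - fit.guess - fit.lapse) * special.ndtr(z)


def fit_psychometric(
    contrasts,
    yes_counts,
    totals,
    catch_yes: int,
    catch_total: int,
    lapse: float = 0.01,
) -> PsychometricFit:
    """Maximum-likelihood fit of the detection psychometric function.

    gamma comes from the catch trials, (catch_yes + 1) / (catch_total + 2),
    so an all-"no" catch block yields a small positive floor rather than a
    hard zero that would make low inversion targets infeasible.  (m, log w)
    maximize the binomial likelihood at the signal contrasts.
    """
    contrasts = np.asarray(contrasts, float)
    yes = np.asarray(yes_counts, int)
    tot = np.asarray(totals, int)
    if len(np.unique(contrasts)) < 3:
        raise PsychometricError("need >= 3 distinct contrast levels")
    if np.any(contrasts <= 0) or np.any(tot <= 0) or np.any(yes < 0) or np.any(yes > tot):
        raise PsychometricError("invalid counts or contrasts")
    if catch_total < 1:
        raise PsychometricError("need at least one catch trial")
    rates = yes / tot
    if np.all(rates == rates[0]) and rates[0] in (0.0, 1.0):
        raise PsychometricError(
            f"degenerate data: every level has yes-rate {rates[0]:.0f}; "
            "the slope is not identifiable"
        )
    gamma = (catch_yes + 1) / (catch_total + 2)
    logc = np.log(contrasts)

    def negll(theta):
        m, logw = theta
        p = gamma + (1 - gamma - lapse) * special.ndtr((logc - m) / np.exp(logw))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -np.sum(yes * np.log(p) + (tot - yes) * np.log1p(-p))

    span = logc.max() - logc.min()
    best = None
    for m0, w0 in [
        (np.average(logc, weights=tot), span / 2),
        (logc.min(), span),
        (logc.max(), span / 4),
    ]:
        res = optimize.minimize(
            negll, [m0, np.log(max(w0, 1e-3))], method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    m, logw = best.x
    return PsychometricFit(
        guess=float(gamma), lapse=float(lapse), location=float(m),
        width=float(np.exp(logw)), loglik=float(-best.fun),
    )


def invert_psychometric(fit: PsychometricFit, target_yes_rate: float) -> float:
    """Contrast at which the fitted curve equals ``target_yes_rate``.

    Closed-form inverse; evaluating the curve at the returned contrast
    reproduces the target to ~1e-9.  Targets outside the achievable band
    (gamma, 1 - lambda) raise a range error naming the bounds.
    """
    lo, hi = fit.guess, 1.0 - fit.lapse
    if not lo < target_yes_rate < hi:
        raise PsychometricError(
            f"target yes-rate {target_yes_rate} outside achievable range "
            f"({lo:.4f}, {hi:.4f})"
        )
    q = (target_yes_rate - fit.guess) / (1.0 - fit.guess - fit.lapse)
    return float(np.exp(fit.location + fit.width * special.ndtri(q)))


def match_contrasts(fit: PsychometricFit, memory_hit_rates) -> np.ndarray:
    """Invert the curve at the four memory hit rates (ordered by lag).

    Lag 1 (largest temporal distance within the encoding stream as tested
    here) is the hardest level; the output preserves lag order.  Range
    errors are re-raised with the offending lag index.
    """
    rates = np.asarray(memory_hit_rates, float)
    if rates.shape != (4,):
        raise PsychometricError("expected 4 memory hit rates (lags 1..4)")
    out = np.empty(4)
    for i, r in enumerate(rates):
        try:
            out[i] = invert_psychometric(fit, r)
        except PsychometricError as err:
            raise PsychometricError(f"lag {i + 1}: {err}") from err
    return out
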