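"""Per-subject and group-level first/second-order summaries and exclusions.

Hit rate is the "yes" rate on strength>0 trials, false-alarm rate the
"yes" rate on strength-0 trials; confidence means are conditioned on
first-order accuracy.  Group tables mirror the descriptive tables of
case-control confidence studies: mean ± SD per group with a t-test and a
JZS Bayes factor per measure, uncorrected for multiple comparisons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bayes import jzs_bf, two_sample_t
from .schema import TASKS, validate_trials

#: Measures entering the group table, with the scale they are reported on.
DEFAULT_MEASURES = (
    "hit_rate",
    "fa_rate",
    "accuracy",
    "mean_confidence_correct",
    "mean_confidence_error",
)


def performance_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """One row per subject x task of first/second-order summaries.

    Cells that cannot be computed (no trials, no errors, no correct
    responses) are NaN, with the supporting counts (``n_trials``,
    ``n_errors``, ...) exposed so that emptiness is explicit rather than a
    silent zero.
    """
    df = validate_trials(trials)
    groups = df.groupby("subject_id")["group"].first()
    rows = []
    for (sid, task), sub in df.groupby(["subject_id", "task"], sort=True):
        signal = sub[sub["strength"] > 0]
        catch = sub[sub["strength"] == 0]
        correct = sub[sub["accuracy"] == 1]
        error = sub[sub["accuracy"] == 0]
        rows.append(
            {
                "subject_id": sid,
                "group": groups[sid],
                "task": task,
                "n_trials": len(sub),
                "n_signal": len(signal),
                "n_catch": len(catch),
                "n_correct": len(correct),
                "n_errors": len(error),
                "hit_rate": (sub["response"].eq("yes") & (sub["strength"] > 0)).sum() / len(signal)
                if len(signal)
                else np.nan,
                "fa_rate": (sub["response"].eq("yes") & (sub["strength"] == 0)).sum() / len(catch)
                if len(catch)
                else np.nan,
                "accuracy": sub["accuracy"].mean(),
                "mean_confidence_correct": correct["confidence"].mean() if len(correct) else np.nan,
                "mean_confidence_error": error["confidence"].mean() if len(error) else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    # make missing subject x task cells explicit
    full = pd.MultiIndex.from_product(
        [sorted(df["subject_id"].unique()), TASKS], names=["subject_id", "task"]
    )
    out = out.set_index(["subject_id", "task"]).reindex(full).reset_index()
    out["group"] = out["subject_id"].map(groups)
    for col in ("n_trials", "n_signal", "n_catch", "n_correct", "n_errors"):
        out[col] = out[col].fillna(0).astype(int)
    return out


def apply_exclusions(
    summaries: pd.DataFrame,
    ceiling_accuracy: float = 0.95,
    min_error_trials: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude subjects unusable for second-order analysis.

    A subject is excluded when accuracy in any task reaches
    ``ceiling_accuracy`` or any task holds fewer than ``min_error_trials``
    error trials (confidence-in-error estimates need errors).  Returns
    (kept summaries, exclusion log with one reason string per ground).
    """
    reasons: dict[str, list[str]] = {}
    for _, row in summaries.iterrows():
        why = []
        if pd.notna(row["accuracy"]) and row["accuracy"] >= ceiling_accuracy:
            why.append(f"ceiling:{row['task']}")
        if row["n_errors"] < min_error_trials:
            why.append(f"too_few_errors:{row['task']}")
        if why:
            reasons.setdefault(row["subject_id"], []).extend(why)
    excluded = pd.DataFrame(
        {
            "subject_id": list(reasons),
            "reasons": [";".join(v) for v in reasons.values()],
        }
    )
    kept = summaries[~summaries["subject_id"].isin(reasons)].reset_index(drop=True)
    return kept, excluded


def group_table(
    summaries: pd.DataFrame,
    measures=DEFAULT_MEASURES,
    r_scale: float = 0.7,
    variant: str = "welch",
) -> pd.DataFrame:
    """Per (task, measure) group contrast: means ± SD, t, p, BF10.

    Uses Welch's t by default (group SDs are rarely equal in case-control
    samples) and the JZS Bayes factor at the given prior scale.  Measures
    with zero pooled variance are reported with missing statistics instead
    of failing the whole table.
    """
    rows = []
    for task in TASKS:
        sub = summaries[summaries["task"] == task]
        ctrl = sub[sub["group"] == "control"]
        scz = sub[sub["group"] == "scz"]
        for measure in measures:
            a = ctrl[measure].dropna().to_numpy()
            b = scz[measure].dropna().to_numpy()
            row = {
                "task": task,
                "measure": measure,
                "control_mean": a.mean() if len(a) else np.nan,
                "control_sd": a.std(ddof=1) if len(a) > 1 else np.nan,
                "scz_mean": b.mean() if len(b) else np.nan,
                "scz_sd": b.std(ddof=1) if len(b) > 1 else np.nan,
                "n_control": len(a),
                "n_scz": len(b),
                "t": np.nan,
                "df": np.nan,
                "p": np.nan,
                "bf10": np.nan,
            }
            if len(a) >= 2 and len(b) >= 2 and (a.std(ddof=1) > 0 or b.std(ddof=1) > 0):
                tt = two_sample_t(a, b, variant=variant)
                row.update(t=tt.t, df=tt.df, p=tt.p)
                row["bf10"] = jzs_bf(tt.t, len(a), len(b), r_scale=r_scale).bf10
            rows.append(row)
    return pd.DataFrame(rows)
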