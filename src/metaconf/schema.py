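"""Trial-level data model, session design and delimited-file I/O.

The paradigm interleaves three yes/no tasks — visual detection, familiarity
and recollection — within blocks of trials.  Every trial carries a stimulus
strength in 0..4: strength 0 tags trials whose correct answer is "no" (catch
trial / new face / other context), strengths 1..4 index increasing evidence
(contrast level for detection, encoding lag for the memory tasks).  Each
first-order response is followed by a confidence rating on a continuous
0-100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

TASKS = ("detection", "familiarity", "recollection")
GROUPS = ("control", "scz")
RESPONSES = ("yes", "no")
STRENGTHS = (0, 1, 2, 3, 4)

#: CSV column order for trial tables.  Optional fields (``contrast``,
#: ``lag``) are written as empty strings where they do not apply.
COLUMNS = (
    "subject_id",
    "group",
    "task",
    "block",
    "trial_index",
    "strength",
    "contrast",
    "lag",
    "response",
    "accuracy",
    "confidence",
)


class DesignError(ValueError):
    """Inconsistent session-design configuration."""


class TrialValidationError(ValueError):
    """A trial table violates the schema; message lists offending rows."""


@dataclass(frozen=True)
class SessionDesign:
    """Block/trial layout of one experimental session.

    Defaults encode the main session: 10 blocks of 30 randomly interleaved
    trials (300 total), 100 trials per task, and a uniform 20 trials per
    (task, strength) cell — so strength-0 trials are exactly 20% of each
    task.
    """

    n_blocks: int = 10
    trials_per_block: int = 30
    tasks: Sequence[str] = TASKS
    strengths_per_task: Mapping[int, int] = field(
        default_factory=lambda: {s: 20 for s in STRENGTHS}
    )

    @property
    def total_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def trials_per_task(self) -> int:
        return int(sum(self.strengths_per_task.values()))

    def strength_priors(self) -> np.ndarray:
        """P(strength class) implied by the per-task cell counts."""
        counts = np.array([self.strengths_per_task.get(s, 0) for s in STRENGTHS], float)
        return counts / counts.sum()

    def validate(self) -> None:
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise DesignError("n_blocks and trials_per_block must be >= 1")
        if any(n < 0 for n in self.strengths_per_task.values()):
            raise DesignError("cell counts must be nonnegative")
        if any(s not in STRENGTHS for s in self.strengths_per_task):
            raise DesignError(f"strength levels must lie in {STRENGTHS}")
        total = len(self.tasks) * self.trials_per_task
        if total != self.total_trials:
            raise DesignError(
                f"cell counts sum to {total} trials but the block layout "
                f"holds {self.total_trials}"
            )


def build_session_design(design: SessionDesign, seed: int) -> pd.DataFrame:
    """Randomly interleave the exact multiset of (task, strength) cells.

    Returns a frame with columns ``block``, ``trial_index``, ``task``,
    ``strength``: a seeded permutation of the design's cells, cut
    sequentially into blocks.  Deterministic given ``seed``.
    """
    design.validate()
    slots = [
        (task, s)
        for task in design.tasks
        for s, n in design.strengths_per_task.items()
        for _ in range(n)
    ]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(slots))
    tasks = np.array([slots[i][0] for i in order])
    strengths = np.array([slots[i][1] for i in order], dtype=int)
    idx = np.arange(len(slots))
    return pd.DataFrame(
        {
            "block": idx // design.trials_per_block + 1,
            "trial_index": idx + 1,
            "task": tasks,
            "strength": strengths,
        }
    )


def _check(mask: pd.Series, message: str, errors: list[str]) -> None:
    bad = np.flatnonzero(mask.to_numpy())
    if bad.size:
        rows = ", ".join(str(i) for i in bad[:10])
        more = "" if bad.size <= 10 else f" (+{bad.size - 10} more)"
        errors.append(f"{message}: rows [{rows}]{more}")


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial table against the schema; return a coerced copy.

    Raises :class:`TrialValidationError` naming offending row positions
    (0-based within the table) for every violated invariant.
    """
    missing = [c for c in COLUMNS if c not in trials.columns]
    if missing:
        raise TrialValidationError(f"missing required columns: {missing}")
    df = trials.loc[:, list(COLUMNS)].reset_index(drop=True).copy()
    df["subject_id"] = df["subject_id"].astype(str)
    for col in ("block", "trial_index", "strength", "accuracy"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    for col in ("contrast", "lag", "confidence"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    errors: list[str] = []
    _check(~df["group"].isin(GROUPS), f"unknown group label (expected {GROUPS})", errors)
    _check(~df["task"].isin(TASKS), f"unknown task label (expected {TASKS})", errors)
    _check(~df["response"].isin(RESPONSES), "response must be 'yes' or 'no'", errors)
    _check(df["block"].isna() | (df["block"] < 1), "block must be an integer >= 1", errors)
    _check(
        df["trial_index"].isna() | (df["trial_index"] < 1),
        "trial_index must be an integer >= 1",
        errors,
    )
    _check(
        df["strength"].isna() | ~df["strength"].isin(STRENGTHS),
        "strength must be an integer in 0..4",
        errors,
    )
    _check(
        df["confidence"].isna() | (df["confidence"] < 0) | (df["confidence"] > 100),
        "confidence must lie in [0, 100]",
        errors,
    )
    # accuracy == 1 iff (response == "yes") == (strength > 0)
    ok = df["response"].isin(RESPONSES) & df["strength"].isin(STRENGTHS)
    expected = (
        (df["response"] == "yes") == (df["strength"] > 0)
    ).astype(int)
    _check(
        ok & (df["accuracy"].isna() | (df["accuracy"] != expected)),
        "accuracy inconsistent with response/strength",
        errors,
    )
    is_det = df["task"] == "detection"
    _check(is_det & df["lag"].notna(), "lag must be empty for detection trials", errors)
    _check(
        ~is_det & (df["strength"] > 0) & (df["lag"] != df["strength"]),
        "lag must equal strength on memory trials with strength > 0",
        errors,
    )
    _check(
        ~is_det & (df["strength"] == 0) & df["lag"].notna(),
        "lag must be empty on strength-0 memory trials",
        errors,
    )
    _check(~is_det & df["contrast"].notna(), "contrast applies to detection only", errors)
    _check(
        is_det & df["contrast"].notna() & (df["contrast"] <= 0),
        "contrast must be > 0 where present",
        errors,
    )
    if errors:
        raise TrialValidationError("; ".join(errors))
    df["lag"] = df["lag"].astype("Int64")
    return df


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as comma-separated UTF-8 with a header row."""
    out = trials.loc[:, list(COLUMNS)]
    out.to_csv(path, index=False, na_rep="")


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial table written by :func:`write_trials`."""
    df = pd.read_csv(
        path,
        dtype={"subject_id": str, "group": str, "task": str, "response": str},
        keep_default_na=True,
    )
    return validate_trials(df)
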