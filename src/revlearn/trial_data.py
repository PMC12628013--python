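"""Domain types and I/O for binary two-choice trial data.

The on-disk format is a long-format CSV with one row per choice trial and a
fixed 13-column dictionary::

    date, ID, age, sex, task, colour, session, trial, succ,
    cumsum, cumTrial, crit, critTrial

``succ`` is 1 for a correct choice (first contact with the rewarded stimulus
S+) and 0 otherwise.  ``cumTrial`` is the 1-based trial number pooled across
sessions within a subject x task, ``cumsum`` the running count of correct
choices, and ``crit``/``critTrial`` record attainment of the configured
trials-to-criterion rule.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "SESSION_TRIAL_CAP",
    "TrialSequence",
    "SessionCapWarning",
    "DataConsistencyWarning",
    "read_trials_csv",
    "write_trials_csv",
    "running_accuracy",
    "parse_trial_date",
]

#: Canonical column order of the trial CSV.
COLUMNS = [
    "date", "ID", "age", "sex", "task", "colour", "session", "trial",
    "succ", "cumsum", "cumTrial", "crit", "critTrial",
]

#: Protocol limit on trials per subject per day (session).
SESSION_TRIAL_CAP = 50

TASKS = ("AL", "RL")
COLOURS = ("LB", "DB")


class SessionCapWarning(UserWarning):
    """A session exceeds the 50-trials-per-day protocol cap."""


class DataConsistencyWarning(UserWarning):
    """Derived CSV columns disagree with their closed-form definitions."""


@dataclass
class TrialSequence:
    """Ordered binary outcomes for one subject in one task.

    Parameters
    ----------
    subject_id : str
        Individual identifier (ring code).
    task : {"AL", "RL"}
        Associative learning (initial discrimination) or reversal learning.
    positive_colour : {"LB", "DB"}
        The rewarded lid colour (S+) for this subject in this task.
    outcomes : array of {0, 1}
        One entry per trial, in cumTrial order; 1 = correct.
    session_index : array of int, optional
        Per-trial session number (nondecreasing, 1-based).  Defaults to
        blocks of at most :data:`SESSION_TRIAL_CAP` trials.
    dates : sequence of str, optional
        Per-trial date strings (mm/dd/Y); only used for inter-task intervals.
    age, sex : str, optional
        Pass-through metadata (plumage age class; mass-determined sex).
    """

    subject_id: str
    task: str
    positive_colour: str = "LB"
    outcomes: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int8))
    session_index: Optional[np.ndarray] = None
    dates: Optional[Sequence[str]] = None
    age: Optional[str] = None
    sex: Optional[str] = None

    def __post_init__(self) -> None:
        self.outcomes = np.asarray(self.outcomes, dtype=np.int8)
        if self.outcomes.size == 0:
            raise ValueError(f"{self.subject_id}/{self.task}: outcomes must be nonempty")
        if not np.isin(self.outcomes, (0, 1)).all():
            raise ValueError(f"{self.subject_id}/{self.task}: outcomes must be binary (0/1)")
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}, got {self.task!r}")
        if self.positive_colour not in COLOURS:
            raise ValueError(f"positive_colour must be one of {COLOURS}, got {self.positive_colour!r}")
        if self.session_index is None:
            n = self.outcomes.size
            self.session_index = np.arange(n) // SESSION_TRIAL_CAP + 1
        else:
            self.session_index = np.asarray(self.session_index, dtype=np.int64)
            if self.session_index.size != self.outcomes.size:
                raise ValueError("session_index must have one entry per trial")
            if (self.session_index < 1).any():
                raise ValueError("session indices must be positive")
            if (np.diff(self.session_index) < 0).any():
                raise ValueError("session_index must be nondecreasing in trial order")
        _, counts = np.unique(self.session_index, return_counts=True)
        if (counts > SESSION_TRIAL_CAP).any():
            warnings.warn(
                f"{self.subject_id}/{self.task}: session exceeds the "
                f"{SESSION_TRIAL_CAP}-trial daily cap (protocol rule, not a data error)",
                SessionCapWarning,
                stacklevel=2,
            )
        if self.dates is not None and len(self.dates) != self.outcomes.size:
            raise ValueError("dates must have one entry per trial")

    @property
    def n(self) -> int:
        """Total number of trials."""
        return int(self.outcomes.size)

    @property
    def trial_numbers(self) -> np.ndarray:
        """1-based cumulative trial numbers (the ``cumTrial`` column)."""
        return np.arange(1, self.n + 1)

    @property
    def proportion_correct(self) -> float:
        return float(self.outcomes.mean())

    def truncated(self, max_trials: int) -> "TrialSequence":
        """Copy restricted to the first ``max_trials`` trials."""
        if max_trials < 1:
            raise ValueError("max_trials must be >= 1")
        m = min(self.n, int(max_trials))
        return replace(
            self,
            outcomes=self.outcomes[:m].copy(),
            session_index=self.session_index[:m].copy(),
            dates=None if self.dates is None else list(self.dates[:m]),
        )


def parse_trial_date(value) -> Optional[_dt.date]:
    """Parse a dictionary-format (mm/dd/Y) date; return None when unparseable.

    Dates only matter for inter-task intervals, so failures degrade to a
    warning rather than an error.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip()
    for fmt in ("%m/%d/%Y", "%m/%d/%y", "%Y-%m-%d"):
        try:
            return _dt.datetime.strptime(text, fmt).date()
        except ValueError:
            continue
    warnings.warn(f"unparseable date {text!r}; treating as opaque", DataConsistencyWarning,
                  stacklevel=2)
    return None


def running_accuracy(seq: TrialSequence, window: int = 12) -> np.ndarray:
    """Trailing-window proportion correct at every trial.

    The value at (1-based) trial ``t`` is the mean outcome over the last
    ``min(t, window)`` trials — the black running-accuracy curve of a
    learning plot.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    y = seq.outcomes.astype(np.float64)
    cs = np.concatenate(([0.0], np.cumsum(y)))
    t = np.arange(1, y.size + 1)
    lo = np.maximum(t - window, 0)
    return (cs[t] - cs[lo]) / np.minimum(t, window)


# ---------------------------------------------------------------------------
# CSV reading / writing


_REQUIRED_MIN = ["ID", "task", "succ", "cumTrial"]


def _sequences_from_frame(df: pd.DataFrame) -> list[TrialSequence]:
    sequences = []
    for (sid, task), grp in df.groupby(["ID", "task"], sort=True):
        grp = grp.sort_values("cumTrial")
        colour = grp["colour"].iloc[0] if "colour" in grp else "LB"
        sequences.append(
            TrialSequence(
                subject_id=str(sid),
                task=str(task),
                positive_colour=str(colour) if colour in COLOURS else "LB",
                outcomes=grp["succ"].to_numpy(),
                session_index=grp["session"].to_numpy() if "session" in grp else None,
                dates=[str(d) for d in grp["date"]] if "date" in grp else None,
                age=str(grp["age"].iloc[0]) if "age" in grp else None,
                sex=str(grp["sex"].iloc[0]) if "sex" in grp else None,
            )
        )
    return sequences


def read_trials_csv(path, strict: bool = False) -> tuple[pd.DataFrame, list[TrialSequence]]:
    """Read a long-format trial CSV.

    Returns the validated table and one :class:`TrialSequence` per
    subject x task, outcomes ordered by ``cumTrial``.

    In strict mode all 13 dictionary columns must be present and the
    derived columns (``cumsum``, ``cumTrial``) must match their closed
    forms; in lax mode inconsistencies are warned about and recomputed.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_MIN if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    if strict:
        missing_all = [c for c in COLUMNS if c not in df.columns]
        if missing_all:
            raise ValueError(f"strict mode: missing column(s): {', '.join(missing_all)}")

    succ = pd.to_numeric(df["succ"], errors="coerce")
    if succ.isna().any() or not succ.isin([0, 1]).all():
        bad = df["succ"][~succ.isin([0, 1])].iloc[0]
        raise ValueError(f"non-binary outcome in succ column: {bad!r}")
    df = df.copy()
    df["succ"] = succ.astype(np.int8)

    dup = df.duplicated(subset=["ID", "task", "cumTrial"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise ValueError(
            f"duplicate (ID, task, cumTrial) = ({row['ID']}, {row['task']}, {row['cumTrial']})"
        )

    df = df.sort_values(["ID", "task", "cumTrial"], kind="stable").reset_index(drop=True)
    grouped = df.groupby(["ID", "task"], sort=False)
    expect_cumtrial = grouped.cumcount() + 1
    expect_cumsum = grouped["succ"].cumsum()

    bad_ct = df["cumTrial"].to_numpy() != expect_cumtrial.to_numpy()
    if bad_ct.any():
        i = int(np.argmax(bad_ct))
        msg = f"cumTrial inconsistent for {df.loc[i, 'ID']}/{df.loc[i, 'task']} (expected contiguous 1..n)"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg + "; recomputing", DataConsistencyWarning, stacklevel=2)
        df["cumTrial"] = expect_cumtrial

    if "cumsum" in df.columns:
        bad_cs = pd.to_numeric(df["cumsum"], errors="coerce").to_numpy() != expect_cumsum.to_numpy()
        if bad_cs.any():
            i = int(np.argmax(bad_cs))
            msg = (
                f"cumsum inconsistent at cumTrial {df.loc[i, 'cumTrial']} "
                f"for {df.loc[i, 'ID']}/{df.loc[i, 'task']}"
            )
            if strict:
                raise ValueError(msg)
            warnings.warn(msg + "; recomputing", DataConsistencyWarning, stacklevel=2)
    df["cumsum"] = expect_cumsum.to_numpy()

    return df, _sequences_from_frame(df)


def write_trials_csv(sequences: Sequence[TrialSequence], path, criterion_spec=None) -> pd.DataFrame:
    """Write sequences as a 13-column dictionary CSV.

    Derived columns (``cumsum``, ``cumTrial``, ``crit``, ``critTrial``) are
    recomputed from the outcomes and the criterion rule, so a read/write
    round trip is the identity on (subject, task, outcomes).
    """
    from .criterion import CriterionSpec, ttc  # local import: criterion builds on this module

    spec = criterion_spec if criterion_spec is not None else CriterionSpec()
    frames = []
    for seq in sequences:
        n = seq.n
        crit_trial = ttc(seq, spec)
        cum_trial = seq.trial_numbers
        # trial number restarts within each session
        session = seq.session_index
        trial_in_session = np.concatenate(
            [np.arange(1, c + 1) for c in np.unique(session, return_counts=True)[1]]
        )
        frames.append(pd.DataFrame({
            "date": list(seq.dates) if seq.dates is not None else [""] * n,
            "ID": seq.subject_id,
            "age": seq.age or "",
            "sex": seq.sex or "",
            "task": seq.task,
            "colour": seq.positive_colour,
            "session": session,
            "trial": trial_in_session,
            "succ": seq.outcomes.astype(int),
            "cumsum": np.cumsum(seq.outcomes).astype(int),
            "cumTrial": cum_trial,
            "crit": (cum_trial >= crit_trial).astype(int) if crit_trial is not None else 0,
            "critTrial": crit_trial if crit_trial is not None else "",
        }))
    out = pd.concat(frames, ignore_index=True)[COLUMNS]
    out.to_csv(path, index=False)
    return out
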