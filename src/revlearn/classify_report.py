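"""Per-subject classification report and cross-task consistency statistics.

Each subject x task sequence is summarized on five axes: trials to
criterion (TTC), initial accuracy (first 12 trials vs simulated chance
percentiles), overall accuracy (exact binomial test), learning-curve slope
(vs an individual simulated null), and — where the criterion was met —
post-criterion accuracy.  The wide table mirrors the conventional
participant-summary layout: one row per subject, an initial-task column
block and a reversal-task block, absent values rendered as an em dash.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .criterion import CriterionSpec, ttc
from .learning_curves import (
    SlopeFit,
    fit_learning_curve,
    initial_accuracy_assess,
    overall_accuracy_assess,
    post_criterion_assess,
    simulate_null_slopes,
    slope_p_value,
)
from .trial_data import TrialSequence, parse_trial_date

__all__ = [
    "ClassifyConfig",
    "LearnerClassification",
    "CohortReport",
    "classify_subject_task",
    "classify_cohort",
    "build_summary_table",
    "parse_summary_table",
    "cross_task_slope_correlation",
    "interval_performance_correlation",
    "inter_task_intervals",
]

_DASH = "—"


@dataclass(frozen=True)
class ClassifyConfig:
    """Shared settings for a classification run.

    ``seed`` is a master seed; per-subject simulation seeds are derived from
    it and a stable hash of (subject, task), so results do not depend on
    processing order.  ``map_separated_to_above`` optionally folds
    separated-positive slope fits into the "above" class for strict
    participant-table emulation.
    """

    criterion: CriterionSpec = field(default_factory=CriterionSpec)
    null_agents: int = 1000
    fp_agents: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    initial_window: int = 12
    conservative_p: bool = False
    map_separated_to_above: bool = False

    def subtask_seed(self, subject_id: str, task: str, salt: str = "") -> int:
        digest = zlib.crc32(f"{subject_id}|{task}|{salt}".encode())
        return int((self.seed * 0x9E3779B1 + digest) % (2**31))


@dataclass
class LearnerClassification:
    """One participant-table row for a subject x task."""

    subject_id: str
    task: str
    n: int
    ttc: Optional[int]
    initial: str   # above | NS | below
    overall: str
    slope_class: str  # above | NS
    separated: bool
    slope_value: float
    slope_p: float
    post_ttc: Optional[str] = None
    post_n: Optional[int] = None


@dataclass
class CohortReport:
    classifications: list
    table: pd.DataFrame
    summary: dict


def classify_subject_task(
    seq: TrialSequence, config: ClassifyConfig = ClassifyConfig()
) -> LearnerClassification:
    """Compose criterion, accuracy and slope assessments into one row."""
    spec = config.criterion
    t = ttc(seq, spec)

    init = initial_accuracy_assess(
        seq, window=config.initial_window, n_agents=config.fp_agents,
        seed=config.subtask_seed(seq.subject_id, seq.task, "initial"),
    )
    overall = overall_accuracy_assess(seq, alpha=config.alpha)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        fit = fit_learning_curve(seq)
        null = simulate_null_slopes(
            n_trials=seq.n, n_agents=config.null_agents,
            seed=config.subtask_seed(seq.subject_id, seq.task, "null"),
        )
        p = slope_p_value(fit, null, conservative=config.conservative_p)
    if fit.separated and fit.slope > 0 and config.map_separated_to_above:
        slope_class = "above"
    else:
        slope_class = "above" if p < config.alpha else "NS"

    post_cls = post_n = None
    if t is not None:
        post, n_post = post_criterion_assess(seq, spec, alpha=config.alpha)
        if post is not None:
            post_cls, post_n = post.classification, n_post
        else:
            post_n = 0

    return LearnerClassification(
        subject_id=seq.subject_id, task=seq.task, n=seq.n, ttc=t,
        initial=init.classification, overall=overall.classification,
        slope_class=slope_class, separated=fit.separated,
        slope_value=fit.slope, slope_p=p,
        post_ttc=post_cls, post_n=post_n,
    )


def classify_cohort(
    sequences: Sequence[TrialSequence], config: ClassifyConfig = ClassifyConfig()
) -> list:
    return [classify_subject_task(s, config) for s in sequences]


def _fmt(value) -> str:
    if value is None:
        return _DASH
    if isinstance(value, float):
        if np.isposinf(value):
            return "+inf"
        if np.isneginf(value):
            return "-inf"
        return f"{value:.4g}"
    return str(value)


_AL_COLS = ["AL_n", "AL_TTC", "AL_initial", "AL_overall", "AL_slope"]
_RL_COLS = ["RL_n", "RL_TTC", "RL_initial", "RL_overall", "RL_postTTC", "RL_post_n", "RL_slope"]


def build_summary_table(
    classifications: Sequence[LearnerClassification],
    path=None,
) -> CohortReport:
    """Assemble the wide participant-summary table and cohort counts.

    Ordered by subject; duplicate subject x task rows are an error.  When
    ``path`` is given the table is also written as TSV.
    """
    if not classifications:
        raise ValueError("no classifications to summarize")
    seen = set()
    for c in classifications:
        key = (c.subject_id, c.task)
        if key in seen:
            raise ValueError(f"duplicate classification for {key}")
        seen.add(key)

    by_subject: dict[str, dict] = {}
    for c in classifications:
        by_subject.setdefault(c.subject_id, {})[c.task] = c
    rows = []
    for sid in sorted(by_subject):
        rec = {"ID": sid}
        al = by_subject[sid].get("AL")
        rl = by_subject[sid].get("RL")
        rec["AL_n"] = _fmt(al.n) if al else _DASH
        rec["AL_TTC"] = _fmt(al.ttc) if al else _DASH
        rec["AL_initial"] = al.initial if al else _DASH
        rec["AL_overall"] = al.overall if al else _DASH
        rec["AL_slope"] = (al.slope_class + ("*" if al.separated else "")) if al else _DASH
        rec["RL_n"] = _fmt(rl.n) if rl else _DASH
        rec["RL_TTC"] = _fmt(rl.ttc) if rl else _DASH
        rec["RL_initial"] = rl.initial if rl else _DASH
        rec["RL_overall"] = rl.overall if rl else _DASH
        rec["RL_postTTC"] = _fmt(rl.post_ttc) if rl else _DASH
        rec["RL_post_n"] = _fmt(rl.post_n) if rl else _DASH
        rec["RL_slope"] = (rl.slope_class + ("*" if rl.separated else "")) if rl else _DASH
        rows.append(rec)
    table = pd.DataFrame(rows, columns=["ID"] + _AL_COLS + _RL_COLS)

    al_rows = [c for c in classifications if c.task == "AL"]
    rl_rows = [c for c in classifications if c.task == "RL"]

    def _counts(rows):
        ttc_set = {c.subject_id for c in rows if c.ttc is not None}
        lc_set = {c.subject_id for c in rows if c.slope_class == "above"}
        return {
            "n": len(rows),
            "ttc_birds": len(ttc_set),
            "lc_learners": len(lc_set),
            "ttc_only": len(ttc_set - lc_set),
            "lc_only": len(lc_set - ttc_set),
            "both": len(ttc_set & lc_set),
        }

    summary = {"AL": _counts(al_rows), "RL": _counts(rl_rows)}
    if path is not None:
        table.to_csv(path, sep="\t", index=False)
    return CohortReport(classifications=list(classifications), table=table, summary=summary)


def parse_summary_table(path_or_buf) -> pd.DataFrame:
    """Read back an emitted TSV report (dash = absent)."""
    return pd.read_csv(path_or_buf, sep="\t", dtype=str, keep_default_na=False)


# ---------------------------------------------------------------------------
# Cross-task consistency


def _slope_of(x) -> float:
    if isinstance(x, SlopeFit):
        return x.slope
    if isinstance(x, LearnerClassification):
        return x.slope_value
    return float(x)


def cross_task_slope_correlation(al_fits: dict, rl_fits: dict):
    """Pearson correlation of paired finite learning slopes across tasks.

    ``al_fits`` and ``rl_fits`` map subject_id -> SlopeFit (or slope value).
    Separated (infinite) fits are excluded with a logged count; at least
    three finite pairs are required.
    """
    shared = sorted(set(al_fits) & set(rl_fits))
    pairs = [(_slope_of(al_fits[s]), _slope_of(rl_fits[s])) for s in shared]
    finite = [(a, b) for a, b in pairs if np.isfinite(a) and np.isfinite(b)]
    n_excluded = len(pairs) - len(finite)
    if n_excluded:
        warnings.warn(
            f"excluded {n_excluded} pair(s) with separated (infinite) slopes",
            UserWarning, stacklevel=2,
        )
    if len(finite) < 3:
        raise ValueError("need at least 3 paired subjects with finite slopes")
    a, b = map(np.asarray, zip(*finite))
    r = stats.pearsonr(a, b)
    return float(r.statistic), float(r.pvalue), len(finite)


def interval_performance_correlation(intervals_days, rl_proportions):
    """Spearman rank correlation of inter-task interval vs reversal-task
    overall proportion correct."""
    x = np.asarray(intervals_days, dtype=float)
    y = np.asarray(rl_proportions, dtype=float)
    if x.size != y.size:
        raise ValueError("paired inputs required")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("degenerate (constant) input; rank correlation undefined")
    r = stats.spearmanr(x, y)
    return float(r.statistic), float(r.pvalue)


def inter_task_intervals(sequences: Sequence[TrialSequence]) -> dict:
    """Days between the last initial-task session and the first reversal
    session, per subject with dated data in both tasks."""
    al_last: dict[str, object] = {}
    rl_first: dict[str, object] = {}
    for s in sequences:
        if s.dates is None:
            continue
        parsed = [parse_trial_date(d) for d in s.dates]
        parsed = [d for d in parsed if d is not None]
        if not parsed:
            continue
        if s.task == "AL":
            al_last[s.subject_id] = max(parsed)
        elif s.task == "RL":
            rl_first[s.subject_id] = min(parsed)
    return {
        sid: (rl_first[sid] - al_last[sid]).days
        for sid in al_last.keys() & rl_first.keys()
    }
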