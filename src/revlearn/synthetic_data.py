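"""Synthetic trial sequences and cohorts.

Generators produce the statistical structure the analysis assumes — not a
behavioural simulation.  Each agent is a marginal-probability model: its
per-trial success probability is a function of trial number only, and
outcomes are independent Bernoulli draws from it.  Phenotypes:

``random``
    chance agent, p = 0.5 at every trial (the null of every test here);
``constant_bias``
    fixed p != 0.5 (e.g. an immediate colour preference);
``logistic_learner``
    p(t) = logistic(a + b t), the gradual improver the slope test targets;
``step_learner``
    p_before until a switch trial, p_after from then on (insight-like jump);
``perseverative_reverser``
    logistic ramp starting below chance (keeps choosing the formerly
    rewarded stimulus) and rising toward p_end — the reversal-phase
    phenotype.

Cohorts mimic a field study: ~32 subjects in the initial association task,
roughly 18 of which continue to the reversal, heterogeneous trial counts,
sessions capped at 50 trials/day, and pseudo-random counterbalanced
rewarded colours.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .trial_data import SESSION_TRIAL_CAP, TrialSequence, write_trials_csv

__all__ = [
    "AgentSpec",
    "CohortSpec",
    "success_probability",
    "generate_agent",
    "generate_cohort",
    "generate_glmm_cohort",
]

AGENT_KINDS = (
    "random", "constant_bias", "logistic_learner", "step_learner",
    "perseverative_reverser",
)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


@dataclass(frozen=True)
class AgentSpec:
    """One simulated subject's success-probability model.

    Use the classmethod constructors; parameter fields are kind-specific.
    """

    kind: str
    n_trials: int
    seed: Optional[int] = None
    p: Optional[float] = None               # constant_bias
    intercept: Optional[float] = None       # logistic_learner (log-odds)
    slope: Optional[float] = None           # logistic_learner (log-odds/trial)
    switch_trial: Optional[int] = None      # step_learner
    p_before: Optional[float] = None
    p_after: Optional[float] = None
    p_start: Optional[float] = None         # perseverative_reverser
    p_end: Optional[float] = None
    midpoint: Optional[float] = None        # ramp midpoint (trial)
    steepness: Optional[float] = None       # ramp steepness (1/trials)

    def __post_init__(self) -> None:
        if self.kind not in AGENT_KINDS:
            raise ValueError(f"unknown agent kind {self.kind!r}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.kind == "constant_bias" and not (0.0 < self.p < 1.0):
            raise ValueError("constant_bias requires p in (0, 1)")
        if self.kind == "perseverative_reverser" and not (0.0 < self.p_start < 0.5):
            raise ValueError("perseverative_reverser must start below chance")

    @classmethod
    def random(cls, n_trials: int, seed: Optional[int] = None) -> "AgentSpec":
        return cls(kind="random", n_trials=n_trials, seed=seed)

    @classmethod
    def constant_bias(cls, p: float, n_trials: int, seed: Optional[int] = None) -> "AgentSpec":
        return cls(kind="constant_bias", n_trials=n_trials, seed=seed, p=p)

    @classmethod
    def logistic_learner(cls, intercept: float, slope: float, n_trials: int,
                         seed: Optional[int] = None) -> "AgentSpec":
        return cls(kind="logistic_learner", n_trials=n_trials, seed=seed,
                   intercept=intercept, slope=slope)

    @classmethod
    def step_learner(cls, switch_trial: int, p_before: float, p_after: float,
                     n_trials: int, seed: Optional[int] = None) -> "AgentSpec":
        return cls(kind="step_learner", n_trials=n_trials, seed=seed,
                   switch_trial=switch_trial, p_before=p_before, p_after=p_after)

    @classmethod
    def perseverative_reverser(cls, p_start: float, p_end: float, midpoint: float,
                               steepness: float, n_trials: int,
                               seed: Optional[int] = None) -> "AgentSpec":
        return cls(kind="perseverative_reverser", n_trials=n_trials, seed=seed,
                   p_start=p_start, p_end=p_end, midpoint=midpoint,
                   steepness=steepness)


def success_probability(spec: AgentSpec, t) -> np.ndarray:
    """Per-trial success probability of an agent at 1-based trial(s) t."""
    t = np.asarray(t, dtype=np.float64)
    if np.any(t < 1) or np.any(t > spec.n_trials):
        raise ValueError("trial index out of range 1..n_trials")
    if spec.kind == "random":
        out = np.full_like(t, 0.5)
    elif spec.kind == "constant_bias":
        out = np.full_like(t, spec.p)
    elif spec.kind == "logistic_learner":
        out = _logistic(spec.intercept + spec.slope * t)
    elif spec.kind == "step_learner":
        out = np.where(t < spec.switch_trial, spec.p_before, spec.p_after)
    else:  # perseverative_reverser: logistic ramp p_start -> p_end
        ramp = _logistic(spec.steepness * (t - spec.midpoint))
        out = spec.p_start + (spec.p_end - spec.p_start) * ramp
    return out if out.ndim else float(out)


def generate_agent(
    spec: AgentSpec,
    subject_id: str = "SIM",
    task: str = "AL",
    positive_colour: str = "LB",
    rng: Optional[np.random.Generator] = None,
    session_cap: int = SESSION_TRIAL_CAP,
    dates: Optional[Sequence[str]] = None,
) -> TrialSequence:
    """Draw one Bernoulli outcome sequence from an agent's mean function.

    Session indices are assigned in blocks of at most ``session_cap`` trials.
    Deterministic for a fixed ``spec.seed`` (or an explicitly passed rng).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    t = np.arange(1, spec.n_trials + 1)
    p = np.asarray(success_probability(spec, t))
    outcomes = (rng.random(spec.n_trials) < p).astype(np.int8)
    session = np.arange(spec.n_trials) // session_cap + 1
    return TrialSequence(
        subject_id=subject_id, task=task, positive_colour=positive_colour,
        outcomes=outcomes, session_index=session, dates=dates,
    )


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Shape of a synthetic field cohort.

    The default phenotype mixture and trial-count distributions are chosen to
    resemble a wild two-task study: most subjects contribute 10-60 initial
    trials (a few far more), reversal sequences run longer, roughly a third
    of subjects are gradual learners, and a block of subjects shows an
    immediate strong colour preference (high constant p).
    """

    n_subjects: int = 32
    rl_probability: float = 18 / 32
    session_cap: int = SESSION_TRIAL_CAP
    master_seed: int = 0
    # (kind, weight) mixtures; parameters are drawn per subject
    al_mixture: tuple = (
        ("logistic_learner", 0.30),
        ("constant_bias", 0.25),
        ("random", 0.35),
        ("step_learner", 0.10),
    )
    rl_mixture: tuple = (
        ("perseverative_reverser", 0.40),
        ("random", 0.40),
        ("logistic_learner", 0.20),
    )

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.0 <= self.rl_probability <= 1.0:
            raise ValueError("rl_probability must be a probability")


def _draw_n_trials(rng: np.random.Generator, task: str) -> int:
    # AL counts are right-skewed around ~36; RL sequences run longer (~65)
    if task == "AL":
        n = int(np.round(np.exp(rng.normal(np.log(30.0), 0.6))))
    else:
        n = int(np.round(rng.normal(68.0, 35.0)))
    return int(np.clip(n, 4, 136))


def _draw_agent(rng: np.random.Generator, kind: str, n: int, task: str) -> AgentSpec:
    if kind == "random":
        return AgentSpec.random(n)
    if kind == "constant_bias":
        return AgentSpec.constant_bias(p=rng.uniform(0.6, 0.9), n_trials=n)
    if kind == "logistic_learner":
        return AgentSpec.logistic_learner(
            intercept=rng.uniform(-1.0, 0.0), slope=rng.uniform(0.04, 0.15), n_trials=n,
        )
    if kind == "step_learner":
        s = int(rng.integers(5, max(6, n // 2 + 1)))
        return AgentSpec.step_learner(switch_trial=s, p_before=0.45, p_after=0.9, n_trials=n)
    # perseverative_reverser
    return AgentSpec.perseverative_reverser(
        p_start=rng.uniform(0.15, 0.4), p_end=rng.uniform(0.6, 0.9),
        midpoint=rng.uniform(10.0, min(50.0, max(11.0, n * 0.6))),
        steepness=rng.uniform(0.1, 0.4), n_trials=n,
    )


def _session_dates(start: _dt.date, session_index: np.ndarray) -> list[str]:
    return [
        (start + _dt.timedelta(days=int(s) - 1)).strftime("%m/%d/%Y")
        for s in session_index
    ]


def generate_cohort(spec: CohortSpec = CohortSpec()):
    """Generate a full two-task cohort.

    Returns ``(sequences, table)``: the in-memory :class:`TrialSequence`
    list (AL for every subject, RL for a sampled subset) and the 13-column
    trial table.  Per-subject random substreams are spawned from the master
    seed, so cohorts are reproducible and subjects independent.  The
    reversal task swaps the rewarded colour and starts 1-11 days after the
    last initial-task session.
    """
    root = np.random.SeedSequence(spec.master_seed)
    streams = [np.random.default_rng(s) for s in root.spawn(spec.n_subjects)]
    kinds_al = [k for k, _ in spec.al_mixture]
    w_al = np.array([w for _, w in spec.al_mixture], dtype=float)
    w_al /= w_al.sum()
    kinds_rl = [k for k, _ in spec.rl_mixture]
    w_rl = np.array([w for _, w in spec.rl_mixture], dtype=float)
    w_rl /= w_rl.sum()

    start_date = _dt.date(2024, 8, 17)
    sequences: list[TrialSequence] = []
    for i, rng in enumerate(streams):
        sid = f"S{i + 1:02d}"
        colour_al = "LB" if (i + int(rng.integers(0, 2))) % 2 == 0 else "DB"
        age = str(rng.choice(["HY", "JUV", "SA", "AD"], p=[0.4, 0.4, 0.1, 0.1]))
        sex = str(rng.choice(["F", "M"]))

        n_al = _draw_n_trials(rng, "AL")
        agent_al = _draw_agent(rng, kinds_al[int(rng.choice(len(kinds_al), p=w_al))], n_al, "AL")
        seq_al = generate_agent(agent_al, subject_id=sid, task="AL",
                                positive_colour=colour_al, rng=rng,
                                session_cap=spec.session_cap)
        al_dates = _session_dates(start_date, seq_al.session_index)
        seq_al = TrialSequence(
            subject_id=sid, task="AL", positive_colour=colour_al,
            outcomes=seq_al.outcomes, session_index=seq_al.session_index,
            dates=al_dates, age=age, sex=sex,
        )
        sequences.append(seq_al)

        if rng.random() < spec.rl_probability:
            n_rl = _draw_n_trials(rng, "RL")
            agent_rl = _draw_agent(rng, kinds_rl[int(rng.choice(len(kinds_rl), p=w_rl))], n_rl, "RL")
            colour_rl = "DB" if colour_al == "LB" else "LB"
            seq_rl = generate_agent(agent_rl, subject_id=sid, task="RL",
                                    positive_colour=colour_rl, rng=rng,
                                    session_cap=spec.session_cap)
            gap = int(np.clip(1 + rng.poisson(1.6), 1, 11))
            rl_start = start_date + _dt.timedelta(
                days=int(seq_al.session_index.max()) - 1 + gap)
            rl_dates = _session_dates(rl_start, seq_rl.session_index)
            seq_rl = TrialSequence(
                subject_id=sid, task="RL", positive_colour=colour_rl,
                outcomes=seq_rl.outcomes, session_index=seq_rl.session_index,
                dates=rl_dates, age=age, sex=sex,
            )
            sequences.append(seq_rl)

    import io

    buf = io.StringIO()
    table = write_trials_csv(sequences, buf)
    return sequences, table


# ---------------------------------------------------------------------------
# Mixed-model cohorts (known fixed and random effects)


def generate_glmm_cohort(
    beta: dict,
    re_sd: Optional[dict] = None,
    n_subjects: int = 32,
    rl_probability: float = 18 / 32,
    n_trials_range: tuple[int, int] = (10, 130),
    seed: int = 0,
) -> list[TrialSequence]:
    """Cohort whose success probabilities follow the population model exactly.

    ``beta`` maps fixed-effect terms (``intercept``, ``trial_z``, ``task_c``,
    ``colour_c``, ``trial_z:task_c``) to log-odds coefficients on the same
    standardized/centred scale the model is fitted on; ``re_sd`` maps random
    terms (``intercept``, ``trial_z``) to per-subject SDs.  Used for
    parameter-recovery checks: the generating coefficients are the truth the
    fit should recover.
    """
    re_sd = re_sd or {}
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        sid = f"G{i + 1:02d}"
        colour = "LB" if i % 2 == 0 else "DB"
        tasks = ["AL"] + (["RL"] if rng.random() < rl_probability else [])
        for task in tasks:
            n = int(rng.integers(n_trials_range[0], n_trials_range[1] + 1))
            rows.append((sid, task, colour, n))

    # assemble covariates first so standardization matches the fitted design
    recs = []
    for sid, task, colour, n in rows:
        for t in range(1, n + 1):
            recs.append((sid, task, colour, t))
    df = pd.DataFrame(recs, columns=["ID", "task", "colour", "cumTrial"])
    trial = df["cumTrial"].to_numpy(dtype=float)
    trial_z = (trial - trial.mean()) / trial.std(ddof=1)
    task_code = (df["task"] == "RL").to_numpy(dtype=float)
    task_c = task_code - task_code.mean()
    col_code = (df["colour"] == "DB").to_numpy(dtype=float)
    colour_c = col_code - col_code.mean()

    eta = (
        beta.get("intercept", 0.0)
        + beta.get("trial_z", 0.0) * trial_z
        + beta.get("task_c", 0.0) * task_c
        + beta.get("colour_c", 0.0) * colour_c
        + beta.get("trial_z:task_c", 0.0) * trial_z * task_c
    )
    subjects = df["ID"].to_numpy()
    for sid in np.unique(subjects):
        mask = subjects == sid
        eta[mask] += rng.normal(0.0, re_sd.get("intercept", 0.0))
        if re_sd.get("trial_z", 0.0) > 0:
            eta[mask] += rng.normal(0.0, re_sd["trial_z"]) * trial_z[mask]
    y = (rng.random(eta.size) < _logistic(eta)).astype(np.int8)
    df["succ"] = y

    sequences = []
    for (sid, task), grp in df.groupby(["ID", "task"], sort=True):
        grp = grp.sort_values("cumTrial")
        sequences.append(TrialSequence(
            subject_id=str(sid), task=str(task),
            positive_colour=str(grp["colour"].iloc[0]),
            outcomes=grp["succ"].to_numpy(),
        ))
    return sequences
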