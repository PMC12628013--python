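"""The trials-to-criterion (TTC) rule and its false-positive behaviour.

A subject "reaches criterion" at the first trial t where at least
``required_k`` of the last ``min(t, window_w)`` choices were correct
(default: 10 of 12).  Because the window slides, a chance-level agent gets a
fresh chance at every trial, so the probability of a false positive grows
with the trial horizon — the repeated-testing inflation this package
quantifies.  Two independent routes compute that attainment probability:

* :func:`criterion_fp_curve_mc` — Monte Carlo over simulated Bernoulli agents;
* :func:`criterion_probability_exact` — exact dynamic programming over the
  2^(window_w - 1) states of recent outcomes, with an absorbing "met" state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import stats

from .trial_data import TrialSequence

__all__ = [
    "CriterionSpec",
    "FalsePositiveCurve",
    "ttc",
    "window_counts",
    "window_pass_probability",
    "criterion_probability_exact",
    "criterion_attainment_exact",
    "criterion_fp_curve_mc",
    "criterion_fp_curve_exact",
    "ttc_batch",
]

_DP_MAX_WINDOW = 20


@dataclass(frozen=True)
class CriterionSpec:
    """The x-of-y sliding-window rule.

    ``allow_short_windows`` controls whether the criterion can be met before
    ``window_w`` trials exist (the window is then the whole prefix).  The
    short-window convention is the default: a perfect opening run of
    ``required_k`` trials counts.
    """

    window_w: int = 12
    required_k: int = 10
    allow_short_windows: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.required_k <= self.window_w):
            raise ValueError(
                f"need 1 <= required_k <= window_w, got k={self.required_k}, w={self.window_w}"
            )


@dataclass
class FalsePositiveCurve:
    """Cumulative criterion-attainment proportion per trial horizon."""

    spec: CriterionSpec
    chance_p: float
    horizons: np.ndarray
    fp_rate: np.ndarray
    n_agents: Optional[int]
    seed: Optional[int]
    method: str  # "monte_carlo" | "exact"

    def at(self, horizon: int) -> float:
        """Attainment proportion at a 1-based horizon."""
        i = int(np.searchsorted(self.horizons, horizon))
        if i >= self.horizons.size or self.horizons[i] != horizon:
            raise ValueError(f"horizon {horizon} not on the curve")
        return float(self.fp_rate[i])


def _outcomes(seq: Union[TrialSequence, np.ndarray]) -> np.ndarray:
    if isinstance(seq, TrialSequence):
        return seq.outcomes
    return np.asarray(seq, dtype=np.int8)


def window_counts(seq, spec: CriterionSpec = CriterionSpec()) -> np.ndarray:
    """Count of correct outcomes in the last min(t, window_w) trials, per t."""
    y = _outcomes(seq)
    cs = np.concatenate(([0], np.cumsum(y)))
    t = np.arange(1, y.size + 1)
    lo = np.maximum(t - spec.window_w, 0)
    return cs[t] - cs[lo]


def ttc(seq, spec: CriterionSpec = CriterionSpec()) -> Optional[int]:
    """Trials to criterion: smallest t with >= required_k correct in the
    trailing window, or None if the criterion is never met."""
    counts = window_counts(seq, spec)
    met = counts >= spec.required_k
    if not spec.allow_short_windows:
        met[: spec.window_w - 1] = False
    idx = np.flatnonzero(met)
    return int(idx[0] + 1) if idx.size else None


def ttc_batch(outcome_matrix: np.ndarray, spec: CriterionSpec = CriterionSpec()) -> np.ndarray:
    """Vectorised :func:`ttc` over rows of a (n_agents, n_trials) 0/1 matrix.

    Returns a float array of first-attainment trials, ``inf`` where the
    criterion is never met.
    """
    y = np.asarray(outcome_matrix)
    if y.ndim != 2:
        raise ValueError("expected a 2-D (agents x trials) matrix")
    cs = np.concatenate([np.zeros((y.shape[0], 1), dtype=np.int64), np.cumsum(y, axis=1)], axis=1)
    t = np.arange(1, y.shape[1] + 1)
    lo = np.maximum(t - spec.window_w, 0)
    counts = cs[:, t] - cs[:, lo]
    met = counts >= spec.required_k
    if not spec.allow_short_windows:
        met[:, : spec.window_w - 1] = False
    any_met = met.any(axis=1)
    first = np.argmax(met, axis=1) + 1.0
    first[~any_met] = np.inf
    return first


def window_pass_probability(spec: CriterionSpec, p: float) -> float:
    """Exact upper-tail probability of >= required_k successes in a single
    block of window_w Bernoulli(p) trials — the naive "one block" logic the
    sliding criterion is often justified by (0.019 for 10-of-12 at p=0.5)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    return float(stats.binom.sf(spec.required_k - 1, spec.window_w, p))


def criterion_attainment_exact(
    spec: CriterionSpec, p: float, max_horizon: int
) -> np.ndarray:
    """Exact P(criterion met by trial t) for t = 1..max_horizon.

    Dynamic programme over the last (window_w - 1) outcomes encoded as bits
    of an integer state, with absorbed probability mass accumulated once the
    trailing-window count reaches required_k.  Early trials (t < window_w)
    are handled by the same states: unobserved leading positions hold zeros,
    and the window is then the whole prefix.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if max_horizon < 1:
        raise ValueError("max_horizon must be >= 1")
    if spec.window_w > _DP_MAX_WINDOW:
        raise ValueError(f"state enumeration guarded at window_w <= {_DP_MAX_WINDOW}")
    w, k = spec.window_w, spec.required_k
    n_states = 1 << (w - 1)
    mask = n_states - 1
    states = np.arange(n_states)
    popcount = np.array([bin(s).count("1") for s in states])
    next0 = (states << 1) & mask
    next1 = ((states << 1) | 1) & mask

    prob = np.zeros(n_states)
    prob[0] = 1.0
    absorbed = 0.0
    out = np.empty(max_horizon)
    for t in range(1, max_horizon + 1):
        # trailing-window success count after appending outcome o is
        # popcount(state) + o (state holds exactly the relevant history)
        meets0 = popcount >= k
        meets1 = popcount + 1 >= k
        if not spec.allow_short_windows and t < w:
            meets0 = np.zeros(n_states, dtype=bool)
            meets1 = np.zeros(n_states, dtype=bool)
        absorbed += (1 - p) * prob[meets0].sum() + p * prob[meets1].sum()
        new = np.zeros(n_states)
        live0 = prob * (1 - p)
        live0[meets0] = 0.0
        live1 = prob * p
        live1[meets1] = 0.0
        np.add.at(new, next0, live0)
        np.add.at(new, next1, live1)
        prob = new
        out[t - 1] = absorbed
    return out


def criterion_probability_exact(spec: CriterionSpec, p: float, horizon: int) -> float:
    """Exact probability that a Bernoulli(p) agent meets the criterion at
    some trial <= horizon."""
    return float(criterion_attainment_exact(spec, p, horizon)[-1])


def criterion_fp_curve_mc(
    spec: CriterionSpec = CriterionSpec(),
    p: float = 0.5,
    max_horizon: int = 75,
    n_agents: int = 10_000,
    seed: Optional[int] = None,
) -> FalsePositiveCurve:
    """Monte-Carlo false-positive curve.

    Simulates one cohort of ``n_agents`` i.i.d. Bernoulli(p) sequences of
    length ``max_horizon`` and, for every horizon t, reports the proportion
    of agents whose TTC is <= t.  Reusing a single cohort across horizons
    makes the curve exactly nondecreasing (attainment is cumulative).
    """
    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")
    rng = np.random.default_rng(seed)
    y = (rng.random((n_agents, max_horizon)) < p).astype(np.int8)
    first = ttc_batch(y, spec)
    horizons = np.arange(1, max_horizon + 1)
    fp_rate = (first[:, None] <= horizons[None, :]).mean(axis=0)
    return FalsePositiveCurve(
        spec=spec, chance_p=p, horizons=horizons, fp_rate=fp_rate,
        n_agents=n_agents, seed=seed, method="monte_carlo",
    )


def criterion_fp_curve_exact(
    spec: CriterionSpec = CriterionSpec(), p: float = 0.5, max_horizon: int = 75
) -> FalsePositiveCurve:
    """Exact counterpart of :func:`criterion_fp_curve_mc` via the DP."""
    rate = criterion_attainment_exact(spec, p, max_horizon)
    return FalsePositiveCurve(
        spec=spec, chance_p=p, horizons=np.arange(1, max_horizon + 1),
        fp_rate=rate, n_agents=None, seed=None, method="exact",
    )
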