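"""Population-level binomial mixed model of trial success.

The model predicts per-trial success (logit link) from standardized trial
number, centred task code, centred stimulus-colour code and optionally the
trial x task interaction, with per-subject random intercepts and random
slopes.  Inference follows a likelihood-ratio workflow: the full model is
compared against a null excluding the test predictors, then single terms
are dropped starting with the interaction.  A trimmed refit on the first 40
trials per subject per task checks robustness to unequal trial counts.

Estimation maximizes the Laplace-approximated marginal likelihood.  Random
effects are parametrized as b_i = L u_i with u_i ~ N(0, I) and L the
lower-triangular Cholesky factor of the between-subject covariance, so the
objective is defined for singular covariances and the per-subject inner
problem (penalized logistic mode finding) is strictly concave.  On failure
to converge, the random structure is simplified along a fixed ladder:
drop slope correlations, drop the colour slope, drop the interaction slope,
fall back to intercepts only; the rung actually used is recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trial_data import TrialSequence

__all__ = [
    "ModelDesign",
    "RandomStructure",
    "PopulationFit",
    "ModelComparison",
    "build_design",
    "fit_population_model",
    "likelihood_ratio_test",
    "full_null_comparison",
    "single_term_tests",
    "trim_trials",
    "MAXIMAL_RANDOM_STRUCTURE",
]

FIXED_TERMS_FULL = ("intercept", "trial_z", "task_c", "colour_c", "trial_z:task_c")


@dataclass(frozen=True)
class RandomStructure:
    """Per-subject random-effect terms.

    ``terms`` are column names of the random-effects design ("intercept",
    "trial_z:task_c", "colour_c", "trial_z", "task_c"); ``correlated``
    selects a full Cholesky covariance versus independent (diagonal) terms.
    """

    terms: tuple = ("intercept",)
    correlated: bool = True

    @property
    def q(self) -> int:
        return len(self.terms)

    @property
    def n_params(self) -> int:
        return self.q * (self.q + 1) // 2 if self.correlated else self.q

    def describe(self) -> str:
        kind = "correlated" if self.correlated and self.q > 1 else "independent"
        return f"({' + '.join(self.terms)} | subject), {kind}"


#: Random slopes for the trial x task interaction and colour, plus intercepts.
MAXIMAL_RANDOM_STRUCTURE = RandomStructure(
    terms=("intercept", "trial_z:task_c", "colour_c"), correlated=True,
)


@dataclass
class ModelDesign:
    """Per-trial model frame with the coding map used to build it."""

    frame: pd.DataFrame  # subject_id, success, trial_z, task_c, colour_c
    include_interaction: bool
    coding: dict

    @property
    def n_obs(self) -> int:
        return len(self.frame)

    @property
    def n_subjects(self) -> int:
        return self.frame["subject_id"].nunique()

    def fixed_terms(self) -> tuple:
        if self.include_interaction:
            return FIXED_TERMS_FULL
        return tuple(t for t in FIXED_TERMS_FULL if t != "trial_z:task_c")

    def column(self, term: str) -> np.ndarray:
        f = self.frame
        if term == "intercept":
            return np.ones(len(f))
        if term == "trial_z:task_c":
            return (f["trial_z"] * f["task_c"]).to_numpy()
        return f[term].to_numpy()


def build_design(
    sequences: Sequence[TrialSequence], include_interaction: bool = True
) -> ModelDesign:
    """Assemble the model frame from trial sequences.

    Trial number (pooled across sessions) is z-scored over the included
    rows (sample SD, n-1 denominator); binary task and colour codes are
    centred on their observed means, so with balance they become -0.5/+0.5.
    The coding map records the constants needed to reproduce the scaling.
    """
    subjects = {s.subject_id for s in sequences}
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects for a mixed model")
    recs = []
    for s in sequences:
        for t, y in zip(s.trial_numbers, s.outcomes):
            recs.append((s.subject_id, s.task, s.positive_colour, int(t), int(y)))
    df = pd.DataFrame(recs, columns=["subject_id", "task", "colour", "cumTrial", "success"])

    task_code = (df["task"] == "RL").astype(float)
    colour_code = (df["colour"] == "DB").astype(float)
    if include_interaction and task_code.nunique() < 2:
        raise ValueError("task has a single level; cannot include the trial x task interaction")

    trial = df["cumTrial"].astype(float)
    mu, sd = trial.mean(), trial.std(ddof=1)
    if sd == 0:
        raise ValueError("trial number has zero variance")
    frame = pd.DataFrame({
        "subject_id": df["subject_id"],
        "success": df["success"].astype(np.int8),
        "trial_z": (trial - mu) / sd,
        "task_c": task_code - task_code.mean(),
        "colour_c": colour_code - colour_code.mean(),
    })
    coding = {
        "trial_mean": float(mu), "trial_sd": float(sd),
        "task_reference": "AL", "task_mean": float(task_code.mean()),
        "colour_reference": "LB", "colour_mean": float(colour_code.mean()),
    }
    return ModelDesign(frame=frame, include_interaction=include_interaction, coding=coding)


@dataclass
class PopulationFit:
    fixed_effects: pd.DataFrame  # index: term; columns: estimate, se
    variance_components: pd.DataFrame  # index: term; column: sd (+ correlations attr)
    random_structure: RandomStructure
    log_likelihood: float
    converged: bool
    n_obs: int
    n_subjects: int
    n_params: int
    fallback_rung: int = 0  # 0 = requested structure fitted as-is
    correlations: Optional[np.ndarray] = None
    fixed_terms: tuple = ()

    def coef(self, term: str) -> float:
        return float(self.fixed_effects.loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.fixed_effects.loc[term, "se"])

    def confint(self, term: str, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        return (self.coef(term) - z * self.se(term), self.coef(term) + z * self.se(term))


@dataclass
class ModelComparison:
    """Likelihood-ratio test between nested fits."""

    statistic: float
    df: int
    p_value: float


# ---------------------------------------------------------------------------
# Laplace machinery


def _theta_to_L(theta: np.ndarray, q: int, correlated: bool) -> np.ndarray:
    L = np.zeros((q, q))
    if correlated:
        idx = np.tril_indices(q)
        L[idx] = theta
    else:
        np.fill_diagonal(L, theta)
    return L


class _LaplaceProblem:
    """Negative Laplace-approximated log-likelihood as a function of
    (beta, theta), with per-subject warm-started inner Newton solves."""

    def __init__(self, y, X, Z, groups, q, correlated):
        self.q = q
        self.correlated = correlated
        order = np.argsort(groups, kind="stable")
        self.y = y[order]
        self.X = X[order]
        self.Z = Z[order]
        g = groups[order]
        _, starts = np.unique(g, return_index=True)
        bounds = np.append(np.sort(starts), g.size)
        self.slices = [slice(bounds[i], bounds[i + 1]) for i in range(bounds.size - 1)]
        self.n_subjects = len(self.slices)
        self._warm = [np.zeros(q) for _ in range(self.n_subjects)]
        self.p = X.shape[1]

    def _subject_nll(self, y, X, Z, beta, L, u0):
        """Laplace contribution of one subject; returns (nll, u_mode)."""
        A = Z @ L  # n_i x q
        offset = X @ beta
        u = u0.copy()
        for _ in range(60):
            eta = offset + A @ u
            mu = 1.0 / (1.0 + np.exp(-eta))
            grad = A.T @ (y - mu) - u
            w = mu * (1.0 - mu)
            H = A.T @ (A * w[:, None]) + np.eye(self.q)
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = grad
            # step-halving on the penalized log-likelihood
            f0 = (y * eta - np.logaddexp(0.0, eta)).sum() - 0.5 * u @ u
            scale = 1.0
            for _ in range(25):
                u_new = u + scale * step
                eta_n = offset + A @ u_new
                f1 = (y * eta_n - np.logaddexp(0.0, eta_n)).sum() - 0.5 * u_new @ u_new
                if f1 >= f0 - 1e-13:
                    break
                scale *= 0.5
            u = u + scale * step
            if np.abs(grad).max() < 1e-11:
                break
        eta = offset + A @ u
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        H = A.T @ (A * w[:, None]) + np.eye(self.q)
        sign, logdet = np.linalg.slogdet(H)
        if sign <= 0:
            return np.inf, u
        f = (y * eta - np.logaddexp(0.0, eta)).sum() - 0.5 * u @ u
        return -(f - 0.5 * logdet), u

    def __call__(self, params: np.ndarray) -> float:
        beta = params[: self.p]
        L = _theta_to_L(params[self.p:], self.q, self.correlated)
        total = 0.0
        for i, sl in enumerate(self.slices):
            nll, u = self._subject_nll(self.y[sl], self.X[sl], self.Z[sl], beta, L, self._warm[i])
            self._warm[i] = u
            total += nll
        return total


def _fit_laplace(design: ModelDesign, fixed_terms, structure: RandomStructure):
    f = design.frame
    y = f["success"].to_numpy(dtype=np.float64)
    X = np.column_stack([design.column(t) for t in fixed_terms])
    Z = np.column_stack([design.column(t) for t in structure.terms])
    groups = f["subject_id"].to_numpy()
    q = structure.q
    prob = _LaplaceProblem(y, X, Z, groups, q, structure.correlated)

    # start fixed effects at the ordinary (no random effects) logistic MLE
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        beta0 = sm.GLM(y, X, family=sm.families.Binomial()).fit().params
    if structure.correlated:
        theta0 = np.zeros(structure.n_params)
        k = 0
        for i in range(q):
            for j in range(i + 1):
                theta0[k] = 0.3 if i == j else 0.0
                k += 1
    else:
        theta0 = np.full(q, 0.3)
    x0 = np.concatenate([beta0, theta0])

    res = optimize.minimize(
        prob, x0, method="BFGS",
        options={"maxiter": 800, "gtol": 5e-4, "eps": 1e-6},
    )
    nll = float(res.fun)
    params = res.x

    # observed-information SEs via central finite differences
    npar = params.size
    h = 1e-4 * np.maximum(1.0, np.abs(params))
    Hess = np.zeros((npar, npar))
    for i in range(npar):
        for j in range(i, npar):
            ei = np.zeros(npar)
            ej = np.zeros(npar)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = prob(params + ei + ej)
            fpm = prob(params + ei - ej)
            fmp = prob(params - ei + ej)
            fmm = prob(params - ei - ej)
            Hess[i, j] = Hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    p = len(fixed_terms)
    se = np.full(p, np.nan)
    ok_se = False
    try:
        cov = np.linalg.inv(Hess)
        d = np.diag(cov)[:p]
        if np.all(d > 0):
            se = np.sqrt(d)
            ok_se = True
    except np.linalg.LinAlgError:
        pass
    if not ok_se:
        try:  # fall back to the beta block alone (theta near a boundary)
            cov_b = np.linalg.inv(Hess[:p, :p])
            d = np.diag(cov_b)
            if np.all(d > 0):
                se = np.sqrt(d)
                ok_se = True
        except np.linalg.LinAlgError:
            pass

    L = _theta_to_L(params[p:], q, structure.correlated)
    Sigma = L @ L.T
    sds = np.sqrt(np.clip(np.diag(Sigma), 0.0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = Sigma / np.outer(sds, sds)
    converged = bool(res.success or np.abs(res.jac).max() < 5e-3) and ok_se and np.isfinite(nll)

    fixed = pd.DataFrame({"estimate": params[:p], "se": se}, index=list(fixed_terms))
    vc = pd.DataFrame({"sd": sds}, index=list(structure.terms))
    return PopulationFit(
        fixed_effects=fixed, variance_components=vc, random_structure=structure,
        log_likelihood=-nll, converged=converged,
        n_obs=design.n_obs, n_subjects=design.n_subjects,
        n_params=p + structure.n_params,
        correlations=corr if q > 1 and structure.correlated else None,
        fixed_terms=tuple(fixed_terms),
    )


def _simplification_ladder(structure: RandomStructure) -> list[RandomStructure]:
    ladder = [structure]
    cur = structure
    if cur.correlated and cur.q > 1:
        cur = replace(cur, correlated=False)
        ladder.append(cur)
    for drop in ("colour_c", "trial_z:task_c"):
        if drop in cur.terms and len(cur.terms) > 1:
            cur = replace(cur, terms=tuple(t for t in cur.terms if t != drop))
            ladder.append(cur)
    if cur.terms != ("intercept",):
        ladder.append(RandomStructure(terms=("intercept",), correlated=False))
    return ladder


def fit_population_model(
    design: ModelDesign,
    random_structure: RandomStructure = MAXIMAL_RANDOM_STRUCTURE,
    fixed_terms: Optional[tuple] = None,
    allow_fallback: bool = True,
) -> PopulationFit:
    """Fit the binomial mixed model.

    ``fixed_terms`` defaults to the design's full term set; pass a subset to
    fit reduced models for likelihood-ratio tests.  With ``allow_fallback``
    a non-converged fit triggers the documented simplification ladder; the
    rung used is recorded on the result.
    """
    if design.n_subjects < 2:
        raise ValueError("random effects are unidentifiable with fewer than 2 subjects")
    terms = tuple(fixed_terms) if fixed_terms is not None else design.fixed_terms()
    unknown = set(terms) - set(FIXED_TERMS_FULL)
    if unknown:
        raise ValueError(f"unknown fixed term(s): {sorted(unknown)}")
    ladder = _simplification_ladder(random_structure) if allow_fallback else [random_structure]
    last = None
    for rung, structure in enumerate(ladder):
        fit = _fit_laplace(design, terms, structure)
        fit.fallback_rung = rung
        if fit.converged:
            if rung > 0:
                warnings.warn(
                    f"random structure simplified to {structure.describe()} "
                    f"(ladder rung {rung}) after convergence failure",
                    UserWarning, stacklevel=2,
                )
            return fit
        last = fit
    raise RuntimeError(
        "mixed model failed to converge even at random intercepts only"
        if last is None or last.random_structure.terms == ("intercept",)
        else "mixed model failed to converge"
    )


# ---------------------------------------------------------------------------
# Likelihood-ratio workflow


def likelihood_ratio_test(full: PopulationFit, reduced: PopulationFit) -> ModelComparison:
    """Chi-square LRT of nested fits on the same rows."""
    if full.n_obs != reduced.n_obs:
        raise ValueError("fits use different numbers of rows; not comparable")
    if not set(reduced.fixed_terms).issubset(full.fixed_terms) or full.n_params < reduced.n_params:
        raise ValueError("reduced model is not nested in the full model")
    stat = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    if stat < 0:
        if stat < -1e-3:
            warnings.warn(
                f"negative LR statistic ({stat:.4g}) beyond optimizer tolerance",
                UserWarning, stacklevel=2,
            )
        stat = 0.0
    df = full.n_params - reduced.n_params
    # df = 0 (identical models) is the degenerate comparison: chi2 mass at 0
    p = 1.0 if df == 0 and stat <= 1e-8 else float(stats.chi2.sf(stat, df)) if df > 0 else 0.0
    return ModelComparison(statistic=float(stat), df=int(df), p_value=p)


def full_null_comparison(
    design: ModelDesign,
    random_structure: RandomStructure = MAXIMAL_RANDOM_STRUCTURE,
) -> tuple[ModelComparison, PopulationFit, PopulationFit]:
    """Full model versus a null excluding trial number and task (colour and
    the random structure are retained) — the overall test that the test
    predictors matter at all."""
    full = fit_population_model(design, random_structure)
    structure = full.random_structure  # reuse whatever rung the full fit needed
    null_terms = ("intercept", "colour_c")
    null = fit_population_model(design, structure, fixed_terms=null_terms,
                                allow_fallback=False)
    return likelihood_ratio_test(full, null), full, null


def single_term_tests(
    design: ModelDesign,
    random_structure: RandomStructure = MAXIMAL_RANDOM_STRUCTURE,
    alpha: float = 0.05,
) -> dict:
    """Drop-one likelihood-ratio tests, interaction first.

    The trial x task interaction is tested against the full model; only if
    it is non-significant is it removed and each main effect tested in the
    reduced model.  Returns a dict mapping term -> ModelComparison plus the
    fits used.
    """
    full = fit_population_model(design, random_structure)
    structure = full.random_structure
    results: dict = {"fits": {"full": full}}
    no_int = fit_population_model(
        design, structure,
        fixed_terms=tuple(t for t in full.fixed_terms if t != "trial_z:task_c"),
        allow_fallback=False,
    )
    results["fits"]["no_interaction"] = no_int
    inter = likelihood_ratio_test(full, no_int)
    results["trial_z:task_c"] = inter
    results["interaction_significant"] = inter.p_value < alpha
    if inter.p_value < alpha:
        return results
    base_terms = no_int.fixed_terms
    for term in ("trial_z", "task_c", "colour_c"):
        reduced = fit_population_model(
            design, structure,
            fixed_terms=tuple(t for t in base_terms if t != term),
            allow_fallback=False,
        )
        results[term] = likelihood_ratio_test(no_int, reduced)
    return results


def trim_trials(
    sequences: Sequence[TrialSequence], max_per_task: int = 40
) -> list[TrialSequence]:
    """First ``max_per_task`` trials per subject per task, for the
    robustness refit against unequal trial counts."""
    if max_per_task < 1:
        raise ValueError("max_per_task must be >= 1")
    return [s.truncated(max_per_task) for s in sequences]
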