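"""Scikit-learn-style estimators for the information-seeking choice models.

Single-participant estimators (:class:`EVIChoiceModel`,
:class:`UPChoiceModel`, :class:`InfoBonusChoiceModel`,
:class:`DiscountedChoiceModel`) maximise the binomial likelihood of one
participant's condition counts over the per-participant parameters, with the
lapse rate ``epsilon`` held fixed.  :class:`GroupChoiceModel` fits a cohort
with a single lapse rate shared across participants (profile likelihood over
``epsilon``; per-participant parameters are conditionally independent given
``epsilon``, so the profile attains the joint maximum).

All estimators follow the sklearn contract: hyperparameters in
``__init__``, fitted quantities as trailing-underscore attributes,
``get_params``/``set_params`` inherited from :class:`~sklearn.base.BaseEstimator`.
``X`` is either a tidy choice-record frame (see
:data:`infoseek.likelihood.CHOICE_COLUMNS`), a counts frame with columns
``cost_cents, rate_s_per_card, n_trials, n_informative``, or a sequence of
:class:`~infoseek.likelihood.ConditionCounts`.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

from scipy.special import expit, xlogy

from .likelihood import (
    ChoiceModelParams,
    ConditionCounts,
    chance_log_likelihood,
    condition_counts,
    informative_choice_probability,
    log_likelihood,
)
from .valuation import MODELS, _path_summaries

#: Per-participant free parameters of each model (epsilon handled separately).
MODEL_THETA = {
    "evi": ("beta",),
    "up": ("beta", "k"),
    "info_bonus": ("beta", "k_hat"),
    "discounted": ("beta", "k_hat", "gamma"),
}

DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "beta": (0.0, 10.0),
    "k": (-2.0, 2.0),
    "k_hat": (-2.0, 2.0),
    "gamma": (0.5, 1.0),
    "epsilon": (0.0, 0.5),
}

_HUGE_NLL = 1e15  # stands in for -inf log-likelihoods inside the optimiser


def params_per_participant(model: str) -> int:
    """Number of per-participant free parameters (1 for EVI, 2 for UP, ...)."""
    return len(MODEL_THETA[model])


def as_condition_counts(X) -> List[ConditionCounts]:
    """Coerce supported input types into a list of condition counts."""
    if isinstance(X, pd.DataFrame):
        if "n_trials" in X.columns:
            return [
                ConditionCounts(
                    cost_cents=int(r.cost_cents),
                    rate_s_per_card=(
                        None if pd.isna(r.rate_s_per_card) else int(r.rate_s_per_card)
                    ),
                    n_trials=int(r.n_trials),
                    n_informative=int(r.n_informative),
                )
                for r in X.itertuples(index=False)
            ]
        return condition_counts(X)
    counts = list(X)
    if not all(isinstance(c, ConditionCounts) for c in counts):
        raise TypeError(
            "X must be a record/counts DataFrame or a sequence of ConditionCounts"
        )
    return counts


def _merged_bounds(bounds: Optional[Mapping[str, Tuple[float, float]]]):
    out = dict(DEFAULT_BOUNDS)
    if bounds:
        out.update(bounds)
    return out


def _maximize_likelihood(
    counts: Sequence[ConditionCounts],
    model: str,
    theta_names: Sequence[str],
    epsilon: float,
    bounds: Mapping[str, Tuple[float, float]],
    starts: np.ndarray,
) -> Tuple[Dict[str, float], float, bool]:
    """Bounded multi-start MLE over ``theta_names``; returns the best
    estimates, the minimised negative log-likelihood, and a convergence flag.
    Ties across starts break to the lowest start index."""

    base = ChoiceModelParams(beta=1.0, epsilon=epsilon)

    def nll(theta: np.ndarray) -> float:
        params = replace(base, **dict(zip(theta_names, theta)))
        value = -log_likelihood(counts, params, model)
        if not math.isfinite(value):
            return _HUGE_NLL
        return value

    box = [bounds[name] for name in theta_names]
    informed = _smart_starts(model, counts, theta_names, epsilon, bounds)
    best: Optional[optimize.OptimizeResult] = None
    any_converged = False
    for x0 in informed + list(starts):
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=box)
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    estimates = dict(zip(theta_names, (float(v) for v in best.x)))
    return estimates, float(best.fun), any_converged


def _auxiliary_logistic_mle(
    counts: Sequence[ConditionCounts], epsilon: float
) -> Tuple[float, float]:
    """MLE of the reduced model ``p = eps/2 + (1-eps) * expit(a - b*cost)``.

    For the rate-unaware models the choice probability depends on the
    parameters only through the intercept/slope pair ``(a, b)`` — e.g. under
    the uncertainty penalty ``a = beta*(20*h(k) - 10*exp(-5k))`` and
    ``b = beta*h(k)`` with ``h(k)`` the win-path penalty sum — and the
    likelihood is well-behaved (concave at eps = 0) in that space.  Solving
    here and inverting the reparametrisation gives the optimiser a start at
    or near the global optimum.
    """
    costs = np.array([c.cost_cents for c in counts], dtype=float)
    n = np.array([c.n_trials for c in counts], dtype=float)
    m = np.array([c.n_informative for c in counts], dtype=float)

    def nll(x):
        p = 0.5 * epsilon + (1.0 - epsilon) * expit(x[0] - x[1] * costs)
        value = -(xlogy(m, p) + xlogy(n - m, 1.0 - p)).sum()
        return value if math.isfinite(value) else _HUGE_NLL

    best = None
    for x0 in ((0.0, 0.0), (2.0, 0.5), (-2.0, 0.5), (6.0, 2.0)):
        res = optimize.minimize(nll, x0, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    return float(best.x[0]), float(best.x[1])


def _up_penalty_sums(k: float) -> Tuple[float, float]:
    """(h(k), exp(-5k)): win-path penalty sum and the non-informative factor."""
    s = _path_summaries()
    return float(np.exp(-k * s.s_info_win).sum()) / 32.0, math.exp(-5.0 * k)


def _smart_starts(
    model: str,
    counts: Sequence[ConditionCounts],
    theta_names: Sequence[str],
    epsilon: float,
    bounds: Mapping[str, Tuple[float, float]],
) -> List[np.ndarray]:
    """Model-specific informed starting points from the auxiliary logistic
    fit, clipped into the optimisation box."""
    try:
        a, b = _auxiliary_logistic_mle(counts, epsilon)
    except Exception:  # pragma: no cover - defensive; aux fit is optional
        return []
    starts: List[Dict[str, float]] = []
    if model == "evi":
        starts.append({"beta": 2.0 * b})
    elif model == "up":
        k_lo, k_hi = bounds["k"]

        def ratio(k: float) -> float:
            h, e5 = _up_penalty_sums(k)
            return 20.0 - 10.0 * e5 / h

        if b > 0:
            target = a / b
            if target <= ratio(k_lo):
                k_hat = k_lo
            elif target >= ratio(k_hi):
                k_hat = k_hi
            else:
                k_hat = float(optimize.brentq(lambda k: ratio(k) - target, k_lo, k_hi))
            starts.append({"beta": b / _up_penalty_sums(k_hat)[0], "k": k_hat})
        else:
            starts.append({"beta": 0.0, "k": 0.0})
    elif model in ("info_bonus", "discounted"):
        # a = beta*k_hat (undiscounted), b = beta/2
        beta = 2.0 * b
        k_hat = a / beta if beta > 0 else 0.0
        point = {"beta": beta, "k_hat": k_hat}
        if model == "discounted":
            point["gamma"] = 1.0
            alt = dict(point, gamma=0.75)
            starts.append(alt)
        starts.append(point)
    out = []
    for point in starts:
        x = np.array([point.get(name, _NEUTRAL_START[name]) for name in theta_names])
        lo = np.array([bounds[n][0] for n in theta_names])
        hi = np.array([bounds[n][1] for n in theta_names])
        out.append(np.clip(x, lo, hi))
    return out


# Neutral first start: the null observer (indifferent, no information value).
# Starting there keeps weakly identified parameters at their parsimonious
# value when the likelihood is flat (e.g. k is meaningless once beta ~ 0),
# since ties across starts resolve to the earliest start.
_NEUTRAL_START = {"beta": 1.0, "k": 0.0, "k_hat": 0.0, "gamma": 1.0, "epsilon": 0.05}


def _starts_for(
    theta_names: Sequence[str],
    bounds: Mapping[str, Tuple[float, float]],
    n_starts: int,
    rng: np.random.Generator,
) -> np.ndarray:
    lo = np.array([bounds[n][0] for n in theta_names])
    hi = np.array([bounds[n][1] for n in theta_names])
    starts = rng.uniform(lo, hi, size=(n_starts, len(theta_names)))
    if n_starts > 0:
        starts[0] = np.clip(
            [_NEUTRAL_START[n] for n in theta_names], lo, hi
        )
    return starts


class _SingleParticipantModel(BaseEstimator):
    """Shared machinery of the per-participant estimators."""

    model_name: str = ""

    def __init__(
        self,
        epsilon: float = 0.0,
        bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
        n_starts: int = 10,
        random_state: Optional[int] = None,
    ):
        self.epsilon = epsilon
        self.bounds = bounds
        self.n_starts = n_starts
        self.random_state = random_state

    # -- sklearn API ----------------------------------------------------
    def fit(self, X, y=None):
        counts = as_condition_counts(X)
        theta_names = MODEL_THETA[self.model_name]
        merged = _merged_bounds(self.bounds)
        rng = np.random.default_rng(
            self.random_state if self.random_state is not None else 0
        )
        starts = _starts_for(theta_names, merged, self.n_starts, rng)
        estimates, nll, converged = _maximize_likelihood(
            counts, self.model_name, theta_names, self.epsilon, merged, starts
        )
        for name, value in estimates.items():
            setattr(self, f"{name}_", value)
        self.epsilon_ = float(self.epsilon)
        self.neg_log_likelihood_ = nll
        self.n_params_ = len(theta_names)
        self.n_choices_ = int(sum(c.n_trials for c in counts))
        self.null_neg_log_likelihood_ = -chance_log_likelihood(counts)
        self.bic_ = 2.0 * nll + self.n_params_ * math.log(max(self.n_choices_, 1))
        self.converged_ = converged
        self.classes_ = np.array(["N", "I"])
        return self

    def _fitted_params(self) -> ChoiceModelParams:
        kwargs = {
            name: getattr(self, f"{name}_") for name in MODEL_THETA[self.model_name]
        }
        return ChoiceModelParams(epsilon=self.epsilon_, **kwargs)

    def predict_proba(self, X) -> np.ndarray:
        """Per-condition choice probabilities; columns follow ``classes_``
        order ``["N", "I"]``."""
        params = self._fitted_params()
        if isinstance(X, pd.DataFrame):
            pairs = zip(X["cost_cents"], X["rate_s_per_card"])
        else:
            pairs = ((c.cost_cents, c.rate_s_per_card) for c in as_condition_counts(X))
        p_info = np.array(
            [
                informative_choice_probability(
                    self.model_name, int(cost), None if pd.isna(rate) else int(rate), params
                )
                for cost, rate in pairs
            ]
        )
        return np.column_stack([1.0 - p_info, p_info])

    def score(self, X, y=None) -> float:
        """Total log-likelihood of ``X`` under the fitted parameters."""
        return log_likelihood(as_condition_counts(X), self._fitted_params(), self.model_name)


class EVIChoiceModel(_SingleParticipantModel):
    """Expected-value-of-information observer: one free parameter (beta)."""

    model_name = "evi"


class UPChoiceModel(_SingleParticipantModel):
    """Uncertainty-penalty observer: free parameters (beta, k)."""

    model_name = "up"


class InfoBonusChoiceModel(_SingleParticipantModel):
    """Information-bonus observer: free parameters (beta, k_hat)."""

    model_name = "info_bonus"


class DiscountedChoiceModel(_SingleParticipantModel):
    """Discounted information-bonus observer: (beta, k_hat, gamma)."""

    model_name = "discounted"


def _participant_rng(random_state: Optional[int], index: int) -> np.random.Generator:
    return np.random.default_rng([0 if random_state is None else int(random_state), index])


class GroupChoiceModel(BaseEstimator):
    """Cohort-level maximum-likelihood fit with a shared lapse rate.

    Parameters
    ----------
    model : {"evi", "up", "info_bonus", "discounted"}
        Valuation model fitted to every participant.
    epsilon_mode : {"shared", "fixed", "per_participant"}
        ``shared`` profiles one lapse rate over the whole cohort (the
        headline scheme: total parameter count = per-participant x P + 1);
        ``fixed`` holds ``epsilon`` at the given value; ``per_participant``
        fits a lapse rate for each participant.
    epsilon : float
        Lapse value used when ``epsilon_mode="fixed"``.
    n_starts : int
        Random optimisation restarts per participant.
    random_state : int, optional
        Seeds all restarts; identical seeds give identical fits.

    Attributes
    ----------
    epsilon_ : float
        Fitted (or fixed) shared lapse rate.
    participant_params_ : pandas.DataFrame
        Per-participant estimates, individual -LL and trial counts.
    neg_log_likelihood_, n_params_, n_choices_, bic_, mcfadden_r2_ : float/int
        Cohort-level fit summaries; ``bic_ = 2*nll + n_params*ln(n_choices)``.
    """

    def __init__(
        self,
        model: str = "up",
        epsilon_mode: str = "shared",
        epsilon: float = 0.0,
        bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
        n_starts: int = 10,
        random_state: Optional[int] = None,
        epsilon_tol: float = 1e-4,
    ):
        self.model = model
        self.epsilon_mode = epsilon_mode
        self.epsilon = epsilon
        self.bounds = bounds
        self.n_starts = n_starts
        self.random_state = random_state
        self.epsilon_tol = epsilon_tol

    def _grouped_counts(self, X) -> Dict[object, List[ConditionCounts]]:
        if isinstance(X, Mapping):
            return {pid: as_condition_counts(v) for pid, v in X.items()}
        if not isinstance(X, pd.DataFrame) or "participant_id" not in X.columns:
            raise ValueError(
                "X must be a choice-record DataFrame with a participant_id "
                "column, or a mapping participant -> counts"
            )
        return {
            pid: condition_counts(grp)
            for pid, grp in X.groupby("participant_id", sort=True)
        }

    def fit(self, X, y=None):
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if self.epsilon_mode not in ("shared", "fixed", "per_participant"):
            raise ValueError(f"unknown epsilon_mode {self.epsilon_mode!r}")
        groups = self._grouped_counts(X)
        if not groups:
            raise ValueError("no participants in input")
        pids = list(groups)
        theta_names = MODEL_THETA[self.model]
        merged = _merged_bounds(self.bounds)
        if self.epsilon_mode == "per_participant":
            theta_names = tuple(theta_names) + ("epsilon",)

        starts = {
            pid: _starts_for(
                theta_names, merged, self.n_starts, _participant_rng(self.random_state, i)
            )
            for i, pid in enumerate(pids)
        }

        def fit_all(eps: float):
            results = {}
            for pid in pids:
                if self.epsilon_mode == "per_participant":
                    est, nll, conv = _maximize_likelihood(
                        groups[pid], self.model, theta_names, 0.0, merged, starts[pid]
                    )
                else:
                    est, nll, conv = _maximize_likelihood(
                        groups[pid], self.model, theta_names, eps, merged, starts[pid]
                    )
                results[pid] = (est, nll, conv)
            return results

        if self.epsilon_mode == "shared":
            lo, hi = merged["epsilon"]

            def profile(eps: float) -> float:
                return sum(r[1] for r in fit_all(eps).values())

            res = optimize.minimize_scalar(
                profile,
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": self.epsilon_tol},
            )
            eps_hat = float(res.x)
            results = fit_all(eps_hat)
            extra_params = 1
        elif self.epsilon_mode == "fixed":
            eps_hat = float(self.epsilon)
            results = fit_all(eps_hat)
            extra_params = 0
        else:  # per_participant
            results = fit_all(0.0)
            eps_hat = float(np.mean([r[0]["epsilon"] for r in results.values()]))
            extra_params = 0

        rows = []
        for pid in pids:
            est, nll, conv = results[pid]
            row = {"participant_id": pid}
            row.update(est)
            if "epsilon" not in est:
                row["epsilon"] = eps_hat
            row["neg_log_likelihood"] = nll
            row["n_choices"] = int(sum(c.n_trials for c in groups[pid]))
            row["converged"] = conv
            rows.append(row)
        table = pd.DataFrame(rows).set_index("participant_id")

        total_nll = float(table["neg_log_likelihood"].sum())
        n_choices = int(table["n_choices"].sum())
        n_params = params_per_participant(self.model) * len(pids) + extra_params
        if self.epsilon_mode == "per_participant":
            n_params = (params_per_participant(self.model) + 1) * len(pids)
        null_nll = -sum(chance_log_likelihood(groups[pid]) for pid in pids)

        self.participant_ids_ = pids
        self.epsilon_ = eps_hat
        self.participant_params_ = table
        self.neg_log_likelihood_ = total_nll
        self.n_params_ = n_params
        self.n_choices_ = n_choices
        self.bic_ = 2.0 * total_nll + n_params * math.log(n_choices)
        self.null_neg_log_likelihood_ = float(null_nll)
        self.mcfadden_r2_ = 1.0 - total_nll / null_nll if null_nll > 0 else float("nan")
        self.converged_ = bool(table["converged"].all())
        self.counts_ = {pid: groups[pid] for pid in pids}
        return self

    def _participant_model_params(self, pid) -> ChoiceModelParams:
        row = self.participant_params_.loc[pid]
        kwargs = {name: float(row[name]) for name in MODEL_THETA[self.model]}
        return ChoiceModelParams(epsilon=float(row["epsilon"]), **kwargs)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Per-row P(["N", "I"]) for tidy records of fitted participants."""
        p_info = np.array(
            [
                informative_choice_probability(
                    self.model,
                    int(r.cost_cents),
                    None if pd.isna(r.rate_s_per_card) else int(r.rate_s_per_card),
                    self._participant_model_params(r.participant_id),
                )
                for r in X.itertuples(index=False)
            ]
        )
        return np.column_stack([1.0 - p_info, p_info])

    def score(self, X=None, y=None) -> float:
        """Total fitted log-likelihood (negated ``neg_log_likelihood_``)."""
        return -self.neg_log_likelihood_
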