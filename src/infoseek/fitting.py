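"""Model-fit summaries: BIC, likelihood-ratio tests, McFadden's pseudo-R2,
and the model-comparison table (group -LL/BIC rows plus per-participant
best-fit tallies by individual BIC).

The functional entry points (`fit_participant`, `fit_group_shared_epsilon`)
are thin wrappers over the estimators in :mod:`infoseek.estimators`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, NamedTuple, Optional, Sequence, Tuple

import pandas as pd
from scipy import stats

from .estimators import (
    MODEL_THETA,
    GroupChoiceModel,
    _SingleParticipantModel,
    as_condition_counts,
    params_per_participant,
)
#: (reduced, full) pairs that differ by fixing parameters at a point, so a
#: likelihood-ratio test applies.  Degrees of freedom = participants x
#: (parameter-count difference).
NESTED_PAIRS = {
    ("evi", "up"),
    ("evi", "info_bonus"),
    ("evi", "discounted"),
    ("info_bonus", "discounted"),
}


def bic(neg_ll: float, n_params: int, n_obs: int) -> float:
    """Bayesian Information Criterion: ``2*neg_ll + n_params*ln(n_obs)``."""
    if n_obs < 1:
        raise ValueError("n_obs must be at least 1")
    return 2.0 * neg_ll + n_params * math.log(n_obs)


class LRTResult(NamedTuple):
    statistic: float
    df: int
    p_value: float


def likelihood_ratio(neg_ll_reduced: float, neg_ll_full: float, df: int) -> LRTResult:
    """Likelihood-ratio test of a nested pair: statistic
    ``2*(neg_ll_reduced - neg_ll_full)`` against the chi-square upper tail
    with ``df`` degrees of freedom.  A negative statistic (full model worse,
    an optimiser artefact) is clamped to 0 with a warning."""
    statistic = 2.0 * (neg_ll_reduced - neg_ll_full)
    if statistic < 0:
        warnings.warn(
            "full model has higher -LL than reduced model; statistic clamped to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        statistic = 0.0
    p = float(stats.chi2.sf(statistic, df)) if statistic > 0 else 1.0
    return LRTResult(statistic=float(statistic), df=int(df), p_value=p)


def mcfadden_r2(neg_ll: float, neg_ll_null: float) -> float:
    """McFadden's pseudo-R2, ``1 - neg_ll / neg_ll_null``, against the
    random-choice null (Pr = 1/2 on every trial)."""
    if neg_ll_null <= 0:
        raise ValueError("null negative log-likelihood must be positive")
    return 1.0 - neg_ll / neg_ll_null


@dataclass
class FitResult:
    """Outcome of one model's fit to a cohort (or a single participant).

    ``participant_params`` has one row per participant: parameter estimates,
    the participant's own -LL, trial count and convergence flag.  ``n_params``
    counts per-participant parameters plus one shared lapse rate when
    ``epsilon_mode == "shared"``.
    """

    model: str
    participant_params: pd.DataFrame
    epsilon: float
    neg_log_likelihood: float
    n_params: int
    n_choices: int
    bic: float
    mcfadden_r2: float
    n_starts: int
    converged: bool
    epsilon_mode: str = "shared"
    null_neg_log_likelihood: float = float("nan")

    def summary_row(self) -> Dict[str, object]:
        return {
            "model": self.model,
            "free_params_per_participant": params_per_participant(self.model),
            "neg_log_likelihood": self.neg_log_likelihood,
            "n_params": self.n_params,
            "bic": self.bic,
            "mcfadden_r2": self.mcfadden_r2,
        }


def _result_from_group(est: GroupChoiceModel) -> FitResult:
    return FitResult(
        model=est.model,
        participant_params=est.participant_params_,
        epsilon=est.epsilon_,
        neg_log_likelihood=est.neg_log_likelihood_,
        n_params=est.n_params_,
        n_choices=est.n_choices_,
        bic=est.bic_,
        mcfadden_r2=est.mcfadden_r2_,
        n_starts=est.n_starts,
        converged=est.converged_,
        epsilon_mode=est.epsilon_mode,
        null_neg_log_likelihood=est.null_neg_log_likelihood_,
    )


def fit_group_shared_epsilon(
    datasets,
    model: str,
    bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
    n_starts: int = 10,
    seed: int = 0,
    epsilon_mode: str = "shared",
) -> FitResult:
    """Cohort maximum-likelihood fit with one shared lapse rate.

    ``datasets`` is a tidy choice-record DataFrame (with participant_id) or
    a mapping participant -> condition counts.  Deterministic given ``seed``.
    """
    est = GroupChoiceModel(
        model=model,
        epsilon_mode=epsilon_mode,
        bounds=bounds,
        n_starts=n_starts,
        random_state=seed,
    ).fit(datasets)
    return _result_from_group(est)


def fit_participant(
    counts,
    model: str,
    epsilon: float = 0.0,
    bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
    n_starts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Single-participant MLE over the per-participant parameters only, with
    the lapse rate fixed (typically at the group estimate, or 0)."""
    cls = {
        c.model_name: c for c in _SingleParticipantModel.__subclasses__()
    }[model]
    est = cls(epsilon=epsilon, bounds=bounds, n_starts=n_starts, random_state=seed)
    est.fit(as_condition_counts(counts))
    theta = {name: getattr(est, f"{name}_") for name in MODEL_THETA[model]}
    table = pd.DataFrame(
        [
            {
                "participant_id": "participant",
                **theta,
                "epsilon": epsilon,
                "neg_log_likelihood": est.neg_log_likelihood_,
                "n_choices": est.n_choices_,
                "converged": est.converged_,
            }
        ]
    ).set_index("participant_id")
    return FitResult(
        model=model,
        participant_params=table,
        epsilon=epsilon,
        neg_log_likelihood=est.neg_log_likelihood_,
        n_params=est.n_params_,
        n_choices=est.n_choices_,
        bic=est.bic_,
        mcfadden_r2=mcfadden_r2(est.neg_log_likelihood_, est.null_neg_log_likelihood_),
        n_starts=n_starts,
        converged=est.converged_,
        epsilon_mode="fixed",
        null_neg_log_likelihood=est.null_neg_log_likelihood_,
    )


@dataclass
class ComparisonTable:
    """Model-comparison summary: one row per model (-LL, BIC, McFadden R2,
    n-best-fit count) plus the per-participant best-model labels.  Best-fit
    counts use individual-participant BICs with per-participant parameter
    counts on that participant's own trial count; the shared lapse rate is
    held at each model's group estimate and not counted."""

    table: pd.DataFrame
    best_model: pd.Series
    lrt: List[Dict[str, object]] = field(default_factory=list)

    @property
    def n_best_fit(self) -> Dict[str, int]:
        return {
            m: int((self.best_model == m).sum()) for m in self.table["model"]
        }


def compare_models(fits: Sequence[FitResult], with_lrt: bool = True) -> ComparisonTable:
    """Assemble the comparison table from group fits of competing models on
    identical data; adds likelihood-ratio tests for nested pairs."""
    if not fits:
        raise ValueError("need at least one fit")
    pids = list(fits[0].participant_params.index)
    n_by_pid = fits[0].participant_params["n_choices"]
    for f in fits[1:]:
        if list(f.participant_params.index) != pids or not (
            f.participant_params["n_choices"] == n_by_pid
        ).all():
            raise ValueError("fits were not computed on identical datasets")

    # Individual-participant BICs: d_m parameters on the participant's own n.
    ind_bic = pd.DataFrame(index=pids)
    for f in fits:
        d = params_per_participant(f.model)
        ind_bic[f.model] = [
            bic(
                float(f.participant_params.loc[pid, "neg_log_likelihood"]),
                d,
                int(f.participant_params.loc[pid, "n_choices"]),
            )
            for pid in pids
        ]
    best_model = ind_bic.idxmin(axis=1)  # ties -> first column = fit order
    best_model.index.name = "participant_id"

    rows = []
    for f in fits:
        row = f.summary_row()
        row["n_best_fit"] = int((best_model == f.model).sum())
        rows.append(row)
    table = pd.DataFrame(rows)

    lrt_rows: List[Dict[str, object]] = []
    if with_lrt and len(fits) > 1:
        by_model = {f.model: f for f in fits}
        for reduced, full in sorted(NESTED_PAIRS):
            if reduced in by_model and full in by_model:
                df = (
                    params_per_participant(full) - params_per_participant(reduced)
                ) * len(pids)
                res = likelihood_ratio(
                    by_model[reduced].neg_log_likelihood,
                    by_model[full].neg_log_likelihood,
                    df,
                )
                lrt_rows.append(
                    {
                        "reduced": reduced,
                        "full": full,
                        "statistic": res.statistic,
                        "df": res.df,
                        "p_value": res.p_value,
                    }
                )
    return ComparisonTable(table=table, best_model=best_model, lrt=lrt_rows)
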