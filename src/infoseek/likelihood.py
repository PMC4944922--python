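"""Choice probabilities and binomial likelihood of condition-level counts.

Action values map to an informative-choice probability through a softmax
(Luce) rule with inverse temperature ``beta``, then through a lapse mixture:
with probability ``epsilon`` the button press is undirected, flooring
predicted probabilities at ``epsilon/2`` and ceiling them at
``1 - epsilon/2``.  Because the models are static within participant x
condition, the data reduce to per-condition sufficient statistics
(n trials, m informative choices) and the likelihood is a product of
binomials over conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import pandas as pd
from scipy.special import expit, gammaln, xlogy

from .valuation import MODELS, ActionValues, action_values_fast

#: Required columns of the tidy choice-record schema.  ``rate_s_per_card``
#: is written as 3 for fixed-rate (Experiment-1 style) sessions.
CHOICE_COLUMNS = (
    "participant_id",
    "experiment",
    "block",
    "trial",
    "cost_cents",
    "rate_s_per_card",
    "choice",
    "catch",
)
CHOICE_VALUES = ("I", "N", "missed")


@dataclass(frozen=True)
class ConditionCounts:
    """Sufficient statistics of one (cost, rate) condition: ``n_trials``
    valid responses, of which ``n_informative`` chose the informative array.
    Missed responses are excluded before counting."""

    cost_cents: int
    rate_s_per_card: Optional[int]
    n_trials: int
    n_informative: int

    def __post_init__(self) -> None:
        if self.n_trials < 0:
            raise ValueError("n_trials must be non-negative")
        if not 0 <= self.n_informative <= self.n_trials:
            raise ValueError("need 0 <= n_informative <= n_trials")


@dataclass(frozen=True)
class ChoiceModelParams:
    """Full parameter set of one participant's choice model.

    ``beta`` >= 0 is the softmax inverse temperature; ``epsilon`` in
    [0, 0.5] the lapse probability; ``k``/``k_hat``/``gamma`` the valuation
    parameters (unused entries are ignored by the respective model).
    """

    beta: float
    epsilon: float = 0.0
    k: float = 0.0
    k_hat: float = 0.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if not 0.0 <= self.epsilon <= 0.5:
            raise ValueError("epsilon must lie in [0, 0.5]")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must lie in (0, 1]")


def softmax_probability(values: ActionValues, beta: float) -> float:
    """P(choose informative) under the softmax rule, computed overflow-safely
    from the value difference: ``expit(beta * (Q_I - Q_N))``."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    return float(expit(beta * (values.q_informative - values.q_noninformative)))


def apply_error_mixture(p: float, epsilon: float) -> float:
    """Lapse mixture ``0.5*epsilon + p*(1 - epsilon)``; bounds the output in
    ``[epsilon/2, 1 - epsilon/2]``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if not 0.0 <= epsilon <= 0.5:
        raise ValueError("epsilon must lie in [0, 0.5]")
    return 0.5 * epsilon + p * (1.0 - epsilon)


def informative_choice_probability(
    model: str,
    cost: int,
    rate: Optional[int],
    params: ChoiceModelParams,
) -> float:
    """Predicted P(a = I | cost, rate): valuation -> softmax -> lapse mixture.

    Rate-unaware models (EVI, UP, undiscounted info-bonus) predict the same
    probability at every rate of a given cost.
    """
    values = action_values_fast(
        model,
        cost,
        k=params.k,
        k_hat=params.k_hat,
        gamma=params.gamma,
        rate=3 if rate is None else int(rate),
    )
    return apply_error_mixture(softmax_probability(values, params.beta), params.epsilon)


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CHOICE_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"choice records are missing columns: {missing}")
    bad = ~records["choice"].isin(CHOICE_VALUES)
    if bad.any():
        row = records.index[bad][0]
        raise ValueError(
            f"row {row}: invalid choice {records.loc[row, 'choice']!r} "
            f"(expected one of {CHOICE_VALUES})"
        )
    for col in ("cost_cents", "rate_s_per_card"):
        try:
            pd.to_numeric(records[col])
        except (ValueError, TypeError) as err:
            raise ValueError(f"column {col!r} is not numeric: {err}") from None
    return records


def condition_counts(
    records: pd.DataFrame, *, exclude_catch: bool = False
) -> List[ConditionCounts]:
    """Aggregate tidy choice records into per-(cost, rate) sufficient
    statistics, excluding missed responses.  Catch trials keep their choice
    and are counted unless ``exclude_catch`` is set."""
    if len(records) == 0:
        return []
    records = _validate_records(records)
    valid = records[records["choice"] != "missed"]
    if exclude_catch:
        valid = valid[valid["catch"].astype(int) == 0]
    out: List[ConditionCounts] = []
    grouped = valid.groupby(["cost_cents", "rate_s_per_card"], sort=True)
    for (cost, rate), grp in grouped:
        out.append(
            ConditionCounts(
                cost_cents=int(cost),
                rate_s_per_card=int(rate),
                n_trials=int(len(grp)),
                n_informative=int((grp["choice"] == "I").sum()),
            )
        )
    return out


def counts_frame(counts: Sequence[ConditionCounts]) -> pd.DataFrame:
    """Tabular view of a list of condition counts."""
    return pd.DataFrame(
        {
            "cost_cents": [c.cost_cents for c in counts],
            "rate_s_per_card": [c.rate_s_per_card for c in counts],
            "n_trials": [c.n_trials for c in counts],
            "n_informative": [c.n_informative for c in counts],
        }
    )


def _log_binomial_coefficient(n: int, m: int) -> float:
    return float(gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1))


def log_likelihood(
    counts: Iterable[ConditionCounts],
    params: ChoiceModelParams,
    model: str,
    *,
    include_coefficient: bool = True,
) -> float:
    """Sum over conditions of the binomial log-likelihood of the counts under
    the model's predicted choice probabilities.

    Returns ``-inf`` (not an exception) when a predicted probability is
    exactly 0 or 1 but the counts disagree; empty conditions contribute 0.
    The binomial coefficient is included by default so totals are comparable
    across implementations that follow the full binomial density.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    total = 0.0
    for cc in counts:
        if cc.n_trials == 0:
            continue
        p = informative_choice_probability(model, cc.cost_cents, cc.rate_s_per_card, params)
        term = float(xlogy(cc.n_informative, p) + xlogy(cc.n_trials - cc.n_informative, 1.0 - p))
        if include_coefficient:
            term += _log_binomial_coefficient(cc.n_trials, cc.n_informative)
        total += term
    return total


def chance_log_likelihood(
    counts: Iterable[ConditionCounts], *, include_coefficient: bool = True
) -> float:
    """Log-likelihood of the counts under the random-choice null (Pr = 1/2
    on every trial); the reference model for McFadden's pseudo-R2."""
    total = 0.0
    for cc in counts:
        if cc.n_trials == 0:
            continue
        term = cc.n_trials * math.log(0.5)
        if include_coefficient:
            term += _log_binomial_coefficient(cc.n_trials, cc.n_informative)
        total += term
    return total
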