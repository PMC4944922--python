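"""Action values Q(I), Q(N) by dynamic programming over the state tree.

Four valuation models share one backward induction and differ only in how a
transition into successor state ``s'`` contributes:

* EVI — expected value of information (reward maximisation only):
  ``R + V(s')``.  Information carries no value, so Q(I) = (w - c)/2 and
  Q(N) = w/2 for win amount ``w``.
* UP — uncertainty penalty: ``R + V(s') * exp(-k * H(s'))``; time spent in
  uncertain states shrinks the value passed back, so the informative branch
  (whose entropy collapses early) is penalised less.
* info-bonus — additive reparametrisation: ``R + k_hat * (H(s) - H(s')) +
  V(s')``; reducing uncertainty by a card reveal earns a bonus.  The bonus
  attaches to card reveals only — the final outcome reveal resolves the same
  residual uncertainty in both branches, and crediting it would make the
  total bonus telescope to ``k_hat * H(root)`` identically for both actions.
* discounted — the information bonus scaled by ``gamma ** elapsed_seconds``
  at each reveal, so slowly delivered information is worth less.

Values are in cents throughout; the softmax inverse temperature absorbs the
scale.  ``enumerate_action_values`` recomputes everything by explicit
summation over all 32 card sequences and is the independent test oracle for
the recursions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import product
from typing import Optional

import numpy as np

from .task import (
    LOSS,
    RATES,
    WIN,
    StateTree,
    TrialConfig,
    _informative_p_win,
    binary_entropy,
    build_state_tree,
    trial_reward,
)

MODELS = ("evi", "up", "info_bonus", "discounted")

# Largest exponent handed to exp() in the uncertainty penalty; beyond this
# the factor is clipped with a warning instead of overflowing.
_MAX_EXPONENT = 700.0


@dataclass(frozen=True)
class UPParams:
    """Uncertainty-penalty weight ``k`` (may be negative: uncertainty bonus)."""

    k: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.k):
            raise ValueError("k must be finite")


@dataclass(frozen=True)
class InfoBonusParams:
    """Information-bonus weight ``k_hat`` (cents per bit of entropy reduced)."""

    k_hat: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.k_hat):
            raise ValueError("k_hat must be finite")


@dataclass(frozen=True)
class DiscountParams:
    """Per-second discount factor ``gamma`` in (0, 1]; 1 disables discounting."""

    gamma: float

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError(f"gamma must lie in (0, 1], got {self.gamma}")


@dataclass(frozen=True)
class ActionValues:
    """Q-values (cents) of observing the informative / non-informative array."""

    q_informative: float
    q_noninformative: float
    cost_cents: int
    rate_seconds_per_card: Optional[int] = None

    @property
    def difference(self) -> float:
        """Informative-minus-noninformative value gap."""
        return self.q_informative - self.q_noninformative


def _penalty_factor(entropy_bits: float, k: float) -> float:
    exponent = -k * entropy_bits
    if abs(exponent) > _MAX_EXPONENT:
        warnings.warn(
            f"uncertainty-penalty exponent {exponent:.3g} clipped to "
            f"+/-{_MAX_EXPONENT:g}",
            RuntimeWarning,
            stacklevel=3,
        )
        exponent = math.copysign(_MAX_EXPONENT, exponent)
    return math.exp(exponent)


def _branch_value(
    tree: StateTree,
    action: str,
    *,
    k: float = 0.0,
    k_hat: float = 0.0,
    gamma: float = 1.0,
    rate: int = 3,
) -> float:
    """General backward induction over one branch; returns the entry value.

    The entropy penalty and information bonus act on card-draw transitions;
    terminal outcome reveals pass value through unchanged (outcome states
    carry zero entropy, so the penalty would be unity there regardless).
    """
    values = {WIN: 0.0, LOSS: 0.0}
    n_cards = tree.config.n_cards
    for nr in range(n_cards, -1, -1):
        for b in range(nr + 1):
            key = (action, nr, b)
            v = 0.0
            for t in tree.transitions[key]:
                succ_value = values[t.target]
                contribution = t.reward_cents + succ_value
                if t.card_draw:
                    h_before = tree.states[key].entropy_bits
                    h_after = tree.states[t.target].entropy_bits
                    if k != 0.0:
                        contribution = (
                            t.reward_cents
                            + succ_value * _penalty_factor(h_after, k)
                        )
                    if k_hat != 0.0:
                        discount = gamma ** (t.n_after * rate) if gamma != 1.0 else 1.0
                        contribution += k_hat * (h_before - h_after) * discount
                v += t.probability * contribution
            values[key] = v
    return values[(action, 0, 0)]


def _check_cost(tree: StateTree, cost: Optional[int]) -> int:
    if cost is not None and cost != tree.config.cost_cents:
        raise ValueError(
            f"tree was built for cost {tree.config.cost_cents}, got {cost}"
        )
    return tree.config.cost_cents


def evi_action_values(tree: StateTree, cost: Optional[int] = None) -> ActionValues:
    """Expected-value-of-information action values (plain Bellman backup)."""
    c = _check_cost(tree, cost)
    return ActionValues(
        q_informative=_branch_value(tree, "I"),
        q_noninformative=_branch_value(tree, "N"),
        cost_cents=c,
        rate_seconds_per_card=tree.config.rate_seconds_per_card,
    )


def up_action_values(
    tree: StateTree, params: UPParams | float, cost: Optional[int] = None
) -> ActionValues:
    """Uncertainty-penalty action values: successor values are multiplied by
    ``exp(-k * H(s'))`` on every card reveal.  ``k = 0`` reduces to EVI."""
    k = params.k if isinstance(params, UPParams) else UPParams(float(params)).k
    c = _check_cost(tree, cost)
    return ActionValues(
        q_informative=_branch_value(tree, "I", k=k),
        q_noninformative=_branch_value(tree, "N", k=k),
        cost_cents=c,
        rate_seconds_per_card=tree.config.rate_seconds_per_card,
    )


def info_bonus_action_values(
    tree: StateTree, params: InfoBonusParams | float, cost: Optional[int] = None
) -> ActionValues:
    """Information-bonus action values: each card reveal adds
    ``k_hat * (H(s) - H(s'))``.  ``k_hat = 0`` reduces to EVI."""
    k_hat = (
        params.k_hat
        if isinstance(params, InfoBonusParams)
        else InfoBonusParams(float(params)).k_hat
    )
    c = _check_cost(tree, cost)
    return ActionValues(
        q_informative=_branch_value(tree, "I", k_hat=k_hat),
        q_noninformative=_branch_value(tree, "N", k_hat=k_hat),
        cost_cents=c,
        rate_seconds_per_card=tree.config.rate_seconds_per_card,
    )


def discounted_action_values(
    tree: StateTree,
    bonus: InfoBonusParams | float,
    disc: DiscountParams | float,
    rate: Optional[int] = None,
    cost: Optional[int] = None,
) -> ActionValues:
    """Information-bonus values with each reveal's bonus discounted by
    ``gamma ** (elapsed seconds)``; ``gamma = 1`` reproduces the undiscounted
    information-bonus model exactly."""
    k_hat = bonus.k_hat if isinstance(bonus, InfoBonusParams) else float(bonus)
    gamma = (
        disc.gamma if isinstance(disc, DiscountParams) else DiscountParams(float(disc)).gamma
    )
    if rate is None:
        rate = tree.config.rate_seconds_per_card
    if rate not in RATES:
        raise ValueError(f"rate must be one of {RATES}, got {rate}")
    c = _check_cost(tree, cost)
    return ActionValues(
        q_informative=_branch_value(tree, "I", k_hat=k_hat, gamma=gamma, rate=rate),
        q_noninformative=_branch_value(tree, "N", k_hat=k_hat, gamma=gamma, rate=rate),
        cost_cents=c,
        rate_seconds_per_card=rate,
    )


def enumerate_action_values(
    cost: int,
    model: str,
    *,
    k: float = 0.0,
    k_hat: float = 0.0,
    gamma: float = 1.0,
    rate: int = 3,
    win_amount_cents: int = 20,
) -> ActionValues:
    """Brute-force oracle: Q(I) and Q(N) by explicit summation over all 32
    equally likely card sequences (and both outcomes for the non-informative
    branch), with no recursion.

    Per sequence, penalty factors multiply the terminal reward once per card
    state entered, and bonuses add ``k_hat * dH * gamma**t`` per reveal.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    totals = {}
    for action in ("I", "N"):
        total = 0.0
        for seq in product((0, 1), repeat=5):
            entropies = [1.0]  # entry state: p_win = 1/2 in both branches
            blacks = 0
            for n, card in enumerate(seq, start=1):
                blacks += card
                p = _informative_p_win(n, blacks) if action == "I" else 0.5
                entropies.append(binary_entropy(p))
            if action == "I":
                outcomes = ((1.0, WIN if sum(seq) >= 3 else LOSS),)
            else:
                outcomes = ((0.5, WIN), (0.5, LOSS))
            expected_reward = sum(
                w * trial_reward(action, oc, cost, win_amount_cents)
                for w, oc in outcomes
            )
            if model == "evi":
                contribution = expected_reward
            elif model == "up":
                contribution = expected_reward * math.exp(-k * sum(entropies[1:]))
            else:
                g = gamma if model == "discounted" else 1.0
                bonus = sum(
                    k_hat * (entropies[n - 1] - entropies[n]) * g ** (n * rate)
                    for n in range(1, 6)
                )
                contribution = expected_reward + bonus
            total += contribution / 32.0
        totals[action] = total
    return ActionValues(
        q_informative=totals["I"],
        q_noninformative=totals["N"],
        cost_cents=cost,
        rate_seconds_per_card=rate,
    )


@dataclass(frozen=True)
class _PathSummaries:
    """Sufficient statistics of the 5-card tree for closed-form Q-values.

    ``s_info_win`` — per-path sums of card-state entropies along the 16
    winning informative sequences; ``s_noninfo`` — the same over all 32
    non-informative sequences (each equals 5 bits: the belief never moves);
    ``d_info`` — expected entropy drop at each of the five reveals in the
    informative branch.
    """

    s_info_win: np.ndarray
    s_noninfo: np.ndarray
    d_info: np.ndarray


@lru_cache(maxsize=1)
def _path_summaries() -> _PathSummaries:
    s_win, s_non = [], []
    d_info = np.zeros(5)
    for seq in product((0, 1), repeat=5):
        blacks = 0
        entropies = [1.0]
        for n, card in enumerate(seq, start=1):
            blacks += card
            entropies.append(binary_entropy(_informative_p_win(n, blacks)))
        for n in range(1, 6):
            d_info[n - 1] += (entropies[n - 1] - entropies[n]) / 32.0
        if sum(seq) >= 3:
            s_win.append(sum(entropies[1:]))
        s_non.append(5.0)
    return _PathSummaries(
        s_info_win=np.asarray(s_win),
        s_noninfo=np.asarray(s_non),
        d_info=d_info,
    )


def action_values_fast(
    model: str,
    cost: int,
    *,
    k: float = 0.0,
    k_hat: float = 0.0,
    gamma: float = 1.0,
    rate: int = 3,
    win_amount_cents: int = 20,
) -> ActionValues:
    """Closed-form Q-values from precomputed path summaries of the tree.

    Algebraically identical to the backward-induction functions (and tested
    against them); used inside likelihood evaluation where the recursion
    would dominate fitting time.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    if cost not in (0, 1, 3, 5):
        raise ValueError(f"cost must be one of (0, 1, 3, 5), got {cost}")
    s = _path_summaries()
    w = float(win_amount_cents)
    if model == "evi":
        q_i, q_n = (w - cost) / 2.0, w / 2.0
    elif model == "up":
        q_i = (w - cost) * float(np.exp(-k * s.s_info_win).sum()) / 32.0
        q_n = w * float(np.exp(-k * s.s_noninfo).sum()) / 64.0
    else:
        g = gamma if model == "discounted" else 1.0
        steps = g ** (rate * np.arange(1, 6, dtype=float))
        q_i = (w - cost) / 2.0 + k_hat * float(steps @ s.d_info)
        q_n = w / 2.0
    return ActionValues(q_i, q_n, cost, rate)


def action_values_for_condition(
    model: str,
    cost: int,
    rate: Optional[int] = None,
    *,
    k: float = 0.0,
    k_hat: float = 0.0,
    gamma: float = 1.0,
    win_amount_cents: int = 20,
) -> ActionValues:
    """Reference Q-values for one (cost, rate) condition via the state-tree
    dynamic programme (builds the tree and runs the requested model)."""
    rate = 3 if rate is None else int(rate)
    tree = build_state_tree(
        TrialConfig(cost_cents=cost, rate_seconds_per_card=rate,
                    win_amount_cents=win_amount_cents)
    )
    if model == "evi":
        return evi_action_values(tree)
    if model == "up":
        return up_action_values(tree, UPParams(k))
    if model == "info_bonus":
        return info_bonus_action_values(tree, InfoBonusParams(k_hat))
    if model == "discounted":
        return discounted_action_values(
            tree, InfoBonusParams(k_hat), DiscountParams(gamma), rate=rate
        )
    raise ValueError(f"model must be one of {MODELS}, got {model!r}")
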