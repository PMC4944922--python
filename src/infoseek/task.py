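"""Card-reveal lottery task represented as a small Markov decision process.

Each trial offers a choice between two five-card arrays revealed one card at
a time while a fair win/lose lottery (20 c or 0 c) resolves. One array (the
*informative* stimulus) is composed so that its majority colour perfectly
predicts the lottery outcome; the other (*non-informative*) array is
colour-random and predicts nothing. Observing the informative array costs
``c`` cents, deducted from winnings only on a win. The information is
non-instrumental: it cannot change the outcome or its probability.

States aggregate card configurations by colour count ``(n_revealed,
n_black)`` — card order is irrelevant to both the posterior win probability
and its entropy — giving 21 card states per branch (counts ``0 <= b <= n <=
5``, including the pre-reveal entry state) plus two terminal outcome states.
Every card draw is Bernoulli(1/2) black/red.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterator, Tuple

#: Information cost conditions, in cents.
COSTS = (0, 1, 3, 5)
#: Card reveal rates, in seconds per card.
RATES = (1, 3, 5)

INFORMATIVE = "informative"
NON_INFORMATIVE = "non_informative"
#: Action labels: observe the informative (I) or non-informative (N) array.
ACTIONS = ("I", "N")
_ACTION_STIMULUS = {"I": INFORMATIVE, "N": NON_INFORMATIVE}

ROOT = "root"
WIN = "win"
LOSS = "loss"

StateKey = Tuple[str, int, int]  # (action, n_revealed, n_black)


def binary_entropy(p: float) -> float:
    """Binary entropy H(p) = -p*log2(p) - (1-p)*log2(1-p), in bits.

    ``0 * log2(0)`` is taken as 0, so H(0) = H(1) = 0 and H(1/2) = 1.

    Raises
    ------
    ValueError
        If ``p`` lies outside [0, 1].
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must lie in [0, 1], got {p!r}")
    h = 0.0
    if p > 0.0:
        h -= p * math.log2(p)
    if p < 1.0:
        h -= (1.0 - p) * math.log2(1.0 - p)
    return h


def _informative_p_win(n_revealed: int, n_black: int, n_cards: int = 5) -> float:
    """P(majority black | n_black of n_revealed cards black), fair i.i.d. cards.

    The denominator is a power of two, so the result is exact in binary
    floating point.
    """
    majority = n_cards // 2 + 1
    remaining = n_cards - n_revealed
    need = majority - n_black
    if need <= 0:
        return 1.0
    if need > remaining:
        return 0.0
    favourable = sum(math.comb(remaining, j) for j in range(need, remaining + 1))
    return favourable / 2**remaining


@dataclass(frozen=True)
class CardState:
    """One node of the per-stimulus state tree.

    ``p_win`` is the posterior probability of the win outcome given the
    revealed colour counts; ``entropy_bits`` is its binary entropy.
    """

    stimulus: str
    n_revealed: int
    n_black: int
    p_win: float
    entropy_bits: float

    @classmethod
    def from_counts(
        cls, stimulus: str, n_revealed: int, n_black: int, n_cards: int = 5
    ) -> "CardState":
        if stimulus not in (INFORMATIVE, NON_INFORMATIVE):
            raise ValueError(f"unknown stimulus {stimulus!r}")
        if not 0 <= n_black <= n_revealed <= n_cards:
            raise ValueError(
                f"need 0 <= n_black <= n_revealed <= {n_cards}, "
                f"got n_black={n_black}, n_revealed={n_revealed}"
            )
        if stimulus == INFORMATIVE:
            p = _informative_p_win(n_revealed, n_black, n_cards)
        else:
            p = 0.5
        return cls(stimulus, n_revealed, n_black, p, binary_entropy(p))


def posterior_win_probability(state: CardState) -> float:
    """Posterior win probability of a card state, recomputed from its counts.

    Informative branch: exact enumeration over the remaining fair cards of
    the probability that the total black count reaches a majority.
    Non-informative branch: 1/2 regardless of the cards shown.
    """
    if state.stimulus == NON_INFORMATIVE:
        return 0.5
    return _informative_p_win(state.n_revealed, state.n_black)


@dataclass(frozen=True)
class TrialConfig:
    """Static parameters of one trial.

    Parameters
    ----------
    cost_cents : int
        Information cost, one of ``COSTS``.
    rate_seconds_per_card : int
        Card reveal rate, one of ``RATES``.
    win_amount_cents : int
        Lottery payoff on a win (0 on a loss).
    n_cards : int
        Array length; only 5 is supported under the default majority rule.
    """

    cost_cents: int = 0
    rate_seconds_per_card: int = 3
    win_amount_cents: int = 20
    n_cards: int = 5

    def __post_init__(self) -> None:
        if self.cost_cents not in COSTS:
            raise ValueError(
                f"cost_cents must be one of {COSTS}, got {self.cost_cents}"
            )
        if self.rate_seconds_per_card not in RATES:
            raise ValueError(
                f"rate_seconds_per_card must be one of {RATES}, "
                f"got {self.rate_seconds_per_card}"
            )
        if self.n_cards != 5:
            raise ValueError(
                "only 5-card arrays are supported under the majority rule"
            )
        if self.win_amount_cents <= max(COSTS):
            raise ValueError("win amount must exceed the largest cost")


def trial_reward(action: str, outcome: str, cost_cents: int,
                 win_amount_cents: int = 20) -> int:
    """Trial winnings in cents: ``win_amount - cost`` for an informative win,
    ``win_amount`` for a non-informative win, 0 for any loss."""
    if action not in ACTIONS:
        raise ValueError(f"action must be one of {ACTIONS}, got {action!r}")
    if outcome not in (WIN, LOSS):
        raise ValueError(f"outcome must be 'win' or 'loss', got {outcome!r}")
    if cost_cents not in COSTS:
        raise ValueError(f"cost_cents must be one of {COSTS}, got {cost_cents}")
    if outcome == LOSS:
        return 0
    return win_amount_cents - cost_cents if action == "I" else win_amount_cents


def trial_delay(rate_seconds_per_card: float, n_cards: int = 5) -> float:
    """Total delay from choice to outcome: five card reveals plus one
    outcome-reveal interval, i.e. ``(n_cards + 1) * rate`` seconds."""
    if rate_seconds_per_card <= 0:
        raise ValueError("rate must be positive")
    return (n_cards + 1) * rate_seconds_per_card


@dataclass(frozen=True)
class Transition:
    """Edge of the state tree.

    ``card_draw`` marks transitions that reveal a card (these are the ones
    the uncertainty penalty and information bonus act on); the root-to-branch
    entry and the final outcome reveal are not card draws.  ``n_after`` is
    the number of reveal intervals elapsed when the transition completes
    (terminal transitions count one extra interval for the outcome reveal),
    so elapsed time is ``n_after * rate``.
    """

    target: object
    probability: float
    reward_cents: float
    card_draw: bool
    n_after: int


@dataclass(frozen=True)
class StateTree:
    """The full MDP for one trial.

    ``transitions`` maps a card-state key ``(action, n_revealed, n_black)``
    — or ``(ROOT, action)`` for the two root actions — to its outgoing
    transitions. Rewards attach to the transition from a full-array state
    into a terminal outcome; all other transitions carry zero reward.
    """

    config: TrialConfig
    states: Dict[StateKey, CardState]
    transitions: Dict[object, Tuple[Transition, ...]]

    def entry(self, action: str) -> StateKey:
        """Key of the branch entry state (no cards revealed) for an action."""
        return (action, 0, 0)

    def card_states(self, action: str) -> Iterator[StateKey]:
        n = self.config.n_cards
        for nr in range(n + 1):
            for b in range(nr + 1):
                yield (action, nr, b)

    def full_array_states(self, action: str) -> Iterator[StateKey]:
        n = self.config.n_cards
        for b in range(n + 1):
            yield (action, n, b)


def build_state_tree(config: TrialConfig) -> StateTree:
    """Construct the trial MDP for one cost/rate condition.

    States are aggregated by ``(stimulus, n_revealed, n_black)``; each card
    draw transitions to black/red successors with probability 1/2 each. In
    the informative branch every full-array state transitions to exactly one
    outcome with probability 1 (majority colour decides); non-informative
    full-array states transition to win/loss with probability 1/2 each.
    """
    n_cards = config.n_cards
    states: Dict[StateKey, CardState] = {}
    transitions: Dict[object, Tuple[Transition, ...]] = {}

    for action, stimulus in _ACTION_STIMULUS.items():
        for nr in range(n_cards + 1):
            for b in range(nr + 1):
                states[(action, nr, b)] = CardState.from_counts(stimulus, nr, b)

    for action in ACTIONS:
        # Root action: a deterministic, non-card-draw move to the branch
        # entry state (the choice-information screen); unpenalised.
        transitions[(ROOT, action)] = (
            Transition((action, 0, 0), 1.0, 0.0, card_draw=False, n_after=0),
        )
        for nr in range(n_cards):
            for b in range(nr + 1):
                transitions[(action, nr, b)] = (
                    Transition((action, nr + 1, b + 1), 0.5, 0.0, True, nr + 1),
                    Transition((action, nr + 1, b), 0.5, 0.0, True, nr + 1),
                )
        for b in range(n_cards + 1):
            key = (action, n_cards, b)
            if action == "I":
                outcome = WIN if states[key].p_win == 1.0 else LOSS
                r = trial_reward("I", outcome, config.cost_cents,
                                 config.win_amount_cents)
                transitions[key] = (
                    Transition(outcome, 1.0, float(r), False, n_cards + 1),
                )
            else:
                r_win = trial_reward("N", WIN, config.cost_cents,
                                     config.win_amount_cents)
                transitions[key] = (
                    Transition(WIN, 0.5, float(r_win), False, n_cards + 1),
                    Transition(LOSS, 0.5, 0.0, False, n_cards + 1),
                )

    return StateTree(config=config, states=states, transitions=transitions)
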