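"""Synthetic trial sequences and model-governed cohorts.

Two session designs are generated:

* ``exp1`` — 7 blocks x 16 trials, four trials per cost condition
  {0, 1, 3, 5} c per block, fixed reveal rate of 3 s/card;
* ``exp2`` — 6 blocks x 12 trials, block reveal rate in {1, 3, 5} s/card
  with no two adjacent blocks sharing a rate, three trials per cost per
  block.

Outcomes are balanced so that every (cost, rate) cell wins on exactly half
its trials (pseudo-random win scheduling); informative-stimulus identity
(A/B) and screen side are counterbalanced, and 10% of trials (rounded) are
flagged as attention-check catch trials.  Choices are then sampled from the
full model chain (valuation -> softmax -> lapse mixture), with optional
condition-independent missed responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .likelihood import CHOICE_COLUMNS, ChoiceModelParams, informative_choice_probability
from .valuation import MODELS

EXPERIMENTS = ("exp1", "exp2")

TRIAL_COLUMNS = (
    "experiment",
    "block",
    "trial",
    "cost_cents",
    "rate_s_per_card",
    "informative_identity",
    "informative_side",
    "outcome",
    "catch",
)


@dataclass(frozen=True)
class _Design:
    n_blocks: int
    trials_per_block: int
    costs: Tuple[int, ...]
    rates: Tuple[int, ...]
    trials_per_cost_per_block: int
    catch_fraction: float = 0.10


_DESIGNS = {
    "exp1": _Design(7, 16, (0, 1, 3, 5), (3,), 4),
    "exp2": _Design(6, 12, (0, 1, 3, 5), (1, 3, 5), 3),
}


def _block_rates(design: _Design, rng: np.random.Generator) -> np.ndarray:
    if len(design.rates) == 1:
        return np.full(design.n_blocks, design.rates[0])
    reps = design.n_blocks // len(design.rates)
    pool = np.repeat(design.rates, reps)
    while True:  # rejection sampling: no two adjacent blocks share a rate
        seq = rng.permutation(pool)
        if (seq[1:] != seq[:-1]).all():
            return seq


def generate_trials(experiment: str, seed: int) -> pd.DataFrame:
    """One session's trial sequence honouring all design constraints.

    Deterministic given ``seed``.  Outcomes are pre-determined and balanced:
    each (cost, rate) cell wins on exactly half of its trials.
    """
    if experiment not in EXPERIMENTS:
        raise ValueError(f"experiment must be one of {EXPERIMENTS}, got {experiment!r}")
    design = _DESIGNS[experiment]
    rng = np.random.default_rng(seed)

    rates = _block_rates(design, rng)
    rows = []
    for block in range(1, design.n_blocks + 1):
        costs = np.repeat(design.costs, design.trials_per_cost_per_block)
        costs = rng.permutation(costs)
        for trial, cost in enumerate(costs, start=1):
            rows.append(
                {
                    "experiment": experiment,
                    "block": block,
                    "trial": trial,
                    "cost_cents": int(cost),
                    "rate_s_per_card": int(rates[block - 1]),
                }
            )
    trials = pd.DataFrame(rows)
    n = len(trials)

    # Balanced, shuffled win schedule within every (cost, rate) cell.
    trials["outcome"] = ""
    for _, idx in trials.groupby(["cost_cents", "rate_s_per_card"]).groups.items():
        m = len(idx)
        outcomes = np.array(["win"] * (m // 2) + ["loss"] * (m - m // 2))
        trials.loc[idx, "outcome"] = rng.permutation(outcomes)

    # Counterbalanced informative identity and screen side.
    identity = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
    side = np.array(["left"] * (n // 2) + ["right"] * (n - n // 2))
    trials["informative_identity"] = rng.permutation(identity)
    trials["informative_side"] = rng.permutation(side)

    # ~10% catch trials, rounded to the nearest whole trial.
    n_catch = round(design.catch_fraction * n)
    catch = np.zeros(n, dtype=int)
    catch[rng.choice(n, size=n_catch, replace=False)] = 1
    trials["catch"] = catch

    return trials[list(TRIAL_COLUMNS)]


def simulate_choices(
    trials: pd.DataFrame,
    params: ChoiceModelParams,
    model: str,
    seed: int,
    *,
    miss_rate: float = 0.0,
    participant_id: str = "p01",
) -> pd.DataFrame:
    """Sample one participant's choices for a trial sequence.

    Per trial the informative array is chosen with the analytic probability
    Pr(a = I | cost, rate) from the full model chain; with probability
    ``miss_rate`` the response is recorded as ``missed`` instead
    (independent of condition).  Deterministic given ``seed``.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    if not 0.0 <= miss_rate < 1.0:
        raise ValueError("miss_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    p_by_condition: Dict[Tuple[int, int], float] = {}
    for cost, rate in set(zip(trials["cost_cents"], trials["rate_s_per_card"])):
        p_by_condition[(int(cost), int(rate))] = informative_choice_probability(
            model, int(cost), int(rate), params
        )
    p = np.array(
        [p_by_condition[(int(c), int(r))] for c, r in zip(trials["cost_cents"], trials["rate_s_per_card"])]
    )
    chose_info = rng.random(len(trials)) < p
    missed = rng.random(len(trials)) < miss_rate
    choice = np.where(missed, "missed", np.where(chose_info, "I", "N"))

    records = trials[
        ["experiment", "block", "trial", "cost_cents", "rate_s_per_card", "catch"]
    ].copy()
    records.insert(0, "participant_id", participant_id)
    records["choice"] = choice
    return records[list(CHOICE_COLUMNS)]


@dataclass
class CohortConfig:
    """Study conditions for a simulated cohort.

    Defaults emulate a 40-participant fixed-rate session with
    uncertainty-penalty participants: k ~ U[0, 0.5], beta ~ U[0.5, 3],
    shared lapse rate 0.03, and a 1.5% condition-independent miss rate.
    """

    experiment: str = "exp1"
    n_participants: int = 40
    model: str = "up"
    beta_range: Tuple[float, float] = (0.5, 3.0)
    k_range: Tuple[float, float] = (0.0, 0.5)
    k_hat_range: Tuple[float, float] = (0.0, 0.5)
    gamma_range: Tuple[float, float] = (1.0, 1.0)
    epsilon: float = 0.03
    miss_rate: float = 0.015

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"experiment must be one of {EXPERIMENTS}")
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if self.n_participants < 1:
            raise ValueError("need at least one participant")


@dataclass
class SimulatedCohort:
    """Choice records plus the generating truth table (kept separate so the
    truth is never mixed into fitting inputs)."""

    choices: pd.DataFrame
    truth: pd.DataFrame
    seed: int

    def write(self, out_dir: Path) -> Tuple[Path, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        choices_path = out_dir / "choices.csv"
        truth_path = out_dir / "truth.csv"
        self.choices.to_csv(choices_path, index=False)
        self.truth.to_csv(truth_path, index=False)
        return choices_path, truth_path


def generate_cohort(
    config: CohortConfig, seed: int, out_dir: Optional[Path] = None
) -> SimulatedCohort:
    """Simulate a cohort: per participant a fresh trial sequence and choices
    sampled from the configured model at randomly drawn true parameters."""
    rng = np.random.default_rng(seed)
    all_choices, truth_rows = [], []
    width = len(str(config.n_participants))
    for i in range(config.n_participants):
        pid = f"p{i + 1:0{width}d}"
        beta = float(rng.uniform(*config.beta_range))
        k = float(rng.uniform(*config.k_range)) if config.model == "up" else 0.0
        k_hat = (
            float(rng.uniform(*config.k_hat_range))
            if config.model in ("info_bonus", "discounted")
            else 0.0
        )
        gamma = (
            float(rng.uniform(*config.gamma_range))
            if config.model == "discounted"
            else 1.0
        )
        params = ChoiceModelParams(
            beta=beta, epsilon=config.epsilon, k=k, k_hat=k_hat, gamma=gamma
        )
        trial_seed = int(rng.integers(2**31))
        choice_seed = int(rng.integers(2**31))
        trials = generate_trials(config.experiment, trial_seed)
        records = simulate_choices(
            trials,
            params,
            config.model,
            choice_seed,
            miss_rate=config.miss_rate,
            participant_id=pid,
        )
        all_choices.append(records)
        truth_rows.append(
            {
                "participant_id": pid,
                "model": config.model,
                "beta": beta,
                "k": k,
                "k_hat": k_hat,
                "gamma": gamma,
                "epsilon": config.epsilon,
                "seed": choice_seed,
            }
        )
    cohort = SimulatedCohort(
        choices=pd.concat(all_choices, ignore_index=True),
        truth=pd.DataFrame(truth_rows),
        seed=seed,
    )
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort
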