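"""Pipeline orchestration: simulate, fit, compare, recover.

Each stage writes delimited-text outputs plus an ``effective_config.yaml``
echoing the settings, seed and package version, so reruns with an identical
config are identical.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .estimators import params_per_participant
from .fitting import ComparisonTable, FitResult, compare_models, fit_group_shared_epsilon
from .likelihood import CHOICE_COLUMNS
from .simulate import CohortConfig, SimulatedCohort, generate_cohort
from .valuation import MODELS

logger = logging.getLogger("infoseek")


@dataclass
class PipelineConfig:
    """Settings shared by the pipeline stages; loadable from YAML."""

    experiment: str = "exp1"
    n_participants: int = 40
    generating_model: str = "up"
    models: List[str] = field(default_factory=lambda: ["evi", "up"])
    n_starts: int = 10
    epsilon_mode: str = "shared"
    bounds: Optional[Dict[str, List[float]]] = None
    miss_rate: float = 0.015
    epsilon: float = 0.03
    beta_range: List[float] = field(default_factory=lambda: [0.5, 3.0])
    k_range: List[float] = field(default_factory=lambda: [0.0, 0.5])
    k_hat_range: List[float] = field(default_factory=lambda: [0.0, 0.5])
    gamma_range: List[float] = field(default_factory=lambda: [1.0, 1.0])


def load_config(path: Optional[Path]) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {k: v for k, v in raw.items() if k in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**known)


def _echo_config(out_dir: Path, config: PipelineConfig, seed: int, stage: str) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "stage": stage,
        "seed": seed,
        "infoseek_version": __version__,
        "config": asdict(config),
    }
    with open(out_dir / "effective_config.yaml", "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def _cohort_config(config: PipelineConfig) -> CohortConfig:
    return CohortConfig(
        experiment=config.experiment,
        n_participants=config.n_participants,
        model=config.generating_model,
        beta_range=tuple(config.beta_range),
        k_range=tuple(config.k_range),
        k_hat_range=tuple(config.k_hat_range),
        gamma_range=tuple(config.gamma_range),
        epsilon=config.epsilon,
        miss_rate=config.miss_rate,
    )


def run_simulate(config: PipelineConfig, seed: int, out_dir: Path) -> SimulatedCohort:
    """Generate a cohort and write ``choices.csv`` and ``truth.csv``."""
    out_dir = Path(out_dir)
    cohort = generate_cohort(_cohort_config(config), seed, out_dir=out_dir)
    _echo_config(out_dir, config, seed, "simulate")
    valid = cohort.choices[cohort.choices["choice"] != "missed"]
    per_condition = valid.groupby(["cost_cents", "rate_s_per_card"]).size()
    logger.info(
        "simulated %d participants, %d valid choices (%d missed)",
        config.n_participants,
        len(valid),
        len(cohort.choices) - len(valid),
    )
    for (cost, rate), count in per_condition.items():
        logger.info("  condition cost=%dc rate=%ds: %d choices", cost, rate, count)
    return cohort


def _load_choices(choices: Path | pd.DataFrame) -> pd.DataFrame:
    if isinstance(choices, pd.DataFrame):
        df = choices
    else:
        df = pd.read_csv(choices)
    missing = [c for c in CHOICE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"choice file is missing columns: {missing}")
    return df


def run_fit(
    choices: Path | pd.DataFrame,
    config: PipelineConfig,
    seed: int,
    out_dir: Optional[Path] = None,
) -> List[FitResult]:
    """Group fit for every requested model; writes a comparison-style report
    (one row per model) plus per-participant estimates."""
    records = _load_choices(choices)
    fits = []
    for model in config.models:
        if model not in MODELS:
            raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
        logger.info("fitting %s model (%d starts)...", model, config.n_starts)
        fit = fit_group_shared_epsilon(
            records,
            model,
            bounds={k: tuple(v) for k, v in (config.bounds or {}).items()} or None,
            n_starts=config.n_starts,
            seed=seed,
            epsilon_mode=config.epsilon_mode,
        )
        logger.info(
            "  %s: -LL=%.2f, BIC=%.2f, epsilon=%.4f, converged=%s",
            model,
            fit.neg_log_likelihood,
            fit.bic,
            fit.epsilon,
            fit.converged,
        )
        fits.append(fit)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report = pd.DataFrame([f.summary_row() for f in fits])
        report.to_csv(out_dir / "fit_report.tsv", sep="\t", index=False)
        estimates = pd.concat(
            {f.model: f.participant_params for f in fits}, names=["model"]
        ).reset_index()
        estimates.to_csv(out_dir / "participant_estimates.csv", index=False)
        _echo_config(out_dir, config, seed, "fit")
    return fits


def run_compare(
    choices: Path | pd.DataFrame,
    config: PipelineConfig,
    seed: int,
    out_dir: Optional[Path] = None,
) -> ComparisonTable:
    """Fit the requested models and emit the comparison table plus
    likelihood-ratio tests for nested pairs."""
    if len(config.models) < 2:
        raise ValueError("model comparison needs at least two models")
    fits = run_fit(choices, config, seed, out_dir=out_dir)
    comparison = compare_models(fits)
    if out_dir is not None:
        out_dir = Path(out_dir)
        comparison.table.to_csv(out_dir / "comparison.tsv", sep="\t", index=False)
        comparison.best_model.rename("best_model").to_csv(out_dir / "best_model.csv")
        if comparison.lrt:
            pd.DataFrame(comparison.lrt).to_csv(out_dir / "lrt.tsv", sep="\t", index=False)
    for row in comparison.lrt:
        logger.info(
            "LRT %s vs %s: chi2(%d) = %.2f, p = %.3g",
            row["reduced"],
            row["full"],
            row["df"],
            row["statistic"],
            row["p_value"],
        )
    return comparison


@dataclass
class RecoveryReport:
    """True-versus-recovered parameter summary of an end-to-end run."""

    params: pd.DataFrame  # per participant: true_* and est_* columns
    rank_correlations: Dict[str, float]
    bias: Dict[str, float]
    rmse: Dict[str, float]
    epsilon_true: float
    epsilon_recovered: float
    n_best_fit: Dict[str, int]
    comparison: ComparisonTable


def run_recover(
    config: PipelineConfig, seed: int, out_dir: Optional[Path] = None
) -> RecoveryReport:
    """Simulate a cohort, fit the requested models, compare them, and report
    parameter- and model-recovery statistics."""
    cohort = generate_cohort(_cohort_config(config), seed)
    models = list(config.models)
    if config.generating_model not in models:
        models = models + [config.generating_model]
    fit_config = PipelineConfig(**{**asdict(config), "models": models})
    comparison_dir = Path(out_dir) if out_dir is not None else None
    fits = run_fit(cohort.choices, fit_config, seed, out_dir=comparison_dir)
    comparison = compare_models(fits)

    gen_fit = next(f for f in fits if f.model == config.generating_model)
    truth = cohort.truth.set_index("participant_id")
    est = gen_fit.participant_params
    shared = [
        name
        for name in ("beta", "k", "k_hat", "gamma")
        if name in est.columns and truth[name].nunique() > 1
    ]
    merged = pd.DataFrame(index=truth.index)
    rank_corr, bias, rmse = {}, {}, {}
    for name in shared:
        merged[f"true_{name}"] = truth[name]
        merged[f"est_{name}"] = est[name]
        rho = stats.spearmanr(truth[name], est[name]).statistic
        rank_corr[name] = float(rho)
        err = est[name] - truth[name]
        bias[name] = float(err.mean())
        rmse[name] = float((err**2).mean() ** 0.5)
        logger.info(
            "recovery %s: spearman rho=%.3f bias=%.3f rmse=%.3f",
            name,
            rank_corr[name],
            bias[name],
            rmse[name],
        )

    report = RecoveryReport(
        params=merged,
        rank_correlations=rank_corr,
        bias=bias,
        rmse=rmse,
        epsilon_true=float(truth["epsilon"].iloc[0]),
        epsilon_recovered=float(gen_fit.epsilon),
        n_best_fit=comparison.n_best_fit,
        comparison=comparison,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        merged.to_csv(out_dir / "recovery_params.csv")
        summary_rows = [
            {
                "parameter": name,
                "spearman_rho": rank_corr[name],
                "bias": bias[name],
                "rmse": rmse[name],
            }
            for name in shared
        ]
        pd.DataFrame(summary_rows).to_csv(out_dir / "recovery_summary.tsv", sep="\t", index=False)
        comparison.table.to_csv(out_dir / "comparison.tsv", sep="\t", index=False)
        _echo_config(out_dir, config, seed, "recover")
    logger.info(
        "epsilon: true=%.3f recovered=%.3f; best-fit counts: %s",
        report.epsilon_true,
        report.epsilon_recovered,
        report.n_best_fit,
    )
    return report
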