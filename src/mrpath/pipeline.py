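"""Config-driven orchestration of the full MR workflow.

``run_forward`` performs screen → clump → harmonize → strength filter →
all estimators → sensitivity → Steiger, and picks a headline estimate by the
decision rule: a significant Egger-intercept (pleiotropy) makes MR-Egger the
headline; otherwise significant Cochran-Q heterogeneity promotes
random-effects IVW; otherwise fixed-effects IVW. ``run_reverse`` swaps the
trait roles, trying the genome-wide threshold first and falling back to the
relaxed 5e-6 screen. ``run_full`` adds per-mediator multivariable MR and the
mediation decomposition and writes one TSV per report table.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .estimators import all_estimates, steiger_test
from .exceptions import EmptyInstrumentSetError
from .instruments import (
    GENOME_WIDE_P,
    RELAXED_P,
    harmonize,
    instrument_strength,
    ld_clump,
    select_instruments,
)
from .io import TraitTable, read_summary_stats
from .mediation import run_mediation
from .mvmr import build_multi_exposure_set, mvmr_fit
from .sensitivity import sensitivity_report

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML via :meth:`from_yaml`."""

    exposure: str | TraitTable | None = None
    outcome: str | TraitTable | None = None
    mediators: list = field(default_factory=list)
    p_threshold_forward: float = GENOME_WIDE_P
    p_threshold_reverse: float = RELAXED_P
    r2_threshold: float = 0.001
    window_kb: float = 10_000
    alpha: float = 0.05
    n_boot: int = 1000
    seed: int = 0
    exclude_weak: bool = True  # drop instruments with F < 10
    output_dir: str | None = None

    def __post_init__(self) -> None:
        for name in ("p_threshold_forward", "p_threshold_reverse", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


@dataclass
class ForwardReport:
    """Everything computed by one forward (or reverse) analysis."""

    estimates: pd.DataFrame
    headline_method: str
    strength: pd.DataFrame
    sensitivity: Any
    steiger: Any
    filter_log: dict[str, Any]
    threshold_used: float


def _as_table(obj, label: str) -> TraitTable:
    if isinstance(obj, TraitTable):
        return obj
    if obj is None:
        raise ValueError(f"{label} table not configured")
    return read_summary_stats(obj)


def _estimates_frame(estimates) -> pd.DataFrame:
    rows = []
    for e in estimates:
        rows.append({
            "method": e.method, "n_snp": e.n_snp, "beta": e.beta, "se": e.se,
            "or": e.or_, "ci_low": e.ci_low, "ci_high": e.ci_high, "pval": e.pval,
            "egger_intercept": e.intercept, "egger_intercept_se": e.intercept_se,
            "egger_intercept_p": e.intercept_p,
        })
    return pd.DataFrame(rows)


def choose_headline(sens, alpha: float) -> str:
    """Decision rule for the primary estimate.

    Pleiotropy (Egger-intercept p < alpha) → ``egger``; else heterogeneity
    (Cochran-Q p < alpha) → ``ivw_random``; else ``ivw_fixed``. Ties at
    exactly p = alpha count as non-significant.
    """
    if sens.egger_intercept_p < alpha:
        return "egger"
    if sens.q_pval < alpha:
        return "ivw_random"
    return "ivw_fixed"


def _analyse(exposure: TraitTable, outcome: TraitTable, config: PipelineConfig,
             p_threshold: float) -> ForwardReport:
    log: dict[str, Any] = {"seed": config.seed, "p_threshold": p_threshold,
                           "n_candidates": exposure.n_snps}
    iv = select_instruments(exposure, p_threshold)
    log["n_significant"] = iv.n_snps
    iv = ld_clump(iv, r2_threshold=config.r2_threshold, window_kb=config.window_kb)
    log["n_after_clump"] = iv.n_snps
    hset = harmonize(iv, outcome)
    log["n_harmonized"] = hset.n_snp

    n_exp = int(exposure.data["n"].iloc[0])
    n_out = int(outcome.data["n"].iloc[0])
    strength = instrument_strength(hset, n=n_exp)
    if config.exclude_weak and strength.n_weak and strength.n_weak < hset.n_snp:
        hset = hset.subset(~strength.weak)
        strength = instrument_strength(hset, n=n_exp)
    log["n_weak_excluded"] = int(strength.weak.sum()) if not config.exclude_weak else \
        log["n_harmonized"] - hset.n_snp
    log["n_final"] = hset.n_snp

    estimates = all_estimates(hset, n_boot=config.n_boot, seed=config.seed)
    sens = sensitivity_report(hset, alpha=config.alpha) if hset.n_snp >= 3 else None
    steiger = steiger_test(hset, n_exp=n_exp, n_out=n_out)
    headline = choose_headline(sens, config.alpha) if sens is not None else "ivw_fixed"
    log["headline_method"] = headline

    strength_df = pd.DataFrame({
        "snp_id": hset.snp_ids, "r2": strength.r2, "f_stat": strength.f_stats,
        "weak": strength.weak,
    })
    return ForwardReport(
        estimates=_estimates_frame(estimates), headline_method=headline,
        strength=strength_df, sensitivity=sens, steiger=steiger,
        filter_log=log, threshold_used=p_threshold,
    )


def run_forward(config: PipelineConfig) -> ForwardReport:
    """Forward MR of the configured exposure on the outcome."""
    exposure = _as_table(config.exposure, "exposure")
    outcome = _as_table(config.outcome, "outcome")
    return _analyse(exposure, outcome, config, config.p_threshold_forward)


def run_reverse(config: PipelineConfig) -> ForwardReport:
    """Reverse MR: outcome instruments, exposure as outcome.

    Tries the strict forward threshold first; when no instruments survive it
    falls back to the relaxed threshold, recording which one was used.
    """
    exposure = _as_table(config.exposure, "exposure")
    outcome = _as_table(config.outcome, "outcome")
    try:
        return _analyse(outcome, exposure, config, config.p_threshold_forward)
    except EmptyInstrumentSetError:
        logger.info("reverse MR: no instruments at p < %g, relaxing to %g",
                    config.p_threshold_forward, config.p_threshold_reverse)
        return _analyse(outcome, exposure, config, config.p_threshold_reverse)


@dataclass
class FullReport:
    forward: ForwardReport
    reverse: ForwardReport | None
    mvmr_models: list
    mediation: list
    tables: dict[str, pd.DataFrame]


def run_full(config: PipelineConfig) -> FullReport:
    """Forward + reverse MR, per-mediator MVMR and mediation decomposition.

    When ``config.output_dir`` is set, six TSV report tables are written:
    instrument strength, MR estimates, pleiotropy, Steiger, MVMR direct
    effects, and the mediation decomposition.
    """
    exposure = _as_table(config.exposure, "exposure")
    outcome = _as_table(config.outcome, "outcome")
    mediators = [_as_table(m, "mediator") for m in config.mediators]

    forward = run_forward(config)
    try:
        reverse = run_reverse(config)
    except EmptyInstrumentSetError:
        logger.warning("reverse MR skipped: no instruments at either threshold")
        reverse = None

    mvmr_models, mediation_results = [], []
    for i, med in enumerate(mediators, start=1):
        mset = build_multi_exposure_set(
            [exposure, med], outcome, p_threshold=config.p_threshold_forward,
            r2_threshold=config.r2_threshold, window_kb=config.window_kb,
        )
        mvmr_models.append(mvmr_fit(mset, model_label=f"model{i}"))
        mediation_results.append(run_mediation(
            exposure, med, outcome, p_threshold=config.p_threshold_forward,
            r2_threshold=config.r2_threshold, window_kb=config.window_kb,
            alpha=config.alpha,
        ))

    sens = forward.sensitivity
    tables = {
        "instrument_strength": pd.DataFrame([{
            "exposure": exposure.trait_id, "n_snp": len(forward.strength),
            "f_median": forward.strength["f_stat"].median(),
            "f_min": forward.strength["f_stat"].min(),
            "f_max": forward.strength["f_stat"].max(),
        }]),
        "mr_estimates": forward.estimates,
        "pleiotropy": pd.DataFrame([{
            "exposure": exposure.trait_id,
            "egger_intercept": sens.egger_intercept if sens else None,
            "se": sens.egger_intercept_se if sens else None,
            "pval": sens.egger_intercept_p if sens else None,
        }]),
        "steiger": pd.DataFrame([{
            "exposure": exposure.trait_id, "outcome": outcome.trait_id,
            "r2_exposure": forward.steiger.r2_exposure,
            "r2_outcome": forward.steiger.r2_outcome,
            "correct_direction": forward.steiger.correct_direction,
            "steiger_pval": forward.steiger.pval,
        }]),
        "mvmr": pd.DataFrame([
            {"model": m.model_label, "exposure": e.exposure_id,
             "n_snp_significant": e.n_snp_significant, "beta": e.beta, "se": e.se,
             "or": e.or_, "ci_low": e.ci_low, "ci_high": e.ci_high, "pval": e.pval}
            for m in mvmr_models for e in m.exposures
        ]),
        "mediation": pd.DataFrame([r.table_row | {
            "se_m": r.se_m, "significant": r.significant,
            "significance_path": r.significance_path,
            "proportion_denominator": r.proportion_denominator,
        } for r in mediation_results]),
    }
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format="%.10g")
    return FullReport(forward=forward, reverse=reverse, mvmr_models=mvmr_models,
                      mediation=mediation_results, tables=tables)
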