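"""Product-of-coefficients mediation on MR effect estimates.

The indirect (mediated) effect of an exposure on an outcome through one
mediator is the product β_M = β_A·β_B of the exposure→mediator effect (from
univariable MR) and the mediator→outcome *direct* effect (from multivariable
MR conditioning on the exposure). Its standard error uses the delta method:

    two_term  (default):  SE_M = sqrt((β_A·SE_B)² + (β_B·SE_A)²)
    three_term:           adds + SE_A²·SE_B² under the root

The two-term variant is the classical first-order delta method; the
three-term variant is the exact variance of a product of independent normals.
The difference only matters when the factor SEs are large relative to the
effects. Both are exposed; two_term is the default and the one whose CIs are
internally consistent with the package's reporting conventions.

Significance follows the causal-stepwise rule: if both β_A and β_B are
individually significant the indirect effect is declared significant via the
stepwise path; otherwise a Sobel z-test on β_M/SE_M decides.

The proportion mediated uses sign-dependent conventions: when β_M and the
exposure's direct effect β_C′ have *opposite* signs the proportion is
|β_M/β_C′|·100 (a proportion of the direct effect); when they share a sign
it is (β_M/β_C)·100 with β_C the univariable total effect. Both conventions
are reported verbatim; interpretation of the mixed-denominator rule is left
to the analyst.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import stats

from .estimators import Z95, ivw
from .exceptions import MRPathError, UndefinedProportionError
from .instruments import GENOME_WIDE_P, harmonize, ld_clump, select_instruments
from .io import TraitTable
from .mvmr import build_multi_exposure_set, mvmr_fit

__all__ = [
    "MediationInput", "MediationResult", "indirect_effect",
    "mediation_significance", "proportion_mediated", "run_mediation",
]


@dataclass
class MediationInput:
    """The four MR effects feeding the mediation calculus.

    β_A: exposure→mediator (univariable MR); β_B: mediator→outcome direct
    effect (MVMR); β_C: exposure→outcome total effect (univariable MR);
    β_C′: exposure→outcome direct effect (MVMR). All with SEs > 0.
    """

    beta_a: float
    se_a: float
    beta_b: float
    se_b: float
    beta_c: float
    se_c: float
    beta_c_prime: float
    se_c_prime: float
    exposure: str = "exposure"
    mediator: str = "mediator"
    outcome: str = "outcome"

    def __post_init__(self) -> None:
        for name in ("se_a", "se_b", "se_c", "se_c_prime"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class MediationResult:
    """Indirect effect, its significance and the proportion mediated."""

    beta_m: float
    se_m: float
    ci_m: tuple[float, float]
    sobel_z: float
    sobel_p: float
    significant: bool
    significance_path: str  # "stepwise" | "sobel"
    proportion: float | None
    proportion_denominator: str | None  # "direct" (β_C′) | "total" (β_C)
    inputs: MediationInput
    table_row: dict[str, Any] = field(default_factory=dict)


def _ci(beta: float, se: float) -> tuple[float, float]:
    return beta - Z95 * se, beta + Z95 * se


def indirect_effect(
    beta_a: float, se_a: float, beta_b: float, se_b: float,
    se_variant: str = "two_term",
) -> tuple[float, float]:
    """β_M = β_A·β_B with delta-method SE (``two_term`` or ``three_term``)."""
    if se_variant not in ("two_term", "three_term"):
        raise ValueError("se_variant must be 'two_term' or 'three_term'")
    beta_m = beta_a * beta_b
    var = (beta_a * se_b) ** 2 + (beta_b * se_a) ** 2
    if se_variant == "three_term":
        var += se_a**2 * se_b**2
    return float(beta_m), float(np.sqrt(var))


def mediation_significance(
    inp: MediationInput, alpha: float = 0.05, se_variant: str = "two_term"
) -> tuple[bool, str, float]:
    """Causal-stepwise rule first, Sobel test as fallback.

    Returns (significant, path, sobel_p); the Sobel p is computed either way
    for reporting.
    """
    crit = stats.norm.isf(alpha / 2.0)
    beta_m, se_m = indirect_effect(inp.beta_a, inp.se_a, inp.beta_b, inp.se_b, se_variant)
    sobel_z = beta_m / se_m if se_m > 0 else np.inf * np.sign(beta_m)
    sobel_p = float(2.0 * stats.norm.sf(abs(sobel_z)))
    if abs(inp.beta_a / inp.se_a) > crit and abs(inp.beta_b / inp.se_b) > crit:
        return True, "stepwise", sobel_p
    return sobel_p < alpha, "sobel", sobel_p


def proportion_mediated(
    inp: MediationInput, beta_m: float
) -> tuple[float, str]:
    """Sign-dependent proportion mediated, as a percentage.

    Opposite signs of β_M and β_C′ → |β_M/β_C′|·100 with the *direct* effect
    as denominator; same sign → (β_M/β_C)·100 against the *total* effect.
    """
    if np.sign(beta_m) != np.sign(inp.beta_c_prime):
        if inp.beta_c_prime == 0:
            raise UndefinedProportionError("direct effect β_C′ is zero")
        return float(abs(beta_m / inp.beta_c_prime) * 100.0), "direct"
    if inp.beta_c == 0:
        raise UndefinedProportionError("total effect β_C is zero")
    return float(beta_m / inp.beta_c * 100.0), "total"


def _stage(name: str):
    """Context manager tagging errors with the pipeline stage they came from."""
    import contextlib

    @contextlib.contextmanager
    def cm():
        try:
            yield
        except MRPathError as err:
            err.args = (f"[stage: {name}] {err.args[0] if err.args else ''}",) + err.args[1:]
            raise
    return cm()


def run_mediation(
    exposure: TraitTable,
    mediator: TraitTable,
    outcome: TraitTable,
    p_threshold: float = GENOME_WIDE_P,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
    alpha: float = 0.05,
    se_variant: str = "two_term",
) -> MediationResult:
    """Full one-mediator decomposition from three summary-stat tables.

    Orchestrates: univariable IVW exposure→mediator (β_A) and
    exposure→outcome (β_C); multivariable MR of {exposure, mediator} on the
    outcome (β_C′ for the exposure, β_B for the mediator); then the indirect
    effect, its significance and the proportion mediated. Errors raised by a
    stage are re-raised tagged with the stage name.
    """
    with _stage("select/clump exposure instruments"):
        iv = ld_clump(select_instruments(exposure, p_threshold),
                      r2_threshold=r2_threshold, window_kb=window_kb)
    # random-effects IVW: the mediator's own SNP effects act as real
    # heterogeneity in the exposure->mediator ratios, so the fixed-effect SE
    # would be badly anti-conservative for the stepwise significance rule
    with _stage("univariable MR exposure->mediator"):
        est_a = ivw(harmonize(iv, mediator), "random")
    with _stage("univariable MR exposure->outcome"):
        est_c = ivw(harmonize(iv, outcome), "random")
    with _stage("multivariable MR {exposure, mediator}->outcome"):
        mset = build_multi_exposure_set(
            [exposure, mediator], outcome, p_threshold=p_threshold,
            r2_threshold=r2_threshold, window_kb=window_kb,
        )
        mv = mvmr_fit(mset)
    direct_exp = mv.by_id(exposure.trait_id)
    direct_med = mv.by_id(mediator.trait_id)

    inp = MediationInput(
        beta_a=est_a.beta, se_a=est_a.se,
        beta_b=direct_med.beta, se_b=direct_med.se,
        beta_c=est_c.beta, se_c=est_c.se,
        beta_c_prime=direct_exp.beta, se_c_prime=direct_exp.se,
        exposure=exposure.trait_id, mediator=mediator.trait_id,
        outcome=outcome.trait_id,
    )
    beta_m, se_m = indirect_effect(inp.beta_a, inp.se_a, inp.beta_b, inp.se_b, se_variant)
    significant, path, sobel_p = mediation_significance(inp, alpha=alpha, se_variant=se_variant)
    sobel_z = beta_m / se_m if se_m > 0 else float("inf")
    try:
        proportion, denom = proportion_mediated(inp, beta_m)
    except UndefinedProportionError:
        proportion, denom = None, None
    table_row = {
        "exposure": inp.exposure, "mediator": inp.mediator, "outcome": inp.outcome,
        "total_effect": inp.beta_c, "total_ci": _ci(inp.beta_c, inp.se_c),
        "effect_e_m": inp.beta_a, "effect_e_m_ci": _ci(inp.beta_a, inp.se_a),
        "effect_m_o": inp.beta_b, "effect_m_o_ci": _ci(inp.beta_b, inp.se_b),
        "effect_e_o": inp.beta_c_prime, "effect_e_o_ci": _ci(inp.beta_c_prime, inp.se_c_prime),
        "mediation_effect": beta_m, "mediation_ci": _ci(beta_m, se_m),
        "proportion_pct": proportion, "sobel_p": sobel_p,
    }
    return MediationResult(
        beta_m=beta_m, se_m=se_m, ci_m=_ci(beta_m, se_m),
        sobel_z=float(sobel_z), sobel_p=sobel_p,
        significant=significant, significance_path=path,
        proportion=proportion, proportion_denominator=denom,
        inputs=inp, table_row=table_row,
    )
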