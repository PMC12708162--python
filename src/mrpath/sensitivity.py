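"""Heterogeneity, pleiotropy, leave-one-out and funnel diagnostics.

All diagnostics use the same first-order ratio weights as the IVW estimator
so that Q, I² and the leave-one-out series are internally consistent with the
primary estimate. The funnel is emitted as plot-ready (ratio, precision)
coordinates together with a numeric symmetry test, since this package writes
tables rather than figures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .estimators import MREstimate, _ivw_core, _ratio_arrays, ivw, mr_egger
from .exceptions import InsufficientInstrumentsError
from .instruments import HarmonizedInstrumentSet


@dataclass
class LeaveOneOutEntry:
    excluded_snp: str
    beta: float
    se: float
    influential: bool


@dataclass
class SensitivityReport:
    """Bundle of all sensitivity diagnostics for one instrument set."""

    q_stat: float
    q_df: int
    q_pval: float
    i2: float
    i2_band: str
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_p: float
    pleiotropy_flag: bool
    loo_estimates: list[LeaveOneOutEntry]
    funnel: list[tuple[float, float]]
    funnel_symmetry_p: float


def cochran_q(
    hset: HarmonizedInstrumentSet, estimate: MREstimate | None = None
) -> tuple[float, int, float]:
    """Cochran's Q across per-SNP Wald ratios: Q = Σ wⱼ(ratioⱼ − β̂)².

    Uses the IVW point estimate (recomputed if not supplied) and IVW weights;
    p-value from chi-square with n_snp − 1 df.
    """
    if hset.n_snp < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs at least 2 instruments")
    *_, ratios, weights = _ratio_arrays(hset)
    if len(ratios) < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs at least 2 usable instruments")
    beta = estimate.beta if estimate is not None else _ivw_core(ratios, weights)[0]
    q = float(np.sum(weights * (ratios - beta) ** 2))
    df = len(ratios) - 1
    return q, df, float(stats.chi2.sf(q, df))


_I2_BANDS = ((25.0, "mild"), (50.0, "moderate"), (float("inf"), "high"))


def i_squared(q: float, df: int) -> tuple[float, str]:
    """I² = (Q − df)/Q × 100, clamped to 0 when Q ≤ df.

    Returns the percentage and its heterogeneity band: mild [0, 25],
    moderate (25, 50], high (> 50).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if q < 0:
        raise ValueError("q must be >= 0")
    i2 = 0.0 if q == 0 else max(0.0, (q - df) / q) * 100.0
    band = next(label for bound, label in _I2_BANDS if i2 <= bound)
    return i2, band


def egger_intercept_test(
    hset: HarmonizedInstrumentSet, alpha: float = 0.05
) -> tuple[float, float, float, bool]:
    """Directional-pleiotropy test: the MR-Egger intercept triple.

    Returns (intercept, se, p, significant-at-alpha). A p-value below alpha
    is read as evidence of horizontal pleiotropy.
    """
    est = mr_egger(hset)
    return est.intercept, est.intercept_se, est.intercept_p, est.intercept_p < alpha


def leave_one_out(hset: HarmonizedInstrumentSet) -> list[LeaveOneOutEntry]:
    """IVW re-estimated with each SNP excluded in turn.

    An exclusion is flagged as influential when it flips the sign of the
    estimate or moves it by more than one full-set SE.
    """
    if hset.n_snp < 2:
        raise InsufficientInstrumentsError("leave-one-out needs at least 2 instruments")
    full = ivw(hset, "fixed")
    entries = []
    for j in range(hset.n_snp):
        mask = np.ones(hset.n_snp, dtype=bool)
        mask[j] = False
        est = ivw(hset.subset(mask), "fixed")
        influential = (np.sign(est.beta) != np.sign(full.beta)) or (
            abs(est.beta - full.beta) > full.se
        )
        entries.append(
            LeaveOneOutEntry(str(hset.snp_ids[j]), est.beta, est.se, bool(influential))
        )
    return entries


def funnel_coordinates(
    hset: HarmonizedInstrumentSet,
) -> tuple[list[tuple[float, float]], float]:
    """Per-SNP (Wald ratio, precision) pairs plus a numeric symmetry test.

    Precision is 1/SE of the ratio (first order). Symmetry is quantified by
    the precision-weighted regression of ratio on precision (the ratio-space
    analogue of the Egger intercept test); the returned p-value tests the
    precision coefficient, with small values indicating asymmetry.
    """
    *_, ratios, weights = _ratio_arrays(hset)
    precision = np.sqrt(weights)
    coords = list(zip(ratios.tolist(), precision.tolist()))
    if len(ratios) >= 3 and np.ptp(precision) > 0:
        X = sm.add_constant(precision)
        fit = sm.WLS(ratios, X, weights=weights).fit()
        floor = min(1.0, float(np.sqrt(fit.scale)))
        se = fit.bse[1] / floor if floor > 0 else 0.0
        if se > 0:
            sym_p = float(2.0 * stats.t.sf(abs(fit.params[1]) / se, len(ratios) - 2))
        else:
            sym_p = 1.0 if fit.params[1] == 0 else 0.0
    else:
        # fewer than 3 SNPs, or all precisions equal: no symmetry information
        sym_p = float("nan")
    return coords, sym_p


def sensitivity_report(
    hset: HarmonizedInstrumentSet, alpha: float = 0.05
) -> SensitivityReport:
    """All diagnostics in one pass (needs at least 3 instruments)."""
    q, df, q_p = cochran_q(hset)
    i2, band = i_squared(q, df)
    intercept, int_se, int_p, flag = egger_intercept_test(hset, alpha=alpha)
    loo = leave_one_out(hset)
    funnel, sym_p = funnel_coordinates(hset)
    return SensitivityReport(
        q_stat=q, q_df=df, q_pval=q_p, i2=i2, i2_band=band,
        egger_intercept=intercept, egger_intercept_se=int_se,
        egger_intercept_p=int_p, pleiotropy_flag=flag,
        loo_estimates=loo, funnel=funnel, funnel_symmetry_p=sym_p,
    )
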