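"""The five two-sample MR causal-effect estimators plus directionality.

All estimators consume a :class:`~mrpath.instruments.HarmonizedInstrumentSet`
and return an :class:`MREstimate` whose beta is on the log-odds scale for
binary outcomes, with the odds ratio and 95% CI attached (z = 1.959964).

* Wald ratio / IVW — the inverse-variance-weighted meta-analysis of per-SNP
  Wald ratios with first-order weights (bx/sy)², the primary estimator.
  The random-effects variant inflates the SE by the multiplicative
  overdispersion sqrt(max(1, Q/(n−1))).
* MR-Egger — weighted regression of outcome on exposure effects *with* an
  intercept; the intercept estimates directional pleiotropy. SNPs are
  oriented to non-negative exposure effects before fitting so the intercept
  is well defined.
* Weighted median — consistent when less than half the instrument weight is
  invalid; SE by seeded parametric bootstrap.
* Simple / weighted mode — kernel-density argmax over the ratio distribution,
  consistent when the largest group of instruments sharing a ratio is valid.
* Steiger test — compares the variance in exposure vs outcome explained by
  the instruments to check that causality runs exposure → outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .exceptions import (
    EmptyInstrumentSetError,
    IndeterminateDirectionError,
    InsufficientInstrumentsError,
)
from .instruments import HarmonizedInstrumentSet, variance_explained

logger = logging.getLogger(__name__)

#: 97.5% normal quantile used for all 95% confidence intervals.
Z95 = 1.959964


@dataclass
class MREstimate:
    """One method's causal estimate.

    ``beta`` is the causal log-odds per unit exposure; ``or_`` = exp(beta)
    with its 95% CI; ``intercept*`` fields are populated for MR-Egger only.
    """

    method: str
    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None


@dataclass
class SteigerResult:
    """Directionality check: variance explained on each side of the arrow."""

    r2_exposure: float
    r2_outcome: float
    correct_direction: bool
    pval: float


def or_from_beta(beta: float, se: float) -> tuple[float, float, float]:
    """Odds ratio and 95% CI from a log-odds estimate: exp(beta ± 1.959964·se)."""
    if se < 0:
        raise ValueError("se must be >= 0")
    return float(np.exp(beta)), float(np.exp(beta - Z95 * se)), float(np.exp(beta + Z95 * se))


def _estimate(method: str, beta: float, se: float, n_snp: int,
              pval: float | None = None, **extra) -> MREstimate:
    or_, lo, hi = or_from_beta(beta, se)
    if pval is None:
        pval = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else (0.0 if beta else 1.0)
    return MREstimate(method=method, beta=float(beta), se=float(se), or_=or_,
                      ci_low=lo, ci_high=hi, pval=float(pval), n_snp=int(n_snp), **extra)


def wald_ratio(bx: float, sx: float, by: float, sy: float) -> MREstimate:
    """Single-SNP causal estimate by/bx with first-order SE sy/|bx|."""
    if sx <= 0 or sy <= 0:
        raise ValueError("standard errors must be > 0")
    if bx == 0:
        raise ValueError("wald ratio undefined for bx = 0")
    return _estimate("wald_ratio", by / bx, sy / abs(bx), 1)


def _ratio_arrays(hset: HarmonizedInstrumentSet):
    """Per-SNP ratios with first-order weights, excluding bx = 0 SNPs."""
    keep = hset.beta_exp != 0.0
    if not keep.all():
        logger.warning("excluding %d SNP(s) with zero exposure effect", int((~keep).sum()))
    if not keep.any():
        raise EmptyInstrumentSetError("all SNPs have zero exposure effect")
    bx, by = hset.beta_exp[keep], hset.beta_out[keep]
    sx, sy = hset.se_exp[keep], hset.se_out[keep]
    ratios = by / bx
    weights = (bx / sy) ** 2  # = 1 / first-order ratio variance
    return bx, sx, by, sy, ratios, weights


def _ivw_core(ratios: np.ndarray, weights: np.ndarray):
    beta = float(np.sum(weights * ratios) / np.sum(weights))
    q = float(np.sum(weights * (ratios - beta) ** 2))
    se_fixed = float(1.0 / np.sqrt(np.sum(weights)))
    return beta, se_fixed, q


def ivw(hset: HarmonizedInstrumentSet, mode: str = "fixed") -> MREstimate:
    """Inverse-variance-weighted estimate.

    Equivalent to the zero-intercept weighted regression of outcome betas on
    exposure betas with weights 1/sy². ``mode="random"`` applies the
    multiplicative overdispersion sqrt(max(1, Q/(n−1))) to the SE.
    """
    if mode not in ("fixed", "random"):
        raise ValueError("mode must be 'fixed' or 'random'")
    *_, ratios, weights = _ratio_arrays(hset)
    n = len(ratios)
    beta, se, q = _ivw_core(ratios, weights)
    if mode == "random" and n > 1:
        se *= float(np.sqrt(max(1.0, q / (n - 1))))
    return _estimate(f"ivw_{mode}", beta, se, n)


def mr_egger(hset: HarmonizedInstrumentSet) -> MREstimate:
    """MR-Egger regression: weighted fit of by on bx with an intercept.

    SNPs are oriented so bx ≥ 0 (flipping by in step). The intercept and its
    test estimate directional pleiotropy; the slope is the causal estimate.
    Inference is classical weighted-regression inference: SEs scale with the
    estimated residual dispersion (not truncated below 1, which would make
    the pleiotropy test conservative) and p-values use the t distribution
    with n − 2 df.
    """
    if hset.n_snp < 3:
        raise InsufficientInstrumentsError("MR-Egger needs at least 3 instruments")
    bx, _, by, sy, *_ = _ratio_arrays(hset)
    if len(bx) < 3:
        raise InsufficientInstrumentsError("MR-Egger needs at least 3 usable instruments")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=1.0 / sy**2).fit()
    se_int, se_slope = float(fit.bse[0]), float(fit.bse[1])
    df = len(bx) - 2

    def _p(param, se):
        if se > 0:
            return 2.0 * stats.t.sf(abs(param) / se, df)
        return 1.0 if param == 0 else 0.0

    p_slope = _p(fit.params[1], se_slope)
    p_int = _p(fit.params[0], se_int)
    return _estimate(
        "egger", fit.params[1], se_slope, len(bx), pval=p_slope,
        intercept=float(fit.params[0]), intercept_se=float(se_int),
        intercept_p=float(p_int),
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Linear interpolation of the weighted empirical CDF at probability 0.5."""
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cdf = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, cdf, v))


def _delta_ratio_var(bx, sx, by, sy) -> np.ndarray:
    """Delta-method variance of by/bx including exposure-side noise."""
    return sy**2 / bx**2 + by**2 * sx**2 / bx**4


def weighted_median(
    hset: HarmonizedInstrumentSet, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    Per-SNP Wald ratios are ordered and weighted by the inverse of their
    delta-method variance; the estimate interpolates the weighted empirical
    CDF at 0.5. It is consistent when under half the total weight comes from
    invalid instruments. The SE resamples per-SNP betas from their sampling
    distributions (``n_boot`` draws, seeded); ``n_boot=0`` skips the
    bootstrap and reports a NaN SE (point estimate only).
    """
    if hset.n_snp < 3:
        raise InsufficientInstrumentsError("weighted median needs at least 3 instruments")
    bx, sx, by, sy, ratios, _ = _ratio_arrays(hset)
    if len(bx) < 3:
        raise InsufficientInstrumentsError("weighted median needs at least 3 usable instruments")
    weights = 1.0 / _delta_ratio_var(bx, sx, by, sy)
    beta = _weighted_median(ratios, weights)
    if n_boot:
        rng = np.random.default_rng(seed)
        bxs = rng.normal(bx, sx, size=(n_boot, len(bx)))
        bys = rng.normal(by, sy, size=(n_boot, len(bx)))
        bxs = np.where(bxs == 0.0, np.finfo(float).tiny, bxs)
        rs = bys / bxs
        ws = 1.0 / _delta_ratio_var(bxs, sx, bys, sy)
        draws = np.array([_weighted_median(r, w) for r, w in zip(rs, ws)])
        se = float(draws.std(ddof=1))
    else:
        se = np.nan
    if not np.isfinite(se) or se == 0.0:
        return MREstimate("weighted_median", float(beta), float(se), float(np.exp(beta)),
                          np.nan, np.nan, np.nan, len(bx))
    return _estimate("weighted_median", beta, se, len(bx))


def _silverman_bandwidth(ratios: np.ndarray, factor: float) -> float:
    """Modified Silverman rule: 0.9·min(sd, scaled MAD)·n^(−1/5), times factor."""
    n = len(ratios)
    sd = float(np.std(ratios, ddof=1))
    mad = 1.4826 * float(np.median(np.abs(ratios - np.median(ratios))))
    base = min(x for x in (sd, mad) if x > 0) if (sd > 0 or mad > 0) else 0.0
    if base == 0.0:
        base = max(abs(float(ratios[0])), 1.0) * 1e-6  # degenerate: all ratios equal
    return factor * 0.9 * base * n ** (-0.2)


def _kde_mode(ratios: np.ndarray, weights: np.ndarray, h: float, grid_points: int = 512) -> float:
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, grid_points)
    dens = (weights[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2)).sum(axis=0)
    return float(grid[np.argmax(dens)])


def mode_estimate(
    hset: HarmonizedInstrumentSet,
    weighted: bool = False,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Mode-based estimate: argmax of a kernel-smoothed ratio density.

    Normal kernel; bandwidth = ``bandwidth_factor`` × the modified Silverman
    rule on the ratios; density evaluated on a 512-point grid spanning the
    ratio range ± 3 bandwidths. The weighted variant weights each kernel by
    the inverse delta-method ratio variance. SE by seeded parametric
    bootstrap (``n_boot=0`` skips it).
    """
    if bandwidth_factor <= 0:
        raise ValueError("bandwidth_factor must be > 0")
    if hset.n_snp < 3:
        raise InsufficientInstrumentsError("mode estimators need at least 3 instruments")
    bx, sx, by, sy, ratios, _ = _ratio_arrays(hset)
    if len(bx) < 3:
        raise InsufficientInstrumentsError("mode estimators need at least 3 usable instruments")

    def point(r, w_var):
        w = 1.0 / w_var if weighted else np.ones_like(r)
        w = w / w.sum()
        return _kde_mode(r, w, _silverman_bandwidth(r, bandwidth_factor))

    beta = point(ratios, _delta_ratio_var(bx, sx, by, sy))
    method = "weighted_mode" if weighted else "simple_mode"
    if n_boot:
        rng = np.random.default_rng(seed)
        draws = np.empty(n_boot)
        for b in range(n_boot):
            bxs = rng.normal(bx, sx)
            bys = rng.normal(by, sy)
            bxs = np.where(bxs == 0.0, np.finfo(float).tiny, bxs)
            draws[b] = point(bys / bxs, _delta_ratio_var(bxs, sx, bys, sy))
        se = float(draws.std(ddof=1))
    else:
        se = np.nan
    if not np.isfinite(se) or se == 0.0:
        return MREstimate(method, float(beta), float(se), float(np.exp(beta)),
                          np.nan, np.nan, np.nan, len(bx))
    return _estimate(method, beta, se, len(bx))


def steiger_test(hset: HarmonizedInstrumentSet, n_exp: int, n_out: int) -> SteigerResult:
    """Directionality via variance explained.

    r² on each side sums 2·MAF·(1−MAF)·β² over instruments; causality is
    declared exposure → outcome when r²_exposure > r²_outcome. The p-value is
    a Fisher-z test comparing the implied correlation magnitudes
    sqrt(r²) between the two GWAS panels:
    z = (atanh r_exp − atanh r_out)/sqrt(1/(n_exp−3) + 1/(n_out−3)).
    """
    if n_exp <= 3 or n_out <= 3:
        raise ValueError("sample sizes must exceed 3")
    r2_exp = float(variance_explained(hset.eaf_exp, hset.beta_exp).sum())
    eaf_out = hset.eaf_out if hset.eaf_out is not None else hset.eaf_exp
    r2_out = float(variance_explained(eaf_out, hset.beta_out).sum())
    if r2_exp == 0.0 and r2_out == 0.0:
        raise IndeterminateDirectionError("no variance explained on either side")
    r_exp, r_out = min(np.sqrt(r2_exp), 1 - 1e-12), min(np.sqrt(r2_out), 1 - 1e-12)
    z = (np.arctanh(r_exp) - np.arctanh(r_out)) / np.sqrt(
        1.0 / (n_exp - 3) + 1.0 / (n_out - 3)
    )
    pval = float(2.0 * stats.norm.sf(abs(z)))
    return SteigerResult(
        r2_exposure=r2_exp, r2_outcome=r2_out,
        correct_direction=bool(r2_exp > r2_out), pval=pval,
    )


def all_estimates(
    hset: HarmonizedInstrumentSet, n_boot: int = 1000, seed: int = 0
) -> list[MREstimate]:
    """IVW (fixed and random), Egger, weighted median and both modes.

    Estimators whose instrument requirements are not met are skipped.
    """
    out = [ivw(hset, "fixed"), ivw(hset, "random")]
    if hset.n_snp >= 3:
        out.append(mr_egger(hset))
        out.append(weighted_median(hset, n_boot=n_boot, seed=seed))
        out.append(mode_estimate(hset, weighted=False, n_boot=n_boot, seed=seed + 1))
        out.append(mode_estimate(hset, weighted=True, n_boot=n_boot, seed=seed + 2))
    return out
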