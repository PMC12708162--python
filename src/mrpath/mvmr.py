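"""Multivariable MR: direct effects of several exposures on one outcome.

The instrument set is the union of SNPs genome-wide significant for *any*
exposure, clumped jointly with the lowest cross-exposure p-value as priority
and harmonized to a common effect allele across all traits. The fit is a
weighted multivariable regression of outcome betas on the matrix of exposure
betas with no intercept and weights 1/se_out² — each coefficient is that
exposure's direct effect conditional on the others.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .estimators import or_from_beta
from .exceptions import CollinearExposuresError, InsufficientInstrumentsError
from .instruments import GENOME_WIDE_P, harmonize, ld_clump
from .io import TraitTable

logger = logging.getLogger(__name__)


@dataclass
class MultiExposureSet:
    """Per-SNP effects for E ≥ 2 exposures plus the outcome, allele-aligned."""

    snp_ids: np.ndarray
    exposure_ids: list[str]
    beta_matrix: np.ndarray  # n_snp × E
    se_matrix: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    sig_counts: np.ndarray | None = None  # per exposure: retained genome-wide-significant SNPs

    def __post_init__(self) -> None:
        n, e = self.beta_matrix.shape
        if e < 2:
            raise ValueError("need at least 2 exposures")
        if self.se_matrix.shape != (n, e) or len(self.beta_out) != n or len(self.snp_ids) != n:
            raise ValueError("inconsistent dimensions")
        if n <= e:
            raise InsufficientInstrumentsError(
                f"{n} SNP(s) cannot identify {e} exposures (need n_snp > E)"
            )

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    @property
    def n_exposures(self) -> int:
        return self.beta_matrix.shape[1]


@dataclass
class ExposureDirectEffect:
    exposure_id: str
    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp_significant: int


@dataclass
class MVMRResult:
    """Direct effect of each exposure conditional on the others."""

    exposures: list[ExposureDirectEffect]
    n_snp: int
    condition_number: float
    model_label: str = ""

    def by_id(self, exposure_id: str) -> ExposureDirectEffect:
        for e in self.exposures:
            if e.exposure_id == exposure_id:
                return e
        raise KeyError(exposure_id)


def build_multi_exposure_set(
    exposures: list[TraitTable],
    outcome: TraitTable,
    p_threshold: float = GENOME_WIDE_P,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
    ld=None,
) -> MultiExposureSet:
    """Pool, clump and harmonize instruments across exposures.

    SNPs significant for any exposure enter the pool; joint clumping uses
    each SNP's lowest p-value across exposures as priority. Per-SNP effects
    are retained for every exposure even where sub-threshold for that
    exposure. Everything is aligned to the first exposure's allele coding.
    """
    if len(exposures) < 2:
        raise ValueError("multivariable MR needs at least 2 exposures")

    # union of significant SNPs, carrying the best p across exposures
    frames = []
    for t in exposures:
        sub = t.data.loc[t.data["pval"] < p_threshold]
        if not sub.empty:
            frames.append(sub)
    if not frames:
        raise InsufficientInstrumentsError(
            f"no SNPs pass p < {p_threshold:g} for any exposure"
        )
    pooled = pd.concat(frames, ignore_index=True)
    pooled = pooled.sort_values(["snp_id", "pval"], kind="mergesort").drop_duplicates("snp_id")
    pooled = pooled.reset_index(drop=True)
    union = TraitTable("mvmr-pool", pooled, exposures[0].trait_type)
    clumped = ld_clump(union, r2_threshold=r2_threshold, window_kb=window_kb, ld=ld)
    snp_ids = clumped.data["snp_id"]

    # align every trait to the pool's allele coding via pairwise harmonization
    reference = TraitTable("mvmr-pool", clumped.data, exposures[0].trait_type)
    aligned_beta, aligned_se, sig_counts, kept_ids = [], [], [], None
    for t in exposures + [outcome]:
        sub = t.subset(t.data["snp_id"].isin(snp_ids).to_numpy())
        h = harmonize(reference, sub)
        df = pd.DataFrame({"snp_id": h.snp_ids, "beta": h.beta_out, "se": h.se_out})
        ids = set(df["snp_id"])
        kept_ids = ids if kept_ids is None else kept_ids & ids
        aligned_beta.append(df)
    keep = [s for s in snp_ids if s in kept_ids]
    if len(keep) <= len(exposures):
        raise InsufficientInstrumentsError(
            f"only {len(keep)} SNP(s) shared across all traits; need more than "
            f"{len(exposures)} to identify the direct effects"
        )
    mats_b, mats_s = [], []
    for df in aligned_beta:
        df = df.set_index("snp_id").loc[keep]
        mats_b.append(df["beta"].to_numpy())
        mats_s.append(df["se"].to_numpy())
    beta_matrix = np.column_stack(mats_b[:-1])
    se_matrix = np.column_stack(mats_s[:-1])

    # per-exposure count of retained genome-wide-significant SNPs
    sig_counts = []
    for t in exposures:
        sig = t.data.loc[t.data["pval"] < p_threshold, "snp_id"]
        sig_counts.append(int(sum(s in set(sig) for s in keep)))

    # warn on effectively duplicated exposures
    e = beta_matrix.shape[1]
    for i in range(e):
        for j in range(i + 1, e):
            ci, cj = beta_matrix[:, i], beta_matrix[:, j]
            if np.std(ci) > 0 and np.std(cj) > 0 and abs(np.corrcoef(ci, cj)[0, 1]) > 0.999:
                warnings.warn(
                    f"exposures {exposures[i].trait_id!r} and {exposures[j].trait_id!r} "
                    "are nearly collinear", stacklevel=2,
                )
    return MultiExposureSet(
        snp_ids=np.asarray(keep, dtype=str),
        exposure_ids=[t.trait_id for t in exposures],
        beta_matrix=beta_matrix,
        se_matrix=se_matrix,
        beta_out=mats_b[-1],
        se_out=mats_s[-1],
        sig_counts=np.asarray(sig_counts),
    )


def mvmr_fit(mset: MultiExposureSet, model_label: str = "") -> MVMRResult:
    """Weighted multivariable regression of outcome on exposure effects.

    No intercept; weights 1/se_out²; per-exposure SEs from the weighted fit
    with multiplicative overdispersion floored at 1; p-values from the t
    distribution with n − E df. Exposure columns that are identically zero
    are dropped (their direct effect is reported as NaN); rank deficiency
    among the remaining columns raises :class:`CollinearExposuresError`
    naming the collinear exposures.
    """
    X = mset.beta_matrix
    nonzero = ~np.all(X == 0.0, axis=0)
    if not nonzero.all():
        dropped = [mset.exposure_ids[i] for i in np.flatnonzero(~nonzero)]
        warnings.warn(f"exposure(s) with all-zero effects dropped from fit: {dropped}",
                      stacklevel=2)
    Xf = X[:, nonzero]
    if Xf.shape[1] == 0:
        raise CollinearExposuresError("all exposure columns are zero")
    w = 1.0 / mset.se_out**2
    Xw = Xf * np.sqrt(w)[:, None]
    rank = np.linalg.matrix_rank(Xw)
    if rank < Xf.shape[1]:
        names = [mset.exposure_ids[i] for i in np.flatnonzero(nonzero)]
        raise CollinearExposuresError(
            f"rank-deficient multivariable design among exposures {names}"
        )
    cond = float(np.linalg.cond(Xw))
    if cond > 1e6:
        warnings.warn(f"ill-conditioned multivariable design (condition number {cond:.3g})",
                      stacklevel=2)
    fit = sm.WLS(mset.beta_out, Xf, weights=w).fit()
    floor = min(1.0, float(np.sqrt(fit.scale)))
    if floor == 0.0:  # exact fit: keep the (zero) nominal SEs
        floor = 1.0
    df = len(mset.beta_out) - Xf.shape[1]
    results = []
    col = 0
    for i, exp_id in enumerate(mset.exposure_ids):
        if not nonzero[i]:
            results.append(ExposureDirectEffect(
                exp_id, float("nan"), float("nan"), float("nan"), float("nan"),
                float("nan"), float("nan"),
                int(mset.sig_counts[i]) if mset.sig_counts is not None else 0,
            ))
            continue
        beta = float(fit.params[col])
        se = float(fit.bse[col] / floor)
        or_, lo, hi = or_from_beta(beta, se)
        pval = float(2.0 * stats.t.sf(abs(beta) / se, df)) if se > 0 else 0.0
        results.append(ExposureDirectEffect(
            exp_id, beta, se, or_, lo, hi, pval,
            int(mset.sig_counts[i]) if mset.sig_counts is not None else 0,
        ))
        col += 1
    return MVMRResult(exposures=results, n_snp=mset.n_snp,
                      condition_number=cond, model_label=model_label)
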