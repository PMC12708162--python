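"""Synthetic GWAS summary statistics under a known causal diagram.

The generator emulates two-sample MR data: a set of candidate instrument SNPs
with per-allele effects on an exposure, optionally a mediator, and an outcome,
each "measured" in an independent GWAS panel so there is no sample overlap.

Generative model, per SNP j:

* minor-allele frequency  maf_j ~ Uniform(maf_range);
* SNP→exposure effect     γ_j = |N(0, snp_effect_sd²)| — every SNP is oriented
  so its effect allele is the exposure-increasing allele, the usual reporting
  convention for instrument lists; magnitudes are half-normal so
  E[γ²] = snp_effect_sd² is preserved;
* SNP→mediator effect     γ_j·β_XM + δ_j with δ_j ~ N(0, mediator_snp_effect_sd²):
  the mediator carries the exposure's signal *and* instruments of its own,
  without which a multivariable fit of {exposure, mediator} on the outcome
  would be unidentified;
* direct SNP→outcome (pleiotropic) effect α_j ~ N(pleiotropy_mean,
  pleiotropy_sd²) for a random invalid_fraction of SNPs, else 0;
* true SNP→outcome effect γ_j·β_XO + (γ_j·β_XM + δ_j)·β_MO + α_j
  (the mediator path is present only in :func:`simulate_mediation`);
* estimated effects are the true effects plus independent N(0, se²) noise with
  se = 1/sqrt(2·maf_j·(1−maf_j)·n_trait), the per-allele variance
  approximation for a standardized trait; p-values from the two-sided normal
  test of beta/se.

With invalid_fraction = 0 and pleiotropy_mean = 0 the data satisfy the three
instrumental-variable assumptions (association, independence, exclusion) by
construction, so every estimator should agree with the truth within sampling
error. A non-zero pleiotropy_mean plants *directional* pleiotropy; a non-zero
pleiotropy_sd with zero mean plants balanced heterogeneity.

SNPs are mutually independent (no LD) and placed > 10,000 kb apart, so
distance-based clumping is a pass-through; ``ld_block_size > 1`` instead packs
consecutive SNPs within 100 kb of each other to exercise the clumping path.
``outcome_snp_fraction > 0`` reserves SNPs with γ = 0 and a direct outcome
effect — the outcome's own instruments, needed for reverse-MR scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
from scipy import stats

from .io import TraitTable, trait_table_from_arrays

# non-palindromic allele pairs cycled across SNPs so harmonization never has
# to drop simulated variants as ambiguous
_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T")]


@dataclass
class SimConfig:
    """Parameters of the generative model (see module docstring for the model).

    Defaults describe a well-powered two-sample design: 100 independent SNPs,
    GWAS panels of 50,000, strong instruments (snp_effect_sd = 0.1 gives
    per-SNP F around 200 at these panel sizes while the instruments jointly
    explain well under 100% of the exposure variance), and all instruments
    valid. Effect sizes are on the log-odds scale for binary traits.
    """

    n_snps: int = 100
    n_exposure: int = 50_000
    n_outcome: int = 50_000
    n_mediator: int = 50_000
    true_beta_xo: float = 0.3
    true_beta_xm: float = 0.5
    true_beta_mo: float = 0.4
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.05
    invalid_fraction: float = 0.0
    maf_range: tuple[float, float] = (0.1, 0.5)
    snp_effect_sd: float = 0.1
    mediator_snp_effect_sd: float | None = None
    outcome_snp_fraction: float = 0.0
    ld_block_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.invalid_fraction <= 1.0:
            raise ValueError("invalid_fraction must be in [0, 1]")
        if not 0.0 <= self.outcome_snp_fraction <= 1.0:
            raise ValueError("outcome_snp_fraction must be in [0, 1]")
        for name in ("n_exposure", "n_outcome", "n_mediator"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be a non-degenerate interval within (0, 0.5]")
        if lo == hi:
            raise ValueError("maf_range collapsed to a point")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.snp_effect_sd <= 0:
            raise ValueError("snp_effect_sd must be > 0")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")

    @property
    def med_effect_sd(self) -> float:
        return self.snp_effect_sd if self.mediator_snp_effect_sd is None else self.mediator_snp_effect_sd


def _positions(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Chromosome/position layout: independent SNPs > 10,000 kb apart, or LD
    blocks of consecutive SNPs within 100 kb when ld_block_size > 1."""
    j = np.arange(config.n_snps)
    block = j // config.ld_block_size
    chrom = (block % 22) + 1
    base = 1_000_000 + (block // 22) * 20_000_000
    pos = base + (j % config.ld_block_size) * 50_000
    return chrom.astype(str), pos.astype(np.int64)


def _noisy(rng: np.random.Generator, true_beta: np.ndarray, maf: np.ndarray, n: int):
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)
    beta = true_beta + rng.normal(0.0, se)
    pval = 2.0 * stats.norm.sf(np.abs(beta) / se)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    return beta, se, pval


def _draw_shared(rng: np.random.Generator, config: SimConfig) -> dict[str, np.ndarray]:
    n = config.n_snps
    maf = rng.uniform(*config.maf_range, size=n)
    gamma = np.abs(rng.normal(0.0, config.snp_effect_sd, size=n))
    outcome_only = np.zeros(n, dtype=bool)
    n_out_snps = int(round(config.outcome_snp_fraction * n))
    if n_out_snps:
        outcome_only[rng.choice(n, size=n_out_snps, replace=False)] = True
        gamma[outcome_only] = 0.0
    eta = np.zeros(n)
    eta[outcome_only] = np.abs(rng.normal(0.0, config.snp_effect_sd, size=n_out_snps))
    invalid = np.zeros(n, dtype=bool)
    n_invalid = int(round(config.invalid_fraction * n))
    candidates = np.flatnonzero(~outcome_only)
    if n_invalid:
        n_invalid = min(n_invalid, candidates.size)
        invalid[rng.choice(candidates, size=n_invalid, replace=False)] = True
    alpha = np.zeros(n)
    alpha[invalid] = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=invalid.sum())
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    chrom, pos = _positions(config)
    snp_id = np.array([f"rs{j + 1}" for j in range(n)])
    return dict(maf=maf, gamma=gamma, eta=eta, invalid=invalid, alpha=alpha,
                ea=ea, oa=oa, chrom=chrom, pos=pos, snp_id=snp_id,
                outcome_only=outcome_only)


def _make_table(trait_id, shared, beta, se, pval, n):
    return trait_table_from_arrays(
        trait_id, shared["snp_id"], shared["chrom"], shared["pos"],
        shared["ea"], shared["oa"], shared["maf"], beta, se, pval,
        np.full(len(beta), n),
    )


def simulate_two_sample(config: SimConfig) -> tuple[TraitTable, TraitTable, dict[str, Any]]:
    """Exposure and outcome summary statistics under the two-sample design.

    Returns
    -------
    (exposure, outcome, truth)
        Trait tables plus a truth record holding every drawn per-SNP
        parameter (maf, gamma, alpha, invalid mask, true marginal effects)
        and the scalar ``true_beta_xo`` for oracle checks.
    """
    rng = np.random.default_rng(config.seed)
    shared = _draw_shared(rng, config)
    true_exp = shared["gamma"]
    true_out = shared["gamma"] * config.true_beta_xo + shared["alpha"] + shared["eta"]
    bx, sx, px = _noisy(rng, true_exp, shared["maf"], config.n_exposure)
    by, sy, py = _noisy(rng, true_out, shared["maf"], config.n_outcome)
    exposure = _make_table("sim-exposure", shared, bx, sx, px, config.n_exposure)
    outcome = _make_table("sim-outcome", shared, by, sy, py, config.n_outcome)
    truth = {
        "config": asdict(config),
        "true_beta_xo": config.true_beta_xo,
        "maf": shared["maf"], "gamma": shared["gamma"], "alpha": shared["alpha"],
        "invalid": shared["invalid"], "outcome_only": shared["outcome_only"],
        "true_beta_exposure": true_exp, "true_beta_outcome": true_out,
    }
    return exposure, outcome, truth


def simulate_mediation(config: SimConfig) -> tuple[TraitTable, TraitTable, TraitTable, dict[str, Any]]:
    """Exposure, mediator and outcome tables under the mediation diagram.

    The truth record carries the total effect β_XO + β_XM·β_MO, the direct
    effect β_XO and the indirect effect β_XM·β_MO alongside all per-SNP draws.
    """
    rng = np.random.default_rng(config.seed)
    shared = _draw_shared(rng, config)
    delta = rng.normal(0.0, config.med_effect_sd, size=config.n_snps)
    delta[shared["outcome_only"]] = 0.0
    true_exp = shared["gamma"]
    true_med = shared["gamma"] * config.true_beta_xm + delta
    true_out = (
        shared["gamma"] * config.true_beta_xo
        + true_med * config.true_beta_mo
        + shared["alpha"] + shared["eta"]
    )
    bx, sx, px = _noisy(rng, true_exp, shared["maf"], config.n_exposure)
    bm, sm, pm = _noisy(rng, true_med, shared["maf"], config.n_mediator)
    by, sy, py = _noisy(rng, true_out, shared["maf"], config.n_outcome)
    exposure = _make_table("sim-exposure", shared, bx, sx, px, config.n_exposure)
    mediator = _make_table("sim-mediator", shared, bm, sm, pm, config.n_mediator)
    outcome = _make_table("sim-outcome", shared, by, sy, py, config.n_outcome)
    truth = {
        "config": asdict(config),
        "true_total": config.true_beta_xo + config.true_beta_xm * config.true_beta_mo,
        "true_direct": config.true_beta_xo,
        "true_indirect": config.true_beta_xm * config.true_beta_mo,
        "true_beta_xm": config.true_beta_xm,
        "true_beta_mo": config.true_beta_mo,
        "maf": shared["maf"], "gamma": shared["gamma"], "delta": delta,
        "alpha": shared["alpha"], "invalid": shared["invalid"],
        "true_beta_exposure": true_exp, "true_beta_mediator": true_med,
        "true_beta_outcome": true_out,
    }
    return exposure, mediator, outcome, truth
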