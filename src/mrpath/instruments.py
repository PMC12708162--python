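"""Instrument selection, LD clumping, allele harmonization and strength tests.

Workflow: screen the exposure GWAS at genome-wide significance (p < 5e-8 by
default, 5e-6 for relaxed reverse-MR screens), prune correlated SNPs by
greedy p-value-priority clumping (r² < 0.001 within 10,000 kb), align the
outcome table to the exposure's effect alleles, then compute per-SNP F
statistics to flag weak instruments (F < 10).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import EmptyInstrumentSetError
from .io import TraitTable

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

GENOME_WIDE_P = 5e-8
RELAXED_P = 5e-6


@dataclass
class HarmonizedInstrumentSet:
    """Exposure and outcome effects aligned to a common effect allele per SNP.

    All arrays are parallel over SNPs. ``flipped`` marks SNPs whose outcome
    effect sign was inverted during alignment; ``eaf_exp`` is the exposure
    effect-allele frequency (used for MAF-based variance-explained formulas).
    """

    snp_ids: np.ndarray
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    eaf_exp: np.ndarray
    eaf_out: np.ndarray | None = None
    flipped: np.ndarray | None = None
    dropped: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        arrays = [self.snp_ids, self.beta_exp, self.se_exp, self.beta_out, self.se_out, self.eaf_exp]
        lengths = {len(a) for a in arrays}
        if len(lengths) != 1:
            raise ValueError("all instrument vectors must have equal length")
        if self.n_snp < 1:
            raise EmptyInstrumentSetError("harmonized instrument set is empty")
        if np.any(self.se_exp <= 0) or np.any(self.se_out <= 0):
            raise ValueError("all standard errors must be > 0")
        if self.flipped is None:
            self.flipped = np.zeros(self.n_snp, dtype=bool)

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    def subset(self, idx) -> "HarmonizedInstrumentSet":
        """Set restricted to positions ``idx`` (mask or integer index)."""
        idx = np.asarray(idx)
        return HarmonizedInstrumentSet(
            snp_ids=self.snp_ids[idx],
            beta_exp=self.beta_exp[idx], se_exp=self.se_exp[idx],
            beta_out=self.beta_out[idx], se_out=self.se_out[idx],
            eaf_exp=self.eaf_exp[idx],
            eaf_out=None if self.eaf_out is None else self.eaf_out[idx],
            flipped=self.flipped[idx],
        )


@dataclass
class InstrumentStrength:
    """Per-SNP instrument strength: variance explained and F statistics."""

    f_stats: np.ndarray
    r2: np.ndarray
    f_median: float
    f_min: float
    f_max: float
    weak: np.ndarray  # F < 10 flags

    @property
    def n_weak(self) -> int:
        return int(self.weak.sum())


def select_instruments(exposure: TraitTable, p_threshold: float = GENOME_WIDE_P) -> TraitTable:
    """Subset of SNPs with exposure p-value below the threshold, order preserved."""
    if exposure.n_snps == 0:
        raise ValueError("exposure table is empty")
    mask = exposure.data["pval"] < p_threshold
    if not mask.any():
        raise EmptyInstrumentSetError(
            f"no SNPs pass p < {p_threshold:g} in trait {exposure.trait_id}"
        )
    return exposure.subset(mask.to_numpy())


def load_ld_table(path: str | Path) -> dict[tuple[str, str], float]:
    """Pairwise r² lookup from a 3-column TSV (snp_a, snp_b, r2), symmetric."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_a": str, "snp_b": str})
    lookup: dict[tuple[str, str], float] = {}
    for a, b, r2 in df.itertuples(index=False):
        lookup[(a, b)] = float(r2)
        lookup[(b, a)] = float(r2)
    return lookup


def ld_clump(
    candidates: TraitTable,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
    ld: dict[tuple[str, str], float] | None = None,
) -> TraitTable:
    """Greedy p-value-priority clumping.

    SNPs are visited in ascending p-value order (ties broken by ascending se
    then snp_id for determinism). A SNP is retained iff, against every SNP
    already retained, it is on a different chromosome, or more than
    ``window_kb`` away, or — when a pairwise r² lookup is supplied — in low
    LD (r² < ``r2_threshold``). Without a lookup the rule degrades to
    distance-only pruning. Output preserves the input row order.
    """
    df = candidates.data.reset_index(drop=True)
    if df.empty:
        return candidates
    order = df.sort_values(["pval", "se", "snp_id"], kind="mergesort").index.to_numpy()
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()
    snp = df["snp_id"].to_numpy()
    window_bp = window_kb * 1_000
    kept: list[int] = []
    for i in order:
        ok = True
        for j in kept:
            if chrom[i] != chrom[j] or abs(pos[i] - pos[j]) > window_bp:
                continue
            if ld is not None and ld.get((snp[i], snp[j]), 0.0) < r2_threshold:
                continue
            ok = False
            break
        if ok:
            kept.append(i)
    mask = df.index.isin(kept)
    return candidates.subset(mask)


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT[ea] == oa


def harmonize(
    exposure: TraitTable,
    outcome: TraitTable,
    palindrome_eaf_window: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedInstrumentSet:
    """Align outcome effects to the exposure's effect allele per SNP.

    Inner join on snp_id. If the outcome's alleles are swapped relative to
    the exposure (directly or as reverse complements), the outcome beta's
    sign is flipped and its EAF replaced by 1 − EAF. Palindromic SNPs (A/T,
    C/G) cannot be aligned by allele letters: they are dropped when the
    exposure EAF falls inside ``palindrome_eaf_window`` (ambiguous strand),
    otherwise aligned by frequency. Unalignable allele pairs are dropped with
    a logged reason; the dropped rows are available on the result.
    """
    merged = exposure.data.merge(
        outcome.data, on="snp_id", suffixes=("_exp", "_out"), how="inner"
    )
    if merged.empty:
        raise EmptyInstrumentSetError(
            f"no shared SNPs between {exposure.trait_id} and {outcome.trait_id}"
        )

    keep_rows, drop_rows = [], []
    for row in merged.itertuples(index=False):
        ea_e, oa_e = row.effect_allele_exp, row.other_allele_exp
        ea_o, oa_o = row.effect_allele_out, row.other_allele_out
        beta_out, eaf_out, flip = row.beta_out, row.eaf_out, False
        if _is_palindromic(ea_e, oa_e):
            lo, hi = palindrome_eaf_window
            if {ea_o, oa_o} != {ea_e, oa_e}:
                drop_rows.append((row.snp_id, "allele mismatch"))
                continue
            if lo <= row.eaf_exp <= hi or lo <= eaf_out <= hi:
                drop_rows.append((row.snp_id, "ambiguous palindrome"))
                continue
            # align by frequency: effect alleles should be on the same side of 0.5
            if (row.eaf_exp < 0.5) != (eaf_out < 0.5):
                flip = True
        else:
            comp = (_COMPLEMENT[ea_o], _COMPLEMENT[oa_o])
            if (ea_o, oa_o) == (ea_e, oa_e) or comp == (ea_e, oa_e):
                pass
            elif (oa_o, ea_o) == (ea_e, oa_e) or (comp[1], comp[0]) == (ea_e, oa_e):
                flip = True
            else:
                drop_rows.append((row.snp_id, "allele mismatch"))
                continue
        if flip:
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out
        keep_rows.append(
            (row.snp_id, row.beta_exp, row.se_exp, beta_out, row.se_out,
             row.eaf_exp, eaf_out, flip)
        )

    if drop_rows:
        logger.warning("harmonize: dropped %d SNP(s): %s", len(drop_rows),
                       "; ".join(f"{s} ({why})" for s, why in drop_rows[:10]))
    if not keep_rows:
        raise EmptyInstrumentSetError("no SNPs survived harmonization")

    cols = list(zip(*keep_rows))
    return HarmonizedInstrumentSet(
        snp_ids=np.asarray(cols[0], dtype=str),
        beta_exp=np.asarray(cols[1], dtype=float),
        se_exp=np.asarray(cols[2], dtype=float),
        beta_out=np.asarray(cols[3], dtype=float),
        se_out=np.asarray(cols[4], dtype=float),
        eaf_exp=np.asarray(cols[5], dtype=float),
        eaf_out=np.asarray(cols[6], dtype=float),
        flipped=np.asarray(cols[7], dtype=bool),
        dropped=pd.DataFrame(drop_rows, columns=["snp_id", "reason"]),
    )


def variance_explained(eaf: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Per-SNP variance explained R² = 2·MAF·(1−MAF)·β², MAF = min(EAF, 1−EAF)."""
    eaf = np.asarray(eaf, dtype=float)
    maf = np.minimum(eaf, 1.0 - eaf)
    return 2.0 * maf * (1.0 - maf) * np.asarray(beta, dtype=float) ** 2


def instrument_strength(
    hset: HarmonizedInstrumentSet,
    n: int,
    k: int = 1,
    overall: bool = False,
) -> InstrumentStrength:
    """Per-SNP F statistics: F = ((N − k − 1)/k) · R²/(1 − R²).

    With ``k = 1`` (default) each SNP is tested on its own, which is the shape
    of per-instrument F summaries (median/min/max). ``overall=True`` instead
    sums R² over instruments and uses k = n_snp, returning the single joint F
    replicated across SNPs.

    Raises
    ------
    ValueError
        If any R² ≥ 1 (malformed input) or n ≤ k + 1.
    """
    if n <= k + 1:
        raise ValueError("sample size must exceed k + 1")
    r2 = variance_explained(hset.eaf_exp, hset.beta_exp)
    if overall:
        k = hset.n_snp
        if n <= k + 1:
            raise ValueError("sample size must exceed n_snp + 1 for the overall F")
        total = float(r2.sum())
        if total >= 1.0:
            raise ValueError("summed R² >= 1: malformed input")
        f = np.full(hset.n_snp, (n - k - 1) / k * total / (1.0 - total))
    else:
        if np.any(r2 >= 1.0):
            raise ValueError("per-SNP R² >= 1: malformed input")
        f = (n - k - 1) / k * r2 / (1.0 - r2)
    return InstrumentStrength(
        f_stats=f, r2=r2,
        f_median=float(np.median(f)), f_min=float(f.min()), f_max=float(f.max()),
        weak=f < 10.0,
    )
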