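"""Reading, validating and writing GWAS summary-statistic tables.

The canonical on-disk dialect is a flat TSV with one row per SNP and header

    snp_id  chrom  pos  effect_allele  other_allele  eaf  beta  se  pval  n

matching the shape of pre-packaged OpenGWAS-style extracts. Comma-separated
files are accepted on read (delimiter sniffed). A ``column_map`` hook renames
non-standard headers onto this schema. Rows violating the per-record
invariants (non-ACGT or identical alleles, se ≤ 0, eaf outside [0, 1],
p outside (0, 1], non-positive n) are dropped with a logged count; indels and
multi-allelic sites are therefore rejected. Positions are 1-based.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError

logger = logging.getLogger(__name__)

#: Canonical column order of the flat summary-statistic dialect.
COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

_NUCLEOTIDES = {"A", "C", "G", "T"}


@dataclass
class TraitTable:
    """One trait's GWAS summary statistics.

    Parameters
    ----------
    trait_id : str
        Identifier for the GWAS (e.g. an accession such as ``"ukb-b-7350"``).
    data : pandas.DataFrame
        One validated row per SNP, columns as in :data:`COLUMNS`.
    trait_type : str
        ``"binary"`` (betas are log-odds) or ``"continuous"``.
    """

    trait_id: str
    data: pd.DataFrame = field(repr=False)
    trait_type: str = "binary"

    def __post_init__(self) -> None:
        if not self.trait_id:
            raise ValueError("trait_id must be non-empty")
        if self.trait_type not in ("binary", "continuous"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"trait table missing column(s): {', '.join(missing)}")
        if self.data["snp_id"].duplicated().any():
            dupes = self.data.loc[self.data["snp_id"].duplicated(), "snp_id"]
            raise ValueError(f"duplicate snp_id in trait {self.trait_id}: {sorted(set(dupes))[:5]}")

    @property
    def n_snps(self) -> int:
        return len(self.data)

    def subset(self, mask) -> "TraitTable":
        """New table with the rows selected by a boolean mask or index, order preserved."""
        return TraitTable(self.trait_id, self.data.loc[mask].reset_index(drop=True), self.trait_type)


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Return (valid rows, number dropped). Alleles are uppercased first."""
    df = df.copy()
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    numeric = ["pos", "eaf", "beta", "se", "pval", "n"]
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")

    ok = (
        df["effect_allele"].isin(_NUCLEOTIDES)
        & df["other_allele"].isin(_NUCLEOTIDES)
        & (df["effect_allele"] != df["other_allele"])
        & df[numeric].notna().all(axis=1)
        & (df["se"] > 0)
        & df["eaf"].between(0.0, 1.0)
        & (df["pval"] > 0.0) & (df["pval"] <= 1.0)
        & (df["n"] >= 1)
        & (df["pos"] >= 1)
    )
    # duplicate IDs: keep first occurrence, drop the rest
    ok &= ~df["snp_id"].duplicated()
    clean = df.loc[ok].reset_index(drop=True)
    clean["pos"] = clean["pos"].astype(np.int64)
    clean["n"] = clean["n"].astype(np.int64)
    return clean, int((~ok).sum())


def read_summary_stats(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    trait_id: str | None = None,
    trait_type: str = "binary",
) -> TraitTable:
    """Read a summary-statistic table from a TSV/CSV file.

    Parameters
    ----------
    path : path-like
        File with a header row; tab- or comma-separated (sniffed).
    column_map : dict, optional
        Mapping from the file's header names to canonical names, e.g.
        ``{"rsid": "snp_id", "freq": "eaf"}``.
    trait_id : str, optional
        Defaults to the file stem.
    trait_type : str
        ``"binary"`` or ``"continuous"``.

    Raises
    ------
    SchemaError
        If a mandatory column is absent after applying ``column_map``.
    ValueError
        If no valid rows remain after filtering.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    if not sample.strip():
        raise ValueError(f"{path}: file is empty")
    try:
        sep = csv.Sniffer().sniff(sample.splitlines()[0], delimiters="\t,").delimiter
    except csv.Error:
        sep = "\t"
    df = pd.read_csv(path, sep=sep, dtype={"chrom": str})
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    df = df[COLUMNS]
    clean, dropped = _validate_rows(df)
    if dropped:
        logger.warning("%s: dropped %d row(s) violating record invariants", path, dropped)
    if clean.empty:
        raise ValueError(f"{path}: no valid rows after filtering")
    return TraitTable(trait_id or path.stem, clean, trait_type)


def write_summary_stats(table: TraitTable, path: str | Path) -> None:
    """Write a trait table as canonical TSV.

    Floats are written with 12 significant digits so write∘read round-trips
    preserve values well past test tolerance.
    """
    if table.n_snps == 0:
        raise ValueError("refusing to write an empty trait table")
    path = Path(path)
    table.data[COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.12g")


def trait_table_from_arrays(
    trait_id: str,
    snp_id,
    chrom,
    pos,
    effect_allele,
    other_allele,
    eaf,
    beta,
    se,
    pval,
    n,
    trait_type: str = "binary",
) -> TraitTable:
    """Assemble a :class:`TraitTable` from parallel arrays (used by the simulator)."""
    df = pd.DataFrame(
        {
            "snp_id": np.asarray(snp_id, dtype=str),
            "chrom": np.asarray(chrom, dtype=str),
            "pos": np.asarray(pos, dtype=np.int64),
            "effect_allele": effect_allele,
            "other_allele": other_allele,
            "eaf": np.asarray(eaf, dtype=float),
            "beta": np.asarray(beta, dtype=float),
            "se": np.asarray(se, dtype=float),
            "pval": np.asarray(pval, dtype=float),
            "n": np.asarray(n, dtype=np.int64),
        }
    )
    return TraitTable(trait_id, df, trait_type)
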