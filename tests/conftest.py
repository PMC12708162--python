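"""Shared builders for small hand-constructed fixtures."""

import numpy as np
import pandas as pd
import pytest

from mrpath.instruments import HarmonizedInstrumentSet
from mrpath.io import TraitTable


def make_trait(
    trait_id="trait",
    snp_ids=("rs1", "rs2", "rs3"),
    chrom=None,
    pos=None,
    ea="A",
    oa="C",
    eaf=0.3,
    beta=0.1,
    se=0.01,
    pval=1e-9,
    n=10_000,
):
    """TraitTable from scalars-or-sequences, broadcasting scalars."""
    k = len(snp_ids)

    def arr(x, dtype=float):
        x = np.asarray(x)
        return np.full(k, x, dtype=dtype) if x.ndim == 0 else x.astype(dtype)

    df = pd.DataFrame(
        {
            "snp_id": list(snp_ids),
            "chrom": arr(chrom if chrom is not None else "1", dtype=object),
            "pos": arr(pos if pos is not None else np.arange(1, k + 1) * 50_000_000, dtype=np.int64),
            "effect_allele": arr(ea, dtype=object),
            "other_allele": arr(oa, dtype=object),
            "eaf": arr(eaf),
            "beta": arr(beta),
            "se": arr(se),
            "pval": arr(pval),
            "n": arr(n, dtype=np.int64),
        }
    )
    return TraitTable(trait_id, df)


def make_hset(bx, sx, by, sy, eaf=0.3, snp_ids=None):
    bx = np.asarray(bx, dtype=float)
    k = len(bx)

    def arr(x):
        x = np.asarray(x, dtype=float)
        return np.full(k, x) if x.ndim == 0 else x

    return HarmonizedInstrumentSet(
        snp_ids=np.asarray(snp_ids if snp_ids is not None else [f"rs{i}" for i in range(k)]),
        beta_exp=bx, se_exp=arr(sx), beta_out=arr(by), se_out=arr(sy),
        eaf_exp=arr(eaf),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)
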