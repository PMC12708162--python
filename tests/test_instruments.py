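import numpy as np
import pytest

from mrpath import (
    EmptyInstrumentSetError,
    harmonize,
    instrument_strength,
    ld_clump,
    select_instruments,
)
from mrpath.simulate import SimConfig, simulate_two_sample

from conftest import make_hset, make_trait


class TestSelect:
    def test_threshold_counting(self):
        t = make_trait(snp_ids=("a", "b", "c"), pval=np.array([1e-9, 1e-7, 1e-3]))
        assert select_instruments(t, 5e-8).n_snps == 1

    def test_threshold_one_keeps_everything(self):
        t = make_trait(snp_ids=("a", "b", "c"), pval=np.array([0.9, 0.5, 0.1]))
        out = select_instruments(t, 1.0)
        assert list(out.data["snp_id"]) == ["a", "b", "c"]  # order preserved

    def test_zero_survivors_is_typed_signal(self):
        t = make_trait(pval=0.5)
        with pytest.raises(EmptyInstrumentSetError):
            select_instruments(t, 5e-8)

    def test_matches_brute_force_on_synthetic_data(self):
        exposure, _, _ = simulate_two_sample(
            SimConfig(n_snps=200, snp_effect_sd=0.05, seed=13))
        got = select_instruments(exposure, 5e-8).n_snps
        expected = int((exposure.data["pval"] < 5e-8).sum())
        assert got == expected > 0


class TestClump:
    def test_within_window_keeps_lower_p(self):
        t = make_trait(snp_ids=("a", "b"), chrom=["1", "1"],
                       pos=[1_000_000, 6_000_000],  # 5,000 kb apart
                       pval=np.array([1e-10, 1e-9]))
        out = ld_clump(t)
        assert list(out.data["snp_id"]) == ["a"]

    def test_different_chromosomes_both_kept(self):
        t = make_trait(snp_ids=("a", "b"), chrom=["1", "2"],
                       pos=[1_000_000, 1_000_000], pval=np.array([1e-10, 1e-9]))
        assert ld_clump(t).n_snps == 2

    def test_ld_lookup_rescues_within_window_pair(self):
        t = make_trait(snp_ids=("a", "b"), chrom=["1", "1"],
                       pos=[1_000_000, 6_000_000], pval=np.array([1e-10, 1e-9]))
        ld = {("a", "b"): 0.0005, ("b", "a"): 0.0005}
        assert ld_clump(t, ld=ld).n_snps == 2
        ld = {("a", "b"): 0.8, ("b", "a"): 0.8}
        assert ld_clump(t, ld=ld).n_snps == 1

    def test_matches_exhaustive_greedy_reference(self, rng):
        # independent reference implementation of greedy p-priority pruning
        k = 20
        t = make_trait(
            snp_ids=tuple(f"s{i}" for i in range(k)),
            chrom=rng.choice(["1", "2", "3"], size=k).tolist(),
            pos=rng.integers(1, 40_000_000, size=k),
            pval=rng.uniform(1e-12, 1e-6, size=k),
            se=rng.uniform(0.01, 0.02, size=k),
        )
        df = t.data
        order = sorted(range(k), key=lambda i: (df["pval"][i], df["se"][i], df["snp_id"][i]))
        kept = []
        for i in order:
            if all(df["chrom"][i] != df["chrom"][j]
                   or abs(df["pos"][i] - df["pos"][j]) > 10_000 * 1_000
                   for j in kept):
                kept.append(i)
        expected = df.iloc[sorted(kept)]["snp_id"].tolist()
        assert list(ld_clump(t).data["snp_id"]) == expected

    def test_output_is_subset_in_original_order(self, rng):
        k = 30
        t = make_trait(
            snp_ids=tuple(f"s{i}" for i in range(k)),
            chrom=rng.choice(["1", "2"], size=k).tolist(),
            pos=rng.integers(1, 30_000_000, size=k),
            pval=rng.uniform(0, 1e-6, size=k),
        )
        out = ld_clump(t)
        ids = list(t.data["snp_id"])
        out_ids = list(out.data["snp_id"])
        assert out_ids == [s for s in ids if s in set(out_ids)]


class TestHarmonize:
    def test_identical_coding_is_identity(self):
        e = make_trait(snp_ids=("a", "b"), beta=np.array([0.1, 0.2]))
        o = make_trait(snp_ids=("a", "b"), beta=np.array([0.5, -0.5]))
        h = harmonize(e, o)
        np.testing.assert_allclose(h.beta_out, [0.5, -0.5])
        assert not h.flipped.any()

    def test_swapped_alleles_flip_sign(self):
        e = make_trait(snp_ids=("a",), ea="A", oa="C", eaf=0.3)
        o = make_trait(snp_ids=("a",), ea="C", oa="A", beta=0.2, eaf=0.7)
        h = harmonize(e, o)
        assert h.beta_out[0] == pytest.approx(-0.2)
        assert h.eaf_out[0] == pytest.approx(0.3)
        assert h.flipped[0]

    def test_reverse_complement_alignment(self):
        e = make_trait(snp_ids=("a",), ea="A", oa="C", beta=0.1)
        o = make_trait(snp_ids=("a",), ea="T", oa="G", beta=0.4)  # same strand flip
        h = harmonize(e, o)
        assert h.beta_out[0] == pytest.approx(0.4)
        assert not h.flipped[0]

    def test_ambiguous_palindrome_dropped(self):
        e = make_trait(snp_ids=("pal", "ok"), ea=["A", "A"], oa=["T", "C"],
                       eaf=np.array([0.5, 0.3]))
        o = make_trait(snp_ids=("pal", "ok"), ea=["A", "A"], oa=["T", "C"],
                       eaf=np.array([0.5, 0.3]))
        h = harmonize(e, o)
        assert list(h.snp_ids) == ["ok"]
        assert list(h.dropped["snp_id"]) == ["pal"]

    def test_informative_palindrome_aligned_by_frequency(self):
        e = make_trait(snp_ids=("pal",), ea="A", oa="T", eaf=0.1, beta=0.3)
        o = make_trait(snp_ids=("pal",), ea="A", oa="T", eaf=0.9, beta=0.2)
        h = harmonize(e, o)  # frequencies disagree on strand: flip
        assert h.beta_out[0] == pytest.approx(-0.2)

    def test_no_overlap_is_typed_signal(self):
        e = make_trait(snp_ids=("a",))
        o = make_trait(snp_ids=("b",))
        with pytest.raises(EmptyInstrumentSetError):
            harmonize(e, o)

    def test_involution_harmonizing_twice_changes_nothing(self):
        exposure, outcome, _ = simulate_two_sample(SimConfig(n_snps=20, seed=5))
        h1 = harmonize(exposure, outcome)
        # rebuild the outcome in the exposure's coding and harmonize again
        realigned = outcome.data.copy()
        realigned["beta"] = h1.beta_out
        realigned["eaf"] = h1.eaf_out
        realigned["effect_allele"] = exposure.data["effect_allele"]
        realigned["other_allele"] = exposure.data["other_allele"]
        h2 = harmonize(exposure, outcome.__class__(outcome.trait_id, realigned))
        np.testing.assert_allclose(h2.beta_out, h1.beta_out)
        assert not h2.flipped.any()


class TestStrength:
    def test_direct_arithmetic(self):
        # MAF 0.5, beta 1, N 1000: R2 = 0.5, F = 998 * (0.5/0.5) = 998
        h = make_hset(bx=[1.0], sx=0.1, by=0.0, sy=0.1, eaf=0.5)
        s = instrument_strength(h, n=1000)
        assert s.r2[0] == pytest.approx(0.5)
        assert s.f_stats[0] == pytest.approx(998.0)

    def test_null_effect_gives_zero(self):
        h = make_hset(bx=[0.0], sx=0.1, by=0.0, sy=0.1, eaf=0.2)
        s = instrument_strength(h, n=1000)
        assert s.r2[0] == 0.0 and s.f_stats[0] == 0.0

    def test_f_monotone_in_r2_over_grid(self):
        betas = np.linspace(0.01, 0.9, 25)
        h = make_hset(bx=betas, sx=0.1, by=0.0, sy=0.1, eaf=0.25)
        s = instrument_strength(h, n=5000)
        assert np.all(np.diff(s.r2) > 0)
        assert np.all(np.diff(s.f_stats) > 0)
        assert np.all(s.f_stats >= 0)

    def test_weak_flag_count_matches_brute_force(self):
        exposure, outcome, _ = simulate_two_sample(
            SimConfig(n_snps=80, snp_effect_sd=0.02, seed=2))
        h = harmonize(exposure, outcome)
        s = instrument_strength(h, n=50_000)
        assert s.n_weak == int((s.f_stats < 10).sum())
        assert s.f_median == pytest.approx(np.median(s.f_stats))
        assert (s.f_min, s.f_max) == (s.f_stats.min(), s.f_stats.max())

    def test_r2_at_least_one_is_hard_error(self):
        h = make_hset(bx=[2.0], sx=0.1, by=0.0, sy=0.1, eaf=0.5)  # R2 = 2
        with pytest.raises(ValueError):
            instrument_strength(h, n=1000)

    def test_overall_variant_uses_joint_r2(self):
        h = make_hset(bx=[0.1, 0.1, 0.1], sx=0.1, by=0.0, sy=0.1, eaf=0.5)
        per = instrument_strength(h, n=10_000)
        joint = instrument_strength(h, n=10_000, overall=True)
        r2_tot = per.r2.sum()
        expected = (10_000 - 3 - 1) / 3 * r2_tot / (1 - r2_tot)
        assert joint.f_stats[0] == pytest.approx(expected)
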