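import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from mrpath import (
    IndeterminateDirectionError,
    InsufficientInstrumentsError,
    SimConfig,
    harmonize,
    ivw,
    mode_estimate,
    mr_egger,
    or_from_beta,
    select_instruments,
    simulate_two_sample,
    steiger_test,
    wald_ratio,
    weighted_median,
)

from conftest import make_hset


def sim_hset(seed, **kw):
    """Screened-and-harmonized instrument set, as the pipeline would build it.

    Screening at genome-wide significance matters for the regression-based
    estimators: it guarantees the exposure-effect signs are measured without
    error, which the Egger orientation step relies on.
    """
    cfg = SimConfig(seed=seed, **kw)
    e, o, truth = simulate_two_sample(cfg)
    return harmonize(select_instruments(e), o), truth


class TestWaldRatio:
    def test_direct_arithmetic(self):
        est = wald_ratio(bx=0.3, sx=0.05, by=0.6, sy=0.1)
        assert est.beta == pytest.approx(2.0)
        assert est.se == pytest.approx(0.1 / 0.3)

    def test_null_numerator(self):
        assert wald_ratio(0.3, 0.05, 0.0, 0.1).beta == 0.0

    def test_zero_denominator_is_hard_error(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.05, 0.6, 0.1)

    @settings(derandomize=True, max_examples=50)
    @given(
        bx=st.floats(0.01, 10), by=st.floats(-10, 10),
        sx=st.floats(0.001, 1), sy=st.floats(0.001, 1),
        c=st.floats(0.01, 100),
    )
    def test_scale_invariance(self, bx, by, sx, sy, c):
        a = wald_ratio(bx, sx, by, sy)
        b = wald_ratio(c * bx, c * sx, c * by, c * sy)
        assert b.beta == pytest.approx(a.beta, rel=1e-9)
        assert b.se == pytest.approx(a.se, rel=1e-9)


class TestIVW:
    def test_single_snp_reduces_to_wald(self):
        h = make_hset(bx=[0.3], sx=0.05, by=0.6, sy=0.1)
        est = ivw(h)
        wald = wald_ratio(0.3, 0.05, 0.6, 0.1)
        assert est.beta == pytest.approx(wald.beta)
        assert est.se == pytest.approx(wald.se)

    def test_consensus_ratio_is_recovered_exactly(self, rng):
        bx = rng.uniform(0.1, 0.5, size=10)
        h = make_hset(bx=bx, sx=0.01, by=1.7 * bx, sy=rng.uniform(0.05, 0.2, size=10))
        assert ivw(h).beta == pytest.approx(1.7, rel=1e-12)

    def test_equals_weighted_least_squares_oracle(self, rng):
        for _ in range(5):
            k = 40
            bx = rng.normal(0.2, 0.1, size=k)
            bx[bx == 0] = 0.1
            by = rng.normal(0.3 * bx, 0.05)
            sy = rng.uniform(0.02, 0.1, size=k)
            h = make_hset(bx=bx, sx=0.01, by=by, sy=sy)
            fit = sm.WLS(by, bx[:, None], weights=1.0 / sy**2).fit()
            est = ivw(h, "fixed")
            assert est.beta == pytest.approx(float(fit.params[0]), abs=1e-10)
            # fixed-effect se is the WLS se with dispersion forced to 1
            assert est.se == pytest.approx(float(fit.bse[0] / np.sqrt(fit.scale)), abs=1e-10)

    def test_random_effects_never_tighter_than_fixed(self, rng):
        h = make_hset(bx=rng.uniform(0.1, 0.3, 20), sx=0.01,
                      by=rng.normal(0.0, 0.5, 20), sy=0.05)
        assert ivw(h, "random").se >= ivw(h, "fixed").se

    def test_snp_order_invariance(self, rng):
        h, _ = sim_hset(seed=21, n_snps=30)
        perm = rng.permutation(h.n_snp)
        assert ivw(h.subset(perm)).beta == pytest.approx(ivw(h).beta, rel=1e-12)


class TestEgger:
    def test_exact_collinear_fit(self):
        bx = np.array([1.0, 2.0, 3.0])
        h = make_hset(bx=bx, sx=0.01, by=0.1 + 0.5 * bx, sy=1.0)
        est = mr_egger(h)
        assert est.beta == pytest.approx(0.5, abs=1e-10)
        assert est.intercept == pytest.approx(0.1, abs=1e-10)

    def test_refuses_below_three_instruments(self):
        h = make_hset(bx=[0.1, 0.2], sx=0.01, by=0.05, sy=0.05)
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(h)

    def test_orientation_makes_fit_sign_convention_free(self):
        """Flipping any SNP's allele coding must not change the Egger fit."""
        h, _ = sim_hset(seed=8, n_snps=30)
        flipped = h.subset(np.arange(h.n_snp))
        flipped.beta_exp = flipped.beta_exp.copy()
        flipped.beta_out = flipped.beta_out.copy()
        flipped.beta_exp[::2] *= -1
        flipped.beta_out[::2] *= -1
        a, b = mr_egger(h), mr_egger(flipped)
        assert b.beta == pytest.approx(a.beta, rel=1e-12)
        assert b.intercept == pytest.approx(a.intercept, rel=1e-12)

    def test_directional_pleiotropy_intercept_recovery(self):
        """Replicate-mean intercept within 3 MC SEs of the planted mean."""
        ints = []
        for seed in range(60):
            h, _ = sim_hset(seed=seed, n_snps=300, true_beta_xo=0.1,
                            snp_effect_sd=0.2, invalid_fraction=1.0,
                            pleiotropy_mean=0.05, pleiotropy_sd=0.05)
            ints.append(mr_egger(h).intercept)
        ints = np.asarray(ints)
        mc_se = ints.std(ddof=1) / np.sqrt(len(ints))
        assert abs(ints.mean() - 0.05) < 3 * mc_se


class TestWeightedMedian:
    def test_hand_computed_cdf_interpolation(self):
        h = make_hset(bx=[1.0, 1.0, 1.0], sx=1e-9, by=[1.0, 2.0, 9.0], sy=1.0)
        est = weighted_median(h, n_boot=200, seed=1)
        assert est.beta == pytest.approx(2.0, abs=1e-6)

    def test_consensus_gives_tiny_bootstrap_se(self):
        bx = np.array([0.2, 0.25, 0.3, 0.4])
        h = make_hset(bx=bx, sx=1e-6, by=1.5 * bx, sy=0.001)
        est = weighted_median(h, n_boot=300, seed=2)
        assert est.beta == pytest.approx(1.5, abs=1e-3)
        assert est.se < 0.05

    def test_matches_brute_force_weighted_cdf_oracle(self, rng):
        for _ in range(10):
            k = 15
            bx = rng.uniform(0.05, 0.4, size=k)
            sx = rng.uniform(0.005, 0.02, size=k)
            by = rng.normal(0.2 * bx, 0.05)
            sy = rng.uniform(0.02, 0.1, size=k)
            h = make_hset(bx=bx, sx=sx, by=by, sy=sy)
            ratios = by / bx
            w = 1.0 / (sy**2 / bx**2 + by**2 * sx**2 / bx**4)
            order = np.argsort(ratios)
            r, ww = ratios[order], w[order]
            cdf = (np.cumsum(ww) - 0.5 * ww) / ww.sum()
            # brute-force piecewise-linear inversion at 1/2
            i = np.searchsorted(cdf, 0.5)
            if i == 0:
                expected = r[0]
            else:
                f = (0.5 - cdf[i - 1]) / (cdf[i] - cdf[i - 1])
                expected = r[i - 1] + f * (r[i] - r[i - 1])
            assert weighted_median(h, n_boot=0).beta == pytest.approx(expected, rel=1e-12)

    def test_snp_order_invariance(self, rng):
        h, _ = sim_hset(seed=30, n_snps=25)
        perm = rng.permutation(h.n_snp)
        assert weighted_median(h.subset(perm), n_boot=0).beta == pytest.approx(
            weighted_median(h, n_boot=0).beta, rel=1e-12)


class TestModeEstimators:
    def test_majority_cluster_wins(self):
        h = make_hset(bx=[1.0, 1.0, 1.0, 1.0], sx=1e-9,
                      by=[2.0, 2.0, 2.0, 7.0], sy=0.5)
        est = mode_estimate(h, weighted=False, n_boot=0)
        assert abs(est.beta - 2.0) < 0.6

    def test_weighting_pulls_mode_to_high_precision_snp(self):
        by = np.array([0.9, 0.95, 1.0, 1.05, 1.1, 5.0])
        sy = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 0.01])
        h = make_hset(bx=np.ones(6), sx=1e-9, by=by, sy=sy)
        simple = mode_estimate(h, weighted=False, n_boot=0).beta
        weighted = mode_estimate(h, weighted=True, n_boot=0).beta
        assert simple < 2.0
        assert weighted > 4.5

    def test_refuses_below_three_instruments(self):
        h = make_hset(bx=[0.1, 0.2], sx=0.01, by=0.05, sy=0.05)
        with pytest.raises(InsufficientInstrumentsError):
            mode_estimate(h)

    def test_bootstrap_is_seed_reproducible(self):
        h, _ = sim_hset(seed=4, n_snps=20)
        a = mode_estimate(h, n_boot=50, seed=9)
        b = mode_estimate(h, n_boot=50, seed=9)
        assert a.se == b.se


class TestSteiger:
    def test_forward_causal_direction_true(self):
        h, _ = sim_hset(seed=17, n_snps=50, true_beta_xo=0.3, snp_effect_sd=0.08)
        res = steiger_test(h, 50_000, 50_000)
        assert res.correct_direction
        assert res.r2_exposure > res.r2_outcome
        assert 0 <= res.r2_exposure < 1 and 0 <= res.r2_outcome < 1
        assert res.pval < 0.05

    def test_swapping_roles_inverts_direction(self):
        h, _ = sim_hset(seed=17, n_snps=50, true_beta_xo=0.3, snp_effect_sd=0.08)
        swapped = make_hset(bx=h.beta_out, sx=h.se_out, by=h.beta_exp,
                            sy=h.se_exp, eaf=h.eaf_exp)
        res = steiger_test(swapped, 50_000, 50_000)
        assert not res.correct_direction

    def test_exact_tie_is_false_with_p_one(self):
        h = make_hset(bx=[0.1, 0.2], sx=0.01, by=[0.1, 0.2], sy=0.01, eaf=0.3)
        res = steiger_test(h, 10_000, 10_000)
        assert not res.correct_direction
        assert res.pval == pytest.approx(1.0)

    def test_degenerate_zero_r2_signalled(self):
        h = make_hset(bx=[0.0], sx=0.01, by=[0.0], sy=0.01)
        with pytest.raises(IndeterminateDirectionError):
            steiger_test(h, 1000, 1000)


class TestORConversion:
    def test_published_total_effect_converts(self):
        or_, _, _ = or_from_beta(-8.14587, 3.969)
        assert round(or_, 5) == 0.00029

    def test_null_beta(self):
        or_, lo, hi = or_from_beta(0.0, 0.0)
        assert (or_, lo, hi) == (1.0, 1.0, 1.0)

    def test_log_two(self):
        assert or_from_beta(np.log(2), 0.0)[0] == pytest.approx(2.0)

    def test_ci_brackets_or(self, rng):
        for _ in range(20):
            b, s = rng.normal(0, 2), rng.uniform(0, 1)
            or_, lo, hi = or_from_beta(b, s)
            assert lo <= or_ <= hi
            assert or_ == pytest.approx(np.exp(b), rel=1e-12)
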