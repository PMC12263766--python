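"""From-scratch MR estimators against closed forms and independent WLS oracles."""

import numpy as np
import pytest
import statsmodels.api as sm

from ketomr.estimators import (
    cochran_q,
    egger_estimate,
    ivw_estimate,
    ratio_estimate,
    weighted_median_estimate,
)
from ketomr.harmonization import HarmonizedInstrumentSet, HarmonizedPair


def make_set(gamma, Gamma, se_out, se_exp=None):
    gamma = np.asarray(gamma, float)
    if se_exp is None:
        se_exp = np.full_like(gamma, 0.01)
    return HarmonizedInstrumentSet.from_arrays(gamma, se_exp, Gamma, se_out)


def single_pair(gamma, Gamma, se_out, se_exp=0.01):
    return HarmonizedPair(
        variant_id="rs1", chrom="1", pos=1, effect_allele="A", other_allele="G",
        exposure_beta=gamma, exposure_se=se_exp,
        outcome_beta=Gamma, outcome_se=se_out,
    )


class TestRatio:
    @pytest.mark.parametrize(
        "gamma, Gamma, se_out, beta, se",
        [
            (0.1, 0.2, 0.05, 2.0, 0.5),
            (0.1, 0.0, 0.05, 0.0, 0.5),
            (-0.1, 0.2, 0.05, -2.0, 0.5),
        ],
    )
    def test_closed_form(self, gamma, Gamma, se_out, beta, se):
        e = ratio_estimate(single_pair(gamma, Gamma, se_out))
        assert e.beta == pytest.approx(beta)
        assert e.se == pytest.approx(se)

    def test_null_outcome_gives_p_one(self):
        assert ratio_estimate(single_pair(0.1, 0.0, 0.05)).pval == pytest.approx(1.0)

    def test_zero_exposure_beta_is_domain_error(self):
        with pytest.raises(ValueError):
            ratio_estimate(single_pair(0.0, 0.1, 0.05))


class TestIVW:
    def test_two_variant_closed_form(self):
        # w = (4, 16), theta = (0.5, 0.5)
        e = ivw_estimate(make_set([0.1, 0.2], [0.05, 0.10], [0.05, 0.05]))
        assert e.beta == pytest.approx(0.5)
        assert e.se == pytest.approx(1 / np.sqrt(20))  # Q=0 so MRE == fixed
        assert e.q_stat == pytest.approx(0.0, abs=1e-12)

    def test_single_pair_reduces_to_ratio(self):
        hset = make_set([0.1], [0.2], [0.05])
        e = ivw_estimate(hset)
        r = ratio_estimate(hset.pairs[0])
        assert e.beta == pytest.approx(r.beta) and e.se == pytest.approx(r.se)

    def test_all_null_outcomes_give_zero(self):
        e = ivw_estimate(make_set([0.1, 0.2, 0.3], [0, 0, 0], [0.05] * 3))
        assert e.beta == 0.0

    def test_empty_set_is_usage_error(self):
        with pytest.raises(ValueError):
            ivw_estimate(
                HarmonizedInstrumentSet("x", "y", [])
            )

    def test_matches_wls_through_origin_oracle(self, rng):
        """IVW equals statsmodels WLS of Gamma on gamma without intercept."""
        for _ in range(100):
            J = int(rng.integers(2, 30))
            g = rng.normal(0, 0.1, J)
            G = rng.normal(0, 0.1, J)
            s = rng.uniform(0.01, 0.2, J)
            e = ivw_estimate(make_set(g, G, s), model="ivw_fixed")
            fit = sm.WLS(G, g[:, None], weights=1 / s**2).fit()
            assert e.beta == pytest.approx(fit.params[0], abs=1e-10)
            # fixed-effect se corresponds to the WLS se with scale forced to 1
            se_fixed = float(np.sqrt(fit.cov_params(scale=1.0)[0, 0]))
            assert e.se == pytest.approx(se_fixed, abs=1e-10)

    def test_mre_floors_at_fixed_se(self, rng):
        g = rng.normal(0, 0.1, 10)
        s = rng.uniform(0.01, 0.1, 10)
        G = 0.2 * g  # exact proportionality: Q = 0, no inflation
        fixed = ivw_estimate(make_set(g, G, s), model="ivw_fixed")
        mre = ivw_estimate(make_set(g, G, s), model="ivw_mre")
        assert mre.se == pytest.approx(fixed.se)

    def test_point_estimate_invariant_to_se_scaling(self, rng):
        g = rng.normal(0, 0.1, 8)
        G = rng.normal(0, 0.1, 8)
        s = rng.uniform(0.01, 0.1, 8)
        base = ivw_estimate(make_set(g, G, s), model="ivw_fixed")
        scaled = ivw_estimate(make_set(g, G, 3.7 * s), model="ivw_fixed")
        assert scaled.beta == pytest.approx(base.beta, abs=1e-12)
        assert scaled.se == pytest.approx(3.7 * base.se, rel=1e-12)


class TestEgger:
    def test_exact_linear_data_recovered(self, rng):
        g = rng.uniform(0.05, 0.2, 6)
        G = 0.01 + 0.3 * g
        e = egger_estimate(make_set(g, G, rng.uniform(0.01, 0.1, 6)))
        assert e.beta == pytest.approx(0.3, abs=1e-10)
        assert e.egger_intercept == pytest.approx(0.01, abs=1e-10)

    def test_proportional_data_gives_zero_intercept_and_ivw_slope(self, rng):
        g = rng.uniform(0.05, 0.2, 6)
        s = rng.uniform(0.01, 0.1, 6)
        G = 0.3 * g
        e = egger_estimate(make_set(g, G, s))
        ivw = ivw_estimate(make_set(g, G, s))
        assert e.egger_intercept == pytest.approx(0.0, abs=1e-12)
        assert e.beta == pytest.approx(ivw.beta, abs=1e-10)

    def test_matches_wls_oracle_after_orientation(self, rng):
        for _ in range(50):
            J = int(rng.integers(3, 20))
            g = rng.normal(0, 0.1, J)
            G = rng.normal(0, 0.1, J)
            s = rng.uniform(0.01, 0.2, J)
            e = egger_estimate(make_set(g, G, s))
            sign = np.where(g < 0, -1.0, 1.0)
            X = sm.add_constant(g * sign)
            fit = sm.WLS(G * sign, X, weights=1 / s**2).fit()
            assert e.beta == pytest.approx(fit.params[1], abs=1e-10)
            assert e.egger_intercept == pytest.approx(fit.params[0], abs=1e-10)

    def test_orientation_makes_result_label_invariant(self, rng):
        g = rng.normal(0, 0.1, 8)
        G = rng.normal(0, 0.1, 8)
        s = rng.uniform(0.01, 0.1, 8)
        flip = rng.choice([-1.0, 1.0], 8)
        a = egger_estimate(make_set(g, G, s))
        b = egger_estimate(make_set(g * flip, G * flip, s))
        assert a.beta == pytest.approx(b.beta, abs=1e-12)
        assert a.egger_intercept == pytest.approx(b.egger_intercept, abs=1e-12)

    def test_too_few_instruments_is_usage_error(self):
        with pytest.raises(ValueError):
            egger_estimate(make_set([0.1, 0.2], [0.0, 0.1], [0.05, 0.05]))


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self):
        e = weighted_median_estimate(
            make_set([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [1.0, 1.0, 1.0]),
            n_boot=50, seed=1,
        )
        assert e.beta == pytest.approx(2.0)

    def test_interpolation_with_unequal_weights(self):
        # theta = (1,2,3) with weights (1,1,2): midpoints (0.125, 0.375, 0.75)
        # -> interpolate at 0.5 between (0.375, 2) and (0.75, 3) = 2.3333
        gamma = np.array([1.0, 1.0, np.sqrt(2.0)])
        Gamma = np.array([1.0, 2.0, 3.0 * np.sqrt(2.0)])
        e = weighted_median_estimate(
            make_set(gamma, Gamma, [1.0, 1.0, 1.0]), n_boot=50, seed=1
        )
        assert e.beta == pytest.approx(2.0 + (0.5 - 0.375) / (0.75 - 0.375), abs=1e-9)

    def test_degenerate_thetas_give_tiny_se(self):
        g = np.array([0.1, 0.2, 0.3])
        e = weighted_median_estimate(
            make_set(g, 2.0 * g, [1e-4] * 3, se_exp=[1e-4] * 3),
            n_boot=200, seed=3,
        )
        assert e.beta == pytest.approx(2.0)
        assert e.se < 0.01

    def test_bootstrap_reproducible_given_seed(self, rng):
        hset = make_set(rng.uniform(0.05, 0.2, 5), rng.normal(0, 0.05, 5),
                        rng.uniform(0.01, 0.1, 5))
        a = weighted_median_estimate(hset, n_boot=200, seed=42)
        b = weighted_median_estimate(hset, n_boot=200, seed=42)
        c = weighted_median_estimate(hset, n_boot=200, seed=43)
        assert a.se == b.se and a.se != c.se

    def test_seed_required(self):
        with pytest.raises(ValueError):
            weighted_median_estimate(make_set([1, 1, 1], [1, 2, 3], [1, 1, 1]))

    def test_odd_equal_weight_median_property(self, rng):
        for _ in range(20):
            J = int(rng.choice([3, 5, 7, 9]))
            theta = rng.normal(0, 1, J)
            e = weighted_median_estimate(
                make_set(np.ones(J), theta, np.ones(J)), n_boot=10, seed=0
            )
            assert e.beta == pytest.approx(np.median(theta), abs=1e-12)


class TestCochranQ:
    def test_homogeneous_gives_zero(self):
        hset = make_set([0.1, 0.2], [0.05, 0.10], [0.05, 0.05])
        q, df, p = cochran_q(hset, 0.5)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)

    def test_direct_sum(self):
        # theta = (0, 1), w = (1, 1), beta = 0.5 -> Q = 0.5
        hset = make_set([1.0, 1.0], [0.0, 1.0], [1.0, 1.0])
        q, df, _ = cochran_q(hset, 0.5)
        assert q == pytest.approx(0.5) and df == 1

    def test_monotone_in_outlier_distance(self):
        qs = []
        for shift in [0.0, 0.5, 1.0, 2.0]:
            hset = make_set([1.0, 1.0, 1.0], [0.5, 0.5, 0.5 + shift], [1.0] * 3)
            qs.append(cochran_q(hset, 0.5)[0])
        assert qs == sorted(qs) and qs[0] < qs[-1]

    def test_single_pair_is_usage_error(self):
        with pytest.raises(ValueError):
            cochran_q(make_set([0.1], [0.05], [0.05]), 0.5)


def test_joint_sign_flip_equivariance(rng):
    """Flipping a variant's exposure and outcome signs together changes nothing."""
    g = rng.uniform(0.05, 0.2, 6)
    G = rng.normal(0.02, 0.05, 6)
    s = rng.uniform(0.01, 0.1, 6)
    flip = np.array([1, -1, 1, -1, -1, 1.0])
    base, flipped = make_set(g, G, s), make_set(g * flip, G * flip, s)
    assert ivw_estimate(base).beta == pytest.approx(ivw_estimate(flipped).beta, abs=1e-12)
    assert egger_estimate(base).beta == pytest.approx(egger_estimate(flipped).beta, abs=1e-12)
    wm_a = weighted_median_estimate(base, n_boot=10, seed=5)
    wm_b = weighted_median_estimate(flipped, n_boot=10, seed=5)
    assert wm_a.beta == pytest.approx(wm_b.beta, abs=1e-12)
    r_a = ratio_estimate(base.pairs[1])
    r_b = ratio_estimate(flipped.pairs[1])
    assert r_a.beta == pytest.approx(r_b.beta) and r_a.se == pytest.approx(r_b.se)
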