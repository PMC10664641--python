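import numpy as np
import pytest

from nichegoal import (
    AbsDevReward,
    EasygoingCost,
    InfluencingVariables,
    LinearProfit,
    MeritParams,
    MeritWeights,
    ProductQuality,
    altruistic_merit,
    easygoing_cost,
    emotional_merit,
    monetary_trait_costs,
    nonmonetary_reward,
    performance_merit,
    product_quality,
    profit_merit,
    total_merit,
)
from conftest import simple_env

LABELS = ("yield", "temperament")


def make_params(**kw) -> MeritParams:
    defaults = dict(trait_labels=LABELS)
    defaults.update(kw)
    return MeritParams(**defaults)


class TestProfit:
    def test_all_zero_coefficients(self):
        p = make_params()
        v = InfluencingVariables()
        assert profit_merit(np.array([3.0, 4.0]), v, p) == 0.0

    def test_direct_arithmetic(self):
        p = make_params(profit=LinearProfit(
            base={"yield": 2.0, "temperament": -1.0}, fixed=-3.0))
        v = InfluencingVariables()
        assert profit_merit(np.array([4.0, 2.0]), v, p) == pytest.approx(3.0)

    def test_price_multiplier(self):
        p = make_params(profit=LinearProfit(
            multipliers={"yield": {"milk_price": 1.0}}))
        e = simple_env()  # milk_price = 0.4
        assert profit_merit(np.array([8000.0, 0.0]), e.influencing, p) == (
            pytest.approx(3200.0))

    def test_missing_variable_errors(self):
        p = make_params(profit=LinearProfit(
            multipliers={"yield": {"wool_price": 1.0}}))
        with pytest.raises(KeyError, match="wool_price"):
            profit_merit(np.zeros(2), InfluencingVariables(), p)


class TestRewards:
    def test_at_optimum_equals_tau_max(self):
        p = make_params(performance=AbsDevReward(
            omega={"yield": 1.0, "temperament": 2.0},
            opt={"yield": 0.0, "temperament": 0.0}, tau_max=10.0))
        assert performance_merit(np.zeros(2), p) == pytest.approx(10.0)
        assert performance_merit(np.array([1.0, 1.0]), p) == pytest.approx(7.0)

    def test_moving_from_optimum_never_increases(self):
        p = make_params(performance=AbsDevReward(
            omega={"yield": 0.7}, opt={"yield": 2.0}, tau_max=5.0))
        at_opt = performance_merit(np.array([2.0, 0.0]), p)
        for dy in (0.1, -0.5, 3.0):
            assert performance_merit(np.array([2.0 + dy, 0.0]), p) <= at_opt

    def test_emotional_zero_omega_constant(self):
        p = make_params(emotional=AbsDevReward(tau_max=5.0))
        for y in ([0.0, 0.0], [9.0, -9.0]):
            assert emotional_merit(np.array(y), p) == pytest.approx(5.0)

    def test_emotional_direct_arithmetic(self):
        p = make_params(emotional=AbsDevReward(
            omega={"yield": 0.5}, opt={"yield": 8.0}, tau_max=5.0))
        assert emotional_merit(np.array([6.0, 0.0]), p) == pytest.approx(4.0)

    def test_altruistic_empty_is_constant_zero(self):
        p = make_params()
        assert altruistic_merit(np.array([7.0, -2.0]), p) == 0.0

    def test_altruistic_direct_arithmetic(self):
        p = make_params(altruistic=AbsDevReward(
            omega={"yield": 1.0}, opt={"yield": 0.0}, tau_max=3.0),
            breed_id="old_breed")
        assert altruistic_merit(np.array([0.5, 0.0]), p) == pytest.approx(2.5)


class TestEasygoingCost:
    def test_equal_costs_give_zero(self):
        p = make_params(easygoing=EasygoingCost(
            omega={"yield": 1.0}, omega_mon={"yield": 1.0}))
        assert easygoing_cost(np.array([4.0, 0.0]), p) == 0.0

    def test_direct_arithmetic(self):
        p = make_params(easygoing=EasygoingCost(
            omega={"yield": 2.0}, omega_mon={"yield": 0.5}))
        assert easygoing_cost(np.array([4.0, 0.0]), p) == pytest.approx(6.0)

    def test_trait_with_lower_perceived_cost_excluded(self):
        base = make_params(easygoing=EasygoingCost(
            omega={"yield": 2.0}, omega_mon={"yield": 0.5}))
        extra = make_params(easygoing=EasygoingCost(
            omega={"yield": 2.0, "temperament": 0.1},
            omega_mon={"yield": 0.5, "temperament": 0.9}))
        y = np.array([4.0, 7.0])
        assert easygoing_cost(y, extra) == easygoing_cost(y, base)


class TestTotalMerit:
    def test_weighted_reward_sum(self):
        p = make_params(
            performance=AbsDevReward(omega={"yield": 1.0}, opt={"yield": 0.0},
                                     tau_max=8.0),
            emotional=AbsDevReward(tau_max=4.0),
            altruistic=AbsDevReward(tau_max=2.5),
            weights=MeritWeights(w=(1.0, 1.0, 1.0)))
        y = np.array([1.0, 0.0])
        assert nonmonetary_reward(y, p) == pytest.approx(7.0 + 4.0 + 2.5)
        p0 = make_params(weights=MeritWeights(w=(0.0, 0.0, 0.0)))
        assert nonmonetary_reward(y, p0) == 0.0

    def test_lambda_zero_reduces_to_profit(self):
        p = make_params(
            profit=LinearProfit(base={"yield": 2.0}, fixed=1.0),
            performance=AbsDevReward(omega={"yield": 1.0},
                                     opt={"yield": 0.0}, tau_max=10.0),
            weights=MeritWeights(lambda_=0.0))
        e = simple_env()
        y = np.array([3.0, 0.0])
        assert total_merit(y, e, p) == profit_merit(y, e.influencing, p)

    def test_linearity_in_lambda(self):
        def tm(lam):
            p = make_params(
                profit=LinearProfit(base={"yield": 1.0}, fixed=3.0),
                performance=AbsDevReward(omega={"yield": 1.0},
                                         opt={"yield": 0.0}, tau_max=10.0),
                easygoing=EasygoingCost(omega={"yield": 2.0},
                                        omega_mon={"yield": 0.5}),
                weights=MeritWeights(lambda_=lam, w=(1.0, 0.0, 0.0)))
            return total_merit(np.array([2.0, 0.0]), simple_env(), p)

        phi = tm(0.0)
        assert tm(0.5) - phi == pytest.approx(0.5 * (tm(1.0) - phi))

    def test_permutation_of_trait_order_is_irrelevant(self):
        kw = dict(
            profit=LinearProfit(base={"yield": 2.0, "temperament": -1.0},
                                fixed=1.0),
            performance=AbsDevReward(
                omega={"yield": 1.0, "temperament": 0.5},
                opt={"yield": 3.0, "temperament": 6.0}, tau_max=9.0),
            easygoing=EasygoingCost(omega={"temperament": 1.0},
                                    omega_mon={"temperament": 0.2}),
        )
        p_fwd = MeritParams(trait_labels=("yield", "temperament"), **kw)
        p_rev = MeritParams(trait_labels=("temperament", "yield"), **kw)
        e = simple_env()
        y = {"yield": 4.0, "temperament": 5.5}
        v_fwd = total_merit(np.array([y["yield"], y["temperament"]]), e, p_fwd)
        v_rev = total_merit(np.array([y["temperament"], y["yield"]]), e, p_rev)
        assert v_fwd == pytest.approx(v_rev)


class TestProductQuality:
    def test_constant_when_no_coefficients(self):
        p = make_params(quality=ProductQuality(q0=2.5))
        assert product_quality(np.array([9.0, 9.0]), p) == pytest.approx(2.5)

    def test_direct_arithmetic_and_scaling(self):
        p = make_params(quality=ProductQuality(
            coef={"yield": 1.0, "temperament": -1.0}, q0=0.0))
        y = np.array([5.0, 2.0])
        assert product_quality(y, p) == pytest.approx(3.0)
        p2 = make_params(quality=ProductQuality(
            coef={"yield": 3.0, "temperament": -3.0}, q0=0.0))
        assert product_quality(y, p2) == pytest.approx(9.0)


class TestMonetaryTraitCosts:
    def test_linear_profit_gradient_is_exact_and_mu_independent(self):
        p = make_params(profit=LinearProfit(
            base={"yield": 2.0, "temperament": -1.0}, fixed=5.0))
        v = InfluencingVariables()
        for mu in (np.zeros(2), np.array([100.0, -3.0])):
            assert monetary_trait_costs(p, mu, v) == pytest.approx([2.0, -1.0])

    def test_matches_finite_differences(self):
        p = make_params(profit=LinearProfit(
            base={"yield": 1.5}, multipliers={"yield": {"milk_price": 2.0}},
            fixed=-4.0))
        e = simple_env()
        mu = np.array([7.0, 3.0])
        grad = monetary_trait_costs(p, mu, e.influencing)
        h = 1e-5
        for k in range(2):
            dmu = np.zeros(2)
            dmu[k] = h
            fd = (profit_merit(mu + dmu, e.influencing, p)
                  - profit_merit(mu - dmu, e.influencing, p)) / (2 * h)
            assert abs(fd - grad[k]) < 1e-6

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            MeritWeights(alpha=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError, match="omega"):
            AbsDevReward(omega={"x": -1.0}, opt={"x": 0.0})
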