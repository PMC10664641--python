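import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import chi2

from nichegoal import (
    AbsDevReward,
    ChoiceDataset,
    FitStructure,
    LinearProfit,
    MeritParams,
    MeritWeights,
    ProductQuality,
    fit_alpha_weights,
    fit_merit_params,
    simulate_choice_experiment,
    total_merit,
    willingness_to_pay,
)
from conftest import simple_env

BOX1 = {"w": (-2.0, 3.0)}


def one_trait_params(omega=1.5, opt=0.7):
    return MeritParams(
        trait_labels=("w",),
        performance=AbsDevReward(omega={"w": omega}, opt={"w": opt},
                                 tau_max=10.0),
        weights=MeritWeights(lambda_=1.0, w=(1.0, 0.0, 0.0),
                             alpha=(0.0, 1.0, 0.0)),
    )


class TestSimulateChoices:
    def test_identical_profiles_choose_half(self, env):
        # force A == B by a zero-width box on an unweighted trait
        p = MeritParams(trait_labels=("w",),
                        weights=MeritWeights(alpha=(0.0, 1.0, 0.0)))
        ds = simulate_choice_experiment(p, env, {"w": (1.0, 1.0)}, n=4000,
                                        scale=1.0, seed=0)
        # utilities identical -> P(A) = 0.5 exactly; frequency binomial
        freq = (ds.table["chosen"] == "A").mean()
        assert abs(freq - 0.5) <= 3 * np.sqrt(0.25 / 4000)

    def test_small_scale_limit_is_deterministic(self, env):
        p = one_trait_params()
        ds = simulate_choice_experiment(p, env, BOX1, n=500, scale=1e-9,
                                        seed=1)
        yA = ds.profiles("A")[:, 0]
        yB = ds.profiles("B")[:, 0]
        better_a = (total_merit(ds.profiles("A"), env, p)
                    > total_merit(ds.profiles("B"), env, p))
        assert np.all((ds.table["chosen"] == "A") == better_a)

    def test_degenerate_box_on_weighted_trait_errors(self, env):
        with pytest.raises(ValueError, match="degenerate"):
            simulate_choice_experiment(one_trait_params(), env,
                                       {"w": (1.0, 1.0)}, n=10, scale=1.0,
                                       seed=0)

    def test_choice_frequencies_follow_logistic_curve(self, env):
        p = one_trait_params(omega=1.0, opt=0.0)
        ds = simulate_choice_experiment(p, env, BOX1, n=10_000, scale=1.0,
                                        seed=2)
        u = (np.asarray(total_merit(ds.profiles("A"), env, p))
             - np.asarray(total_merit(ds.profiles("B"), env, p)))
        chose_a = (ds.table["chosen"] == "A").to_numpy()
        # Hosmer-Lemeshow-style: decile bins of predicted probability
        pred = expit(u)
        bins = np.quantile(pred, np.linspace(0, 1, 11))
        idx = np.clip(np.searchsorted(bins, pred, side="right") - 1, 0, 9)
        stat = 0.0
        for g in range(10):
            m = idx == g
            if m.sum() == 0:
                continue
            o, e = chose_a[m].sum(), pred[m].sum()
            v = (pred[m] * (1 - pred[m])).sum()
            stat += (o - e) ** 2 / v
        assert stat < chi2.ppf(0.99, df=8)

    def test_reproducible_given_seed(self, env):
        p = one_trait_params()
        a = simulate_choice_experiment(p, env, BOX1, n=50, scale=1.0, seed=5)
        b = simulate_choice_experiment(p, env, BOX1, n=50, scale=1.0, seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)


class TestFitMeritParams:
    def test_single_trait_recovery_within_3se(self, env):
        p = one_trait_params(omega=1.5, opt=0.7)
        ds = simulate_choice_experiment(p, env, BOX1, n=5000, scale=1.0,
                                        seed=10)
        fit = fit_merit_params(ds, FitStructure("performance", ("w",)),
                               base_params=p)
        assert fit.converged and not fit.separation
        assert abs(fit.omega["w"] - 1.5) <= 3 * fit.se_omega["w"]
        assert abs(fit.opt["w"] - 0.7) <= 3 * fit.se_opt["w"]
        assert fit.params.performance.omega["w"] == pytest.approx(
            max(fit.omega["w"], 0.0))

    def test_zero_omega_trait_estimated_near_zero(self, env):
        p = MeritParams(
            trait_labels=("w", "v"),
            performance=AbsDevReward(
                omega={"w": 1.2, "v": 0.0}, opt={"w": 0.5, "v": 0.0},
                tau_max=10.0),
            weights=MeritWeights(w=(1.0, 0.0, 0.0), alpha=(0.0, 1.0, 0.0)),
        )
        box = {"w": (-2.0, 3.0), "v": (-2.0, 3.0)}
        ds = simulate_choice_experiment(p, env, box, n=5000, scale=1.0,
                                        seed=11)
        fit = fit_merit_params(
            ds, FitStructure("performance", ("w", "v"), fit_opt=False,
                             opt_fixed={"w": 0.5, "v": 0.0}))
        assert abs(fit.omega["v"]) <= 2 * fit.se_omega["v"]

    def test_mle_beats_truth_likelihood(self, env):
        p = one_trait_params(omega=1.5, opt=0.7)
        ds = simulate_choice_experiment(p, env, BOX1, n=2000, scale=1.0,
                                        seed=12)
        fit = fit_merit_params(ds, FitStructure("performance", ("w",)),
                               base_params=p)
        # log-likelihood at the truth cannot exceed the MLE's
        yA, yB = ds.profiles("A"), ds.profiles("B")
        chose_a = (ds.table["chosen"] == "A").to_numpy()
        X = (np.abs(yB - 0.7) - np.abs(yA - 0.7)) / ds.scale
        u = X @ np.array([1.5])
        s = np.where(chose_a, 1.0, -1.0)
        ll_truth = float(-np.sum(np.logaddexp(0.0, -s * u)))
        assert ll_truth <= fit.loglik + 1e-9

    def test_tau_max_not_identifiable_likelihood_flat(self, env):
        # adding a constant to the utility leaves every choice probability,
        # hence the likelihood, unchanged
        p1 = one_trait_params()
        import dataclasses
        p2 = dataclasses.replace(
            p1, performance=AbsDevReward(omega={"w": 1.5}, opt={"w": 0.7},
                                         tau_max=999.0))
        ds1 = simulate_choice_experiment(p1, env, BOX1, n=300, scale=1.0,
                                         seed=13)
        ds2 = simulate_choice_experiment(p2, env, BOX1, n=300, scale=1.0,
                                         seed=13)
        pd.testing.assert_frame_equal(ds1.table, ds2.table)

    def test_separation_flagged_not_raised(self, env):
        p = one_trait_params(omega=5.0, opt=0.0)
        ds = simulate_choice_experiment(p, env, BOX1, n=200, scale=1e-9,
                                        seed=14)
        fit = fit_merit_params(
            ds, FitStructure("performance", ("w",), fit_opt=False,
                             opt_fixed={"w": 0.0}))
        assert fit.separation
        assert fit.se_omega is None

    def test_consistency_error_shrinks_with_n(self, env):
        p = one_trait_params(omega=1.5, opt=0.7)
        errs = []
        for n in (500, 4000):
            abs_err = []
            for rep in range(6):
                ds = simulate_choice_experiment(p, env, BOX1, n=n, scale=1.0,
                                                seed=100 + rep)
                fit = fit_merit_params(ds,
                                       FitStructure("performance", ("w",)))
                abs_err.append(abs(fit.omega["w"] - 1.5)
                               + abs(fit.opt["w"] - 0.7))
            errs.append(np.median(abs_err))
        assert errs[1] < errs[0]


class TestAlphaWeights:
    def _params(self, alpha):
        # the feed-quality multiplier makes the producer-environment merit a
        # genuinely different function of the profile, not a constant offset
        return MeritParams(
            trait_labels=("w", "v"),
            profit=LinearProfit(base={"w": 1.0},
                                multipliers={"w": {"feed_quality": 0.8}}),
            quality=ProductQuality(coef={"v": 1.5}, q0=0.0),
            performance=AbsDevReward(omega={"v": 0.8}, opt={"v": 0.5},
                                     tau_max=5.0),
            weights=MeritWeights(lambda_=1.0, w=(1.0, 0.0, 0.0), alpha=alpha),
        )

    def test_pure_owner_weight_recovered(self, env):
        producer = simple_env().with_values({"feed_quality": 3.0})
        p = self._params((0.0, 1.0, 0.0))
        box = {"w": (-2.0, 2.0), "v": (-2.0, 2.0)}
        ds = simulate_choice_experiment(p, env, box, n=5000, scale=1.0,
                                        seed=20, utility="adaptedness",
                                        producer_env=producer)
        fit = fit_alpha_weights(ds, p, env, producer)
        assert fit.alpha[1] >= 0.9
        assert sum(fit.alpha) == pytest.approx(1.0, abs=1e-9)

    def test_normalized_to_simplex(self, env):
        producer = simple_env().with_values({"feed_quality": 3.0})
        p = self._params((0.3, 0.4, 0.3))
        box = {"w": (-2.0, 2.0), "v": (-2.0, 2.0)}
        ds = simulate_choice_experiment(p, env, box, n=3000, scale=1.0,
                                        seed=21, utility="adaptedness",
                                        producer_env=producer)
        fit = fit_alpha_weights(ds, p, env, producer)
        assert sum(fit.alpha) == pytest.approx(1.0, abs=1e-9)
        assert all(a >= 0 for a in fit.alpha)

    def test_collinear_components_flagged(self, env):
        # producer env identical to the owner env and no PQ distinction:
        # TM_p == TM_n, so the weights cannot be identified
        p = MeritParams(
            trait_labels=("w",),
            profit=LinearProfit(base={"w": 1.0}),
            quality=ProductQuality(coef={"w": 1.0}),
            weights=MeritWeights(lambda_=0.0, alpha=(0.5, 0.5, 0.0)),
        )
        ds = simulate_choice_experiment(p, env, {"w": (-2.0, 2.0)}, n=500,
                                        scale=1.0, seed=22,
                                        utility="adaptedness",
                                        producer_env=env)
        fit = fit_alpha_weights(ds, p, env, env)
        assert not fit.identifiable


def test_willingness_to_pay():
    assert willingness_to_pay(2.0, 0.5) == pytest.approx(4.0)
    with pytest.raises(ValueError):
        willingness_to_pay(1.0, 0.0)
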