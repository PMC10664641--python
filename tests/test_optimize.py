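import math

import numpy as np
import pytest

from nichegoal import (
    GeneticParameters,
    HalfspaceExclusion,
    PermissibleSet,
    ResponseArea,
    SearchArea,
    build_response_area,
    default_search_box,
    desired_gain_index,
    expected_response,
    index_variance_check,
    membership,
    optimize_goal,
    smith_hazel_index,
)
from conftest import random_genetics


def make_pset(gen, mu_c, labels=None, radius_gens=2, intensity=1.0,
              k_sd=2.0, exclusions=()):
    labels = labels or tuple(f"t{k}" for k in range(gen.K))
    box = default_search_box(labels, mu_c, gen.P, k_sd)
    return PermissibleSet(
        search=SearchArea(box=box, exclusions=tuple(exclusions)),
        response=build_response_area(gen, mu_c, intensity, radius_gens,
                                     labels=labels),
    )


class TestResponseArea:
    def test_scalar_case_is_breeders_equation_interval(self):
        gen = GeneticParameters(G=np.array([[2.0]]), P=np.array([[4.0]]))
        area = build_response_area(gen, np.array([10.0]), intensity=1.5,
                                   generations=4)
        # half-width = T i g / sqrt(p)
        half = 4 * 1.5 * 2.0 / math.sqrt(4.0)
        assert area.contains(np.array([10.0 + half]))
        assert area.contains(np.array([10.0 - half]))
        assert not area.contains(np.array([10.0 + half + 1e-6]))

    def test_identity_matrices_give_euclidean_ball(self):
        gen = GeneticParameters(G=np.eye(3) * 0.999999, P=np.eye(3))
        area = build_response_area(gen, np.zeros(3), intensity=1.0,
                                   generations=2)
        v = np.array([2.0, 0.0, 0.0])
        assert area.quad(v) == pytest.approx(4.0, rel=1e-5)

    def test_index_responses_lie_on_boundary(self):
        rng = np.random.default_rng(42)
        gen = random_genetics(rng, 4)
        T, i = 3, 1.2
        area = build_response_area(gen, np.zeros(4), i, T)
        for _ in range(100):
            b = rng.standard_normal(4)
            resp = T * expected_response(gen, b, i)
            assert area.quad(resp) == pytest.approx((T * i) ** 2, abs=1e-9)

    def test_singular_g_rejected(self):
        G = np.array([[1.0, 1.0], [1.0, 1.0]])
        gen_P = np.eye(2) * 2.0
        gen = GeneticParameters(G=G, P=gen_P)
        with pytest.raises(ValueError, match="singular"):
            build_response_area(gen, np.zeros(2), 1.0, 1)


class TestMembership:
    def test_center_is_member(self, two_trait_state):
        pset = make_pset(two_trait_state.genetics, two_trait_state.mu_c)
        ok, viol = membership(pset, two_trait_state.mu_c)
        assert ok and viol == []

    def test_box_violation_labels_trait(self, two_trait_state):
        pset = make_pset(two_trait_state.genetics, two_trait_state.mu_c,
                         labels=("yield", "temperament"))
        mu = two_trait_state.mu_c + np.array([100.0, 0.0])
        ok, viol = membership(pset, mu)
        assert not ok
        assert "box:yield" in viol

    def test_ellipsoid_boundary_is_member(self):
        gen = GeneticParameters(G=np.eye(2) * 0.5, P=np.eye(2))
        pset = make_pset(gen, np.zeros(2), radius_gens=2, k_sd=10)
        L = np.linalg.cholesky(np.linalg.inv(pset.response.shape))
        mu = pset.response.radius * L[:, 0] / np.linalg.norm(
            np.linalg.solve(L, L[:, 0]))
        # construct a point with quadratic form exactly r^2
        d = np.array([1.0, 0.3])
        q = d @ pset.response.shape @ d
        mu = d * pset.response.radius / math.sqrt(q)
        assert pset.response.quad(mu) == pytest.approx(
            pset.response.radius**2)
        ok, _ = membership(pset, mu)
        assert ok

    def test_exclusion_labelled(self):
        gen = GeneticParameters(G=np.eye(2) * 0.5, P=np.eye(2))
        exc = HalfspaceExclusion("welfare_floor", {"t0": 1.0}, 0.5,
                                 direction="above")
        pset = make_pset(gen, np.zeros(2), exclusions=[exc])
        ok, viol = membership(pset, np.array([1.0, 0.0]))
        assert not ok and "exclusion:welfare_floor" in viol


class TestOptimizeGoal:
    def test_linear_objective_matches_analytic_argmax(self):
        rng = np.random.default_rng(1)
        for trial in range(5):
            gen = random_genetics(rng, 3)
            mu_c = rng.normal(size=3)
            a = rng.normal(size=3)
            pset = make_pset(gen, mu_c, radius_gens=1, intensity=0.5,
                             k_sd=50)  # box never binds
            res = optimize_goal(lambda mu: float(a @ mu), pset,
                                n_starts=3, seed=trial, tol=1e-10)
            Minv = np.linalg.inv(pset.response.shape)
            r = pset.response.radius
            expected = mu_c + r * (Minv @ a) / math.sqrt(a @ Minv @ a)
            np.testing.assert_allclose(res.mu_i, expected, atol=1e-5)

    def test_interior_optimum_found_exactly(self):
        gen = GeneticParameters(G=np.eye(2) * 0.5, P=np.eye(2))
        target = np.array([0.4, -0.3])
        obj = lambda mu: -np.sum(np.abs(mu - target))
        pset = make_pset(gen, np.zeros(2), radius_gens=2, k_sd=5)
        res = optimize_goal(obj, pset, n_starts=3, seed=0, tol=1e-10)
        np.testing.assert_allclose(res.mu_i, target, atol=1e-6)

    def test_result_is_member_and_ascends(self):
        rng = np.random.default_rng(7)
        gen = random_genetics(rng, 3)
        mu_c = rng.normal(size=3)
        obj = lambda mu: -float((mu - mu_c - 0.5) @ (mu - mu_c - 0.5))
        pset = make_pset(gen, mu_c)
        res = optimize_goal(obj, pset, n_starts=4, seed=1)
        ok, _ = membership(pset, res.mu_i)
        assert ok
        assert res.adaptedness >= obj(mu_c) - 1e-12

    def test_multi_start_agrees_with_single_start_on_concave(self):
        gen = GeneticParameters(G=np.eye(2) * 0.5, P=np.eye(2))
        obj = lambda mu: -float(mu @ mu) + float(mu[0])
        pset = make_pset(gen, np.zeros(2))
        r1 = optimize_goal(obj, pset, n_starts=1, seed=3, tol=1e-10)
        r8 = optimize_goal(obj, pset, n_starts=8, seed=3, tol=1e-10)
        assert r1.adaptedness == pytest.approx(r8.adaptedness, abs=1e-8)

    def test_empty_permissible_set_errors(self):
        gen = GeneticParameters(G=np.eye(2) * 0.5, P=np.eye(2))
        exc = HalfspaceExclusion("impossible", {"t0": 1.0}, 1e6,
                                 direction="below")
        with pytest.raises(ValueError, match="planning horizon"):
            make_and_run(gen, exc)

    def test_boundary_tangency_gradient_parallel_to_normal(self):
        # smooth objective, optimum on the ellipsoid: gradient parallel to
        # the constraint normal M (mu - c)
        gen = GeneticParameters(G=np.eye(2) * 0.5, P=np.eye(2))
        a = np.array([1.0, 2.0])
        pset = make_pset(gen, np.zeros(2), k_sd=50)
        res = optimize_goal(lambda mu: float(a @ mu), pset, n_starts=2,
                            seed=0, tol=1e-10)
        normal = pset.response.shape @ (res.mu_i - pset.response.center)
        cos = a @ normal / (np.linalg.norm(a) * np.linalg.norm(normal))
        assert abs(cos - 1.0) < 1e-6

    def test_deterministic_given_seed(self):
        gen = GeneticParameters(G=np.eye(2) * 0.5, P=np.eye(2))
        obj = lambda mu: -abs(mu[0] - 0.3) - abs(mu[1] + 0.2)
        pset = make_pset(gen, np.zeros(2))
        r1 = optimize_goal(obj, pset, n_starts=4, seed=9)
        r2 = optimize_goal(obj, pset, n_starts=4, seed=9)
        np.testing.assert_array_equal(r1.mu_i, r2.mu_i)


def make_and_run(gen, exc):
    pset = make_pset(gen, np.zeros(2), exclusions=[exc])
    return optimize_goal(lambda mu: 0.0, pset, n_starts=2, seed=0)


class TestIndices:
    def test_desired_gain_g_equals_p_cancellation(self):
        P = np.array([[2.0, 0.3], [0.3, 1.0]])
        gen = GeneticParameters(G=P * 0.999999, P=P)
        delta = np.array([1.0, -2.0])
        b = desired_gain_index(gen, delta)
        expected = np.linalg.solve(P, delta)
        expected = expected / math.sqrt(expected @ P @ expected)
        np.testing.assert_allclose(b, expected, rtol=1e-4)

    def test_diagonal_closed_form(self):
        gen = GeneticParameters(G=np.diag([2.0, 2.0]), P=np.diag([4.0, 4.0]))
        b = desired_gain_index(gen, np.array([1.0, 1.0]))
        assert b[0] == pytest.approx(b[1])
        resp = gen.G @ b
        assert resp[0] == pytest.approx(resp[1])

    def test_response_direction_collinear_with_desired_gains(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            gen = random_genetics(rng, 4)
            delta = rng.standard_normal(4)
            b = desired_gain_index(gen, delta)
            resp = expected_response(gen, b, intensity=1.0)
            # angle via the perpendicular component (acos loses precision
            # near zero angle)
            r = resp / np.linalg.norm(resp)
            d = delta / np.linalg.norm(delta)
            angle = np.linalg.norm(r - (r @ d) * d)
            assert angle < 1e-8

    def test_zero_delta_rejected(self):
        gen = GeneticParameters(G=np.eye(2) * 0.5, P=np.eye(2))
        with pytest.raises(ValueError, match="no gain"):
            desired_gain_index(gen, np.zeros(2))
        with pytest.raises(ValueError, match="null index"):
            expected_response(gen, np.zeros(2), 1.0)

    def test_scalar_response_magnitude(self):
        gen = GeneticParameters(G=np.array([[2.0]]), P=np.array([[4.0]]))
        for b in ([1.0], [5.0], [-2.0]):
            resp = expected_response(gen, np.array(b), intensity=1.0)
            assert abs(resp[0]) == pytest.approx(2.0 / math.sqrt(4.0))

    def test_smith_hazel_g_equals_p(self):
        P = np.diag([1.0, 4.0])
        gen = GeneticParameters(G=P * 0.999999, P=P)
        a = np.array([2.0, 1.0])
        b = smith_hazel_index(gen, a)
        assert b[0] / b[1] == pytest.approx(a[0] / a[1], rel=1e-4)

    def test_index_variance_positive_and_flagging(self):
        gen = GeneticParameters(G=np.eye(2) * 0.5, P=np.eye(2))
        var, flagged = index_variance_check(gen, np.array([1.0, 0.0]))
        assert var == pytest.approx(0.5) and not flagged
        # b in the null space of a singular G
        G = np.array([[1.0, 0.0], [0.0, 0.0]])
        gen2 = GeneticParameters(G=G, P=np.eye(2) * 2)
        var2, flagged2 = index_variance_check(gen2, np.array([0.0, 1.0]))
        assert var2 == 0.0 and flagged2

    def test_index_variance_eigendecomposition_identity(self):
        rng = np.random.default_rng(5)
        gen = random_genetics(rng, 4)
        b = rng.standard_normal(4)
        vals, vecs = np.linalg.eigh(gen.G)
        contrib = ((vecs.T @ b) ** 2 * vals).sum()
        var, _ = index_variance_check(gen, b)
        assert abs(var - contrib) < 1e-10 * max(1.0, abs(var))
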