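"""Permissible breeding goals and adaptedness maximization.

The *search area* S_b is a per-trait box (default: current means plus or
minus two phenotypic SDs) minus labelled ethical exclusions (half-spaces or
boxes over traits that are incompatible with animal health or welfare).
The *response area* R_b is the ellipsoid of trait-mean states reachable
within the planning horizon: per generation the multivariate response to
index selection is Delta = i G b / sqrt(b' P b), and sweeping b over all
index vectors traces the surface (mu - mu_c)' (G P^-1 G)^-1 (mu - mu_c) =
i^2, so T generations at intensity i reach the ellipsoid with shape matrix
M = (G P^-1 G)^-1 and radius r = T i.  The permissible set is the
intersection U_b = S_b ∩ R_b minus exclusions.

The optimizer maximizes a (generally nonsmooth, concave) adaptedness
objective over U_b by multi-start projected compass search in the
coordinates in which the ellipsoid is the unit ball, with an SLSQP polish
when all exclusion constraints are convex.  From the optimum, the
desired-gain selection index b = P^-1 G (G' P^-1 G)^-1 Delta-mu realizes
the straight-line path from the current means to the goal; the classical
Smith-Hazel index b = P^-1 G a is provided as the traditional-approach
benchmark.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from ._rng import substream
from .breed import GeneticParameters

__all__ = [
    "HalfspaceExclusion",
    "BoxExclusion",
    "SearchArea",
    "ResponseArea",
    "PermissibleSet",
    "GoalResult",
    "default_search_box",
    "build_response_area",
    "membership",
    "optimize_goal",
    "desired_gain_index",
    "expected_response",
    "smith_hazel_index",
    "index_variance_check",
]

_QUAD_TOL = 1e-12


@dataclass(frozen=True)
class HalfspaceExclusion:
    """Excludes goals on one side of a hyperplane sum_k a_k mu_k vs threshold.

    ``direction`` is "below" (exclude a.mu < threshold, e.g. a health-score
    floor) or "above" (exclude a.mu > threshold).
    """

    label: str
    coeffs: Mapping[str, float]
    threshold: float
    direction: str = "below"

    def __post_init__(self) -> None:
        if self.direction not in ("below", "above"):
            raise ValueError("direction must be 'below' or 'above'")

    def excludes(self, mu: np.ndarray, labels: Sequence[str]) -> bool:
        val = sum(
            c * mu[list(labels).index(t)] for t, c in self.coeffs.items()
        )
        return val < self.threshold if self.direction == "below" else val > self.threshold


@dataclass(frozen=True)
class BoxExclusion:
    """Excludes goals strictly inside an axis-aligned box over some traits."""

    label: str
    bounds: Mapping[str, tuple[float, float]]

    def excludes(self, mu: np.ndarray, labels: Sequence[str]) -> bool:
        lab = list(labels)
        for t, (lo, hi) in self.bounds.items():
            v = mu[lab.index(t)]
            if not (lo < v < hi):
                return False
        return True


@dataclass(frozen=True)
class SearchArea:
    """Per-trait closed intervals plus labelled ethical exclusions."""

    box: Mapping[str, tuple[float, float]]
    exclusions: tuple[HalfspaceExclusion | BoxExclusion, ...] = ()

    def __post_init__(self) -> None:
        for t, (lo, hi) in self.box.items():
            if hi < lo:
                raise ValueError(f"empty search interval for trait {t!r}")
        labels = [x.label for x in self.exclusions]
        if len(set(labels)) != len(labels):
            raise ValueError("exclusion labels must be unique")


def default_search_box(
    labels: Sequence[str], mu_c: np.ndarray, P: np.ndarray, k_sd: float = 2.0
) -> dict[str, tuple[float, float]]:
    """Box mu_c +/- k_sd phenotypic standard deviations per trait."""
    sd = np.sqrt(np.diag(P))
    return {
        t: (float(m - k_sd * s), float(m + k_sd * s))
        for t, m, s in zip(labels, mu_c, sd)
    }


@dataclass(frozen=True)
class ResponseArea:
    """Reachability ellipsoid: (mu-center)' M (mu-center) <= radius^2."""

    center: np.ndarray
    shape: np.ndarray  # M = (G P^-1 G)^-1, symmetric positive definite
    radius: float
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        M = np.asarray(self.shape, dtype=float)
        c = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if not np.allclose(M, M.T, atol=1e-8 * max(1.0, np.abs(M).max())):
            raise ValueError("shape matrix must be symmetric")
        try:
            np.linalg.cholesky(M)
        except np.linalg.LinAlgError:
            raise ValueError("shape matrix must be positive definite") from None
        object.__setattr__(self, "shape", (M + M.T) / 2)
        object.__setattr__(self, "center", c)

    def quad(self, mu: np.ndarray) -> float:
        d = np.asarray(mu, dtype=float) - self.center
        return float(d @ self.shape @ d)

    def contains(self, mu: np.ndarray) -> bool:
        r2 = self.radius**2
        return self.quad(mu) <= r2 * (1 + _QUAD_TOL) + _QUAD_TOL


def build_response_area(
    gen: GeneticParameters,
    mu_c: np.ndarray,
    intensity: float,
    generations: int,
    labels: Sequence[str] | None = None,
) -> ResponseArea:
    """Ellipsoid of goals reachable in ``generations`` at intensity ``i``."""
    if intensity <= 0:
        raise ValueError("selection intensity must be > 0")
    if generations < 1:
        raise ValueError("generations must be >= 1")
    G, P = gen.G, gen.P
    cond = np.linalg.cond(G)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            "G is singular or nearly singular; the response area is degenerate "
            "— reduce the trait set to genetically independent traits"
        )
    Pinv = np.linalg.inv(P)
    A = G @ Pinv @ G  # M^-1
    M = np.linalg.inv(A)
    M = (M + M.T) / 2
    if labels is None:
        labels = tuple(f"trait_{k}" for k in range(gen.K))
    return ResponseArea(
        center=np.asarray(mu_c, dtype=float),
        shape=M,
        radius=float(generations * intensity),
        labels=tuple(labels),
    )


@dataclass(frozen=True)
class PermissibleSet:
    """U_b: in the search box AND in the response ellipsoid AND not excluded."""

    search: SearchArea
    response: ResponseArea

    @property
    def labels(self) -> tuple[str, ...]:
        return self.response.labels


def membership(pset: PermissibleSet, mu: np.ndarray) -> tuple[bool, list[str]]:
    """Exact membership test; returns (member, violated-constraint labels)."""
    mu = np.asarray(mu, dtype=float)
    violated: list[str] = []
    labels = pset.labels
    for k, t in enumerate(labels):
        if t in pset.search.box:
            lo, hi = pset.search.box[t]
            if mu[k] < lo or mu[k] > hi:
                violated.append(f"box:{t}")
    if not pset.response.contains(mu):
        violated.append("response_ellipsoid")
    for exc in pset.search.exclusions:
        if exc.excludes(mu, labels):
            violated.append(f"exclusion:{exc.label}")
    return (not violated), violated


@dataclass(frozen=True)
class GoalResult:
    """Optimized intermediate breeding goal and the index that realizes it."""

    mu_i: np.ndarray  # optimum permissible goal
    mu_c: np.ndarray
    delta_mu: np.ndarray
    adaptedness: float
    labels: tuple[str, ...]
    index_b: np.ndarray | None = None
    mu_s: np.ndarray | None = None  # search-area optimum, ignoring the ellipsoid
    n_starts: int = 0
    n_evaluations: int = 0
    converged: bool = True
    active_constraints: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not np.allclose(self.delta_mu, self.mu_i - self.mu_c, atol=1e-9):
            raise ValueError("delta_mu inconsistent with mu_i - mu_c")


def _ellipsoid_basis(M: np.ndarray) -> np.ndarray:
    """L with L' M L = I, so mu = center + radius * L z maps |z|<=1 onto R_b."""
    vals, vecs = np.linalg.eigh(M)
    return vecs @ np.diag(1.0 / np.sqrt(vals)) @ vecs.T


def optimize_goal(
    objective: Callable[[np.ndarray], float],
    pset: PermissibleSet,
    n_starts: int = 8,
    seed: int = 0,
    tol: float = 1e-9,
    gen: GeneticParameters | None = None,
    max_iter: int = 2000,
) -> GoalResult:
    """Maximize the adaptedness objective over the permissible set.

    Multi-start projected compass search in ellipsoid coordinates (moves are
    accepted only if feasible and improving; steps outside the ball are
    radially projected back), with an SLSQP polish from each compass optimum
    when every exclusion is a half-space (so the feasible set is convex).
    Deterministic given the seed; ties broken by first-found.  If ``gen`` is
    supplied the desired-gain index for the optimal gain vector is attached.
    """
    labels = pset.labels
    K = len(labels)
    center = pset.response.center
    r = pset.response.radius
    L = _ellipsoid_basis(pset.response.shape)
    n_eval = 0

    def to_mu(z: np.ndarray) -> np.ndarray:
        return center + r * (L @ z)

    def feasible(z: np.ndarray) -> bool:
        nz = np.linalg.norm(z)
        if nz > 1.0 + 1e-12:
            return False
        return membership(pset, to_mu(z))[0]

    def project(z: np.ndarray) -> np.ndarray:
        nz = np.linalg.norm(z)
        return z / nz if nz > 1.0 else z

    def value(z: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        return objective(to_mu(z))

    # start points: current means (if permissible) plus random feasible draws
    rng = substream(seed, "goal-optimizer")
    starts: list[np.ndarray] = []
    if feasible(np.zeros(K)):
        starts.append(np.zeros(K))
    attempts = 0
    while len(starts) < n_starts and attempts < 200 * n_starts:
        attempts += 1
        z = rng.standard_normal(K)
        z *= rng.uniform() ** (1.0 / K) / max(np.linalg.norm(z), 1e-300)
        if feasible(z):
            starts.append(z)
    if not starts:
        raise ValueError(
            "no permissible goal: the exclusions swallow the reachable set; "
            "extend the planning horizon so the permissible set is non-empty"
        )

    convex = all(
        isinstance(x, HalfspaceExclusion) for x in pset.search.exclusions
    )

    def compass(z0: np.ndarray, step0: float, tol_step: float
                ) -> tuple[np.ndarray, float]:
        z = z0.copy()
        best = value(z)
        step = step0
        it = 0
        dirs = np.vstack([np.eye(K), -np.eye(K)])
        eps = 1e-12 * (1.0 + abs(best))  # ignore float-noise "improvements"
        while step > tol_step and it < max_iter:
            it += 1
            improved = False
            for d in dirs:
                cand = project(z + step * d)
                if not feasible(cand):
                    continue
                v = value(cand)
                if v > best + eps:
                    z, best = cand, v
                    improved = True
                    break
            if not improved:
                step *= 0.5
        return z, best

    def gradient_polish(z0: np.ndarray) -> tuple[np.ndarray, float] | None:
        """Interior-point polish; valid when all exclusions are half-spaces."""
        from scipy.optimize import LinearConstraint, NonlinearConstraint

        lab = list(labels)
        cons = [NonlinearConstraint(lambda z: z @ z, -np.inf, 1.0)]
        box_rows, box_lo, box_hi = [], [], []
        for k, t in enumerate(lab):
            if t in pset.search.box:
                lo, hi = pset.search.box[t]
                box_rows.append(r * L[k])
                box_lo.append(lo - center[k])
                box_hi.append(hi - center[k])
        if box_rows:
            cons.append(LinearConstraint(np.array(box_rows),
                                         np.array(box_lo), np.array(box_hi)))
        for exc in pset.search.exclusions:
            a = np.zeros(K)
            for t, c in exc.coeffs.items():
                a[lab.index(t)] = c
            aL = (r * (a @ L))[None, :]
            bnd = exc.threshold - float(a @ center)
            if exc.direction == "below":  # keep a.mu >= threshold
                cons.append(LinearConstraint(aL, bnd, np.inf))
            else:
                cons.append(LinearConstraint(aL, -np.inf, bnd))
        scale = abs(value(np.zeros(K))) + 1.0
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = minimize(lambda z: -value(z) / scale, z0,
                           method="trust-constr", constraints=cons,
                           options={"maxiter": 500, "gtol": 1e-12,
                                    "xtol": 1e-12})
        z = res.x
        nz = np.linalg.norm(z)
        if nz > 1.0:  # tolerance-level constraint violation: pull back
            z = z / (nz * (1 + 1e-12))
        if feasible(z):
            return z, value(z)
        return None

    best_z: np.ndarray | None = None
    best_val = -np.inf
    for z0 in starts:
        z, v = z0, value(z0)
        if convex:
            # the closed-form objective is smooth and concave: the gradient
            # polish does the heavy lifting, compass only refines
            polished = gradient_polish(z0)
            if polished is not None and polished[1] >= v:
                z, v = polished
            z, v = compass(z, step0=1e-2, tol_step=tol)
        else:
            z, v = compass(z, step0=0.25, tol_step=tol)
        if v > best_val + 1e-15:
            best_z, best_val = z, v

    assert best_z is not None
    mu_i = to_mu(best_z)
    # snap coordinates to active box faces within tolerance
    for k, t in enumerate(labels):
        if t in pset.search.box:
            lo, hi = pset.search.box[t]
            if abs(mu_i[k] - lo) < 1e-12:
                mu_i[k] = lo
            if abs(mu_i[k] - hi) < 1e-12:
                mu_i[k] = hi
    ok, _ = membership(pset, mu_i)
    if not ok:  # numerical safety: radial pullback
        mu_i = center + (mu_i - center) * (1 - 1e-12)

    active = []
    q = pset.response.quad(mu_i)
    if q >= pset.response.radius**2 * (1 - 1e-6):
        active.append("response_ellipsoid")
    for k, t in enumerate(labels):
        if t in pset.search.box:
            lo, hi = pset.search.box[t]
            width = max(hi - lo, 1.0)
            if min(abs(mu_i[k] - lo), abs(mu_i[k] - hi)) < 1e-7 * width:
                active.append(f"box:{t}")

    delta = mu_i - center
    b = None
    if gen is not None and np.linalg.norm(delta) > 0:
        b = desired_gain_index(gen, delta)
    return GoalResult(
        mu_i=mu_i,
        mu_c=center.copy(),
        delta_mu=delta,
        adaptedness=best_val,
        labels=tuple(labels),
        index_b=b,
        n_starts=len(starts),
        n_evaluations=n_eval,
        converged=True,
        active_constraints=tuple(active),
    )


def desired_gain_index(gen: GeneticParameters, delta_mu: np.ndarray) -> np.ndarray:
    """Index weights whose expected response is proportional to ``delta_mu``.

    b = P^-1 G (G' P^-1 G)^-1 delta_mu, normalized to b' P b = 1 so the
    index has unit phenotypic variance (any positive scaling is equivalent
    for ranking).
    """
    delta = np.asarray(delta_mu, dtype=float)
    if np.linalg.norm(delta) == 0:
        raise ValueError("no gain requested: delta_mu is zero")
    Pinv = np.linalg.inv(gen.P)
    A = gen.G @ Pinv @ gen.G
    b = Pinv @ gen.G @ np.linalg.solve(A, delta)
    return b / math.sqrt(float(b @ gen.P @ b))


def expected_response(
    gen: GeneticParameters, b: np.ndarray, intensity: float
) -> np.ndarray:
    """Per-generation multi-trait response i G b / sqrt(b' P b)."""
    b = np.asarray(b, dtype=float)
    if np.linalg.norm(b) == 0:
        raise ValueError("null index: b is zero")
    return intensity * (gen.G @ b) / math.sqrt(float(b @ gen.P @ b))


def smith_hazel_index(
    gen: GeneticParameters, econ_weights: np.ndarray
) -> np.ndarray:
    """Classical economic index b = P^-1 G a, normalized to b' P b = 1."""
    a = np.asarray(econ_weights, dtype=float)
    b = np.linalg.solve(gen.P, gen.G @ a)
    nrm = math.sqrt(float(b @ gen.P @ b))
    if nrm == 0:
        raise ValueError("economic weights give a null index")
    return b / nrm


def index_variance_check(
    gen: GeneticParameters, b: np.ndarray, tol: float = 1e-10
) -> tuple[float, bool]:
    """Genetic variance b' G b of the index; flags inadmissible-goal risk.

    A (near-)zero genetic variance means selection on the index cannot move
    the population: the goal would exhaust the usable genetic variance
    before being reached.
    """
    b = np.asarray(b, dtype=float)
    var = float(b @ gen.G @ b)
    return var, var <= tol
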