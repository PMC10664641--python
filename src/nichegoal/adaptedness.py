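"""Adaptedness of a breed to an environment and to its niche.

The adaptedness to one environment is the expected role-weighted merit of a
random animal,

    a(mu_b, e) = alpha_p E TM_ep(y') + alpha_n E TM_e(y) + alpha_c E PQ(y),

with y ~ N(mu_b(e), P) and y' ~ N(mu_b(e_p), P).  Under the Gaussian
phenotype model and the package's merit forms every expectation is
available in closed form: linear terms pass through the mean, and each
E|y_k - Opt_k| is the folded-normal mean of the marginal, computed by
:func:`expected_abs_dev`.  A Monte-Carlo route with a plug-in standard
error is provided as an independent check and for any future non-linear
merit extension.

The adaptedness to the niche averages a(mu_b, e) over the niche's mixture
distribution of environments: exactly for finite-atom subniches, by Monte
Carlo over sampled environments for Gaussian subniches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Mapping

import numpy as np
from scipy.special import ndtr

from ._rng import substream
from .breed import BreedState, mean_in_environment, sample_phenotypes
from .environment import (
    AtomDistribution,
    Environment,
    GaussianDistribution,
    Niche,
)
from .merit import (
    MeritParams,
    easygoing_cost,
    product_quality,
    profit_merit,
    total_merit,
)

__all__ = [
    "AdaptednessEstimate",
    "expected_abs_dev",
    "expected_total_merit",
    "adaptedness_env",
    "adaptedness_niche",
]

_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)


@dataclass(frozen=True)
class AdaptednessEstimate:
    value: float
    se: float
    method: str  # "closed_form" | "monte_carlo"
    n: int

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be >= 0")
        if self.method not in ("closed_form", "monte_carlo"):
            raise ValueError(f"unknown method tag {self.method!r}")
        if (self.method == "closed_form") != (self.se == 0.0):
            raise ValueError("SE must be 0 exactly for closed_form estimates")


def expected_abs_dev(m, s, c):
    """E|Y - c| for Y ~ Normal(m, s^2); the folded-normal mean.

    Vectorized over broadcastable arguments.  With delta = m - c,

        E|Y - c| = s sqrt(2/pi) exp(-delta^2 / 2 s^2)
                   + delta (2 Phi(delta / s) - 1),

    reducing to |m - c| at s = 0 and to s sqrt(2/pi) at m = c.
    """
    m = np.asarray(m, dtype=float)
    s = np.asarray(s, dtype=float)
    c = np.asarray(c, dtype=float)
    if np.any(s < 0):
        raise ValueError("s must be >= 0")
    delta = m - c
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(s > 0, delta / np.where(s > 0, s, 1.0), 0.0)
        z = np.clip(z, -40.0, 40.0)  # exp/Phi saturate well before this
        smooth = s * _SQRT_2_OVER_PI * np.exp(-0.5 * z * z) + delta * (
            2.0 * ndtr(z) - 1.0
        )
    out = np.where(s > 0, smooth, np.abs(delta))
    return float(out) if out.ndim == 0 else out


def expected_total_merit(
    mu: np.ndarray, sd: np.ndarray, e: Environment, params: MeritParams
) -> float:
    """Closed-form E TM_e(y) for y ~ N(mu, P) with marginal SDs ``sd``.

    Only the marginal SDs enter: profit, product quality and the easygoing
    cost are linear (expectation passes through the mean) and the reward
    kernels are sums of per-trait folded-normal means.
    """
    lam = params.weights.lambda_
    val = profit_merit(mu, e.influencing, params)
    if lam == 0.0:
        return float(val)
    w1, w2, w3 = params.weights.w
    reward = 0.0
    for w, block in (
        (w1, params.performance),
        (w2, params.emotional),
        (w3, params.altruistic),
    ):
        if w == 0.0:
            continue
        r = block.tau_max
        for lab, om in block.omega.items():
            k = params.index(lab)
            r -= om * expected_abs_dev(mu[k], sd[k], block.opt[lab])
        reward += w * r
    return float(val + lam * (reward - easygoing_cost(mu, params)))


def adaptedness_env(
    state: BreedState,
    e: Environment,
    niche: Niche,
    params: MeritParams,
    method: str = "closed_form",
    n: int = 10_000,
    seed: int = 0,
) -> AdaptednessEstimate:
    """Adaptedness a(mu_b, e): expected role-weighted merit in environment e.

    The producer term uses the niche's producer environment e_p for both the
    profit coefficients and the (possibly reaction-norm shifted) trait means.
    """
    ap, an, ac = params.weights.alpha
    if method == "closed_form":
        sd = np.sqrt(np.diag(state.genetics.P))
        val = 0.0
        if ap != 0.0:
            mu_p = mean_in_environment(state, niche.producer_env)
            val += ap * expected_total_merit(mu_p, sd, niche.producer_env, params)
        mu = mean_in_environment(state, e)
        if an != 0.0:
            val += an * expected_total_merit(mu, sd, e, params)
        if ac != 0.0:
            val += ac * float(product_quality(mu, params))
        return AdaptednessEstimate(value=val, se=0.0, method="closed_form", n=0)
    if method != "monte_carlo":
        raise ValueError(f"unknown method {method!r}")
    if n < 2:
        raise ValueError("monte_carlo requires n >= 2")
    y = sample_phenotypes(state, e, n, seed).values
    contrib = np.zeros(n)
    if ap != 0.0:
        # independent substream for producer-environment draws
        yp = sample_phenotypes(state, niche.producer_env, n, seed + 1_000_003).values
        contrib += ap * total_merit(yp, niche.producer_env, params)
    if an != 0.0:
        contrib += an * total_merit(y, e, params)
    if ac != 0.0:
        contrib += ac * product_quality(y, params)
    value = float(contrib.mean())
    se = float(contrib.std(ddof=1) / math.sqrt(n))
    return AdaptednessEstimate(value=value, se=se, method="monte_carlo", n=n)


def adaptedness_niche(
    state: BreedState,
    niche: Niche,
    params_by_subniche: Mapping[str, MeritParams],
    method: str = "closed_form",
    n_env: int = 200,
    n_pheno: int = 10_000,
    seed: int = 0,
) -> AdaptednessEstimate:
    """Adaptedness a_t(mu_b, E_b): size-weighted niche average of a(mu_b, e).

    Atom subniches are averaged exactly over their atoms; Gaussian subniches
    are averaged over ``n_env`` sampled environments (their contribution is
    Monte Carlo even when the per-environment evaluation is closed form).
    """
    for sub in niche.subniches:
        if sub.label not in params_by_subniche:
            raise KeyError(f"no merit parameters bound for subniche {sub.label!r}")
    weights = niche.weights
    value = 0.0
    var = 0.0
    n_used = 0
    any_mc = False
    for w, sub in zip(weights, niche.subniches):
        if w == 0.0:
            continue
        params = params_by_subniche[sub.label]
        sub_seed = int(substream(seed, f"subniche:{sub.label}").integers(2**31))
        if isinstance(sub.distribution, AtomDistribution):
            sub_val = 0.0
            sub_var = 0.0
            for i, (env, p) in enumerate(sub.distribution.atoms):
                est = adaptedness_env(
                    state, env, niche, params, method=method,
                    n=n_pheno, seed=sub_seed + i,
                )
                sub_val += p * est.value
                sub_var += (p * est.se) ** 2
                n_used += est.n
                any_mc = any_mc or est.method == "monte_carlo"
        elif isinstance(sub.distribution, GaussianDistribution):
            any_mc = True
            rng = substream(seed, f"subniche-env:{sub.label}")
            envs = sub.distribution.sample(rng, n_env)
            vals = np.empty(n_env)
            ses = np.empty(n_env)
            for i, env in enumerate(envs):
                est = adaptedness_env(
                    state, env, niche, params, method=method,
                    n=n_pheno, seed=sub_seed + i,
                )
                vals[i] = est.value
                ses[i] = est.se
                n_used += est.n
            n_used += n_env
            sub_val = float(vals.mean())
            env_var = float(vals.var(ddof=1)) / n_env if n_env > 1 else 0.0
            sub_var = env_var + float((ses**2).mean()) / n_env
        else:  # pragma: no cover - distribution types are closed
            raise TypeError(f"unknown distribution type for {sub.label!r}")
        value += w * sub_val
        var += w * w * sub_var
    if any_mc:
        return AdaptednessEstimate(
            value=value, se=math.sqrt(var), method="monte_carlo", n=max(n_used, 2)
        )
    return AdaptednessEstimate(value=value, se=0.0, method="closed_form", n=0)


def _compile_group(
    state: BreedState,
    envs: list[Environment],
    wts: np.ndarray,
    params: MeritParams,
    producer_env: Environment,
    sd: np.ndarray,
) -> Callable[[np.ndarray], float]:
    """Precompile the wt-weighted sum of a(mu, e) over a batch of environments.

    All environments in the batch share one MeritParams (one subniche), so
    the reward-block structure is common and everything vectorizes across
    environments: only the profit coefficients and reaction-norm shifts
    vary per environment.
    """
    from .merit import profit_coefficients

    K = len(params.trait_labels)
    n = len(envs)
    ap, an, ac = params.weights.alpha
    lam = params.weights.lambda_

    def env_arrays(env_list: list[Environment]) -> tuple[np.ndarray, ...]:
        shifts = np.zeros((len(env_list), K))
        C = np.zeros((len(env_list), K))
        fixed = np.zeros(len(env_list))
        for i, env in enumerate(env_list):
            if state.reaction_norm is not None:
                shifts[i] = state.reaction_norm.shift(env)
            C[i], fixed[i] = profit_coefficients(params, env.influencing)
        return shifts, C, fixed

    shifts, C, fixed = env_arrays(envs)
    pshift, pC, pfixed = env_arrays([producer_env])

    blocks = []
    easy = np.zeros(K)
    if lam != 0.0:
        for w, block in zip(params.weights.w,
                            (params.performance, params.emotional,
                             params.altruistic)):
            if w == 0.0 or not block.omega:
                blocks.append((w, block.tau_max, None, None, None, None))
                continue
            idx = np.array([params.index(t) for t in block.omega], dtype=int)
            om = np.array([block.omega[t] for t in block.omega])
            op = np.array([block.opt[t] for t in block.omega])
            blocks.append((w, block.tau_max, idx, om, op, sd[idx]))
        for lab in params.easygoing.included_traits():
            easy[params.index(lab)] = (
                params.easygoing.omega[lab]
                - params.easygoing.omega_mon.get(lab, 0.0)
            )
    q = np.zeros(K)
    for lab, coef in params.quality.coef.items():
        q[params.index(lab)] = coef
    q0 = params.quality.q0
    wsum = float(wts.sum())

    def etm_batch(M: np.ndarray, Cb: np.ndarray, fb: np.ndarray) -> np.ndarray:
        # M: (m, K) means per environment
        val = np.einsum("ij,ij->i", M, Cb) + fb
        if lam == 0.0:
            return val
        reward = np.zeros(M.shape[0])
        for w, tau, idx, om, op, s in blocks:
            if idx is None:
                reward += w * tau
                continue
            dev = expected_abs_dev(M[:, idx], s[None, :], op[None, :])
            reward += w * (tau - dev @ om)
        return val + lam * (reward - M @ easy)

    def value(mu: np.ndarray) -> float:
        total = 0.0
        if an != 0.0:
            M = mu[None, :] + shifts
            total += an * float(wts @ etm_batch(M, C, fixed))
        if ap != 0.0:
            Mp = mu[None, :] + pshift
            total += ap * wsum * float(etm_batch(Mp, pC, pfixed)[0])
        if ac != 0.0:
            M = mu[None, :] + shifts
            total += ac * float(wts @ (M @ q + q0))
        return total

    return value


def niche_objective(
    state: BreedState,
    niche: Niche,
    params_by_subniche: Mapping[str, MeritParams],
    n_env: int = 200,
    seed: int = 0,
) -> Callable[[np.ndarray], float]:
    """Deterministic closed-form niche-adaptedness objective mu -> a(mu).

    Gaussian-subniche environments are sampled once (common random numbers)
    so the returned function is deterministic and suitable for optimization.
    Under the constant-mean model the objective is concave in mu.  The
    per-environment expectations are precompiled to array form; the result
    agrees with :func:`adaptedness_niche` in closed-form mode.
    """
    weights = niche.weights
    sd = np.sqrt(np.diag(state.genetics.P))
    groups: list[Callable[[np.ndarray], float]] = []
    for w, sub in zip(weights, niche.subniches):
        if w == 0.0:
            continue
        params = params_by_subniche[sub.label]
        if isinstance(sub.distribution, AtomDistribution):
            envs = [env for env, p in sub.distribution.atoms if p > 0]
            wts = np.array([w * p for _, p in sub.distribution.atoms if p > 0])
        else:
            rng = substream(seed, f"subniche-env:{sub.label}")
            envs = sub.distribution.sample(rng, n_env)
            wts = np.full(n_env, w / n_env)
        groups.append(
            _compile_group(state, envs, wts, params, niche.producer_env, sd)
        )

    def objective(mu: np.ndarray) -> float:
        mu = np.asarray(mu, dtype=float)
        return sum(g(mu) for g in groups)

    return objective
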