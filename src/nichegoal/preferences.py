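"""Stated-preference estimation of merit-function parameters.

Merit parameters are identified from binary forced-choice experiments: a
respondent sees two animal trait profiles drawn uniformly from the search
area and picks one; the choice probability follows a conditional logit on
the total-merit difference,

    P(choose A) = logistic((TM_e(y_A) - TM_e(y_B)) / scale).

Because choices depend only on merit *differences*, additive constants
(tau_max) and the common scale are not identifiable; tau_max is therefore
fixed, and omega estimates are reported on the scale implied by the known
``scale`` parameter of the design.

Fitting: for a reward block tau_max - sum_k omega_k |y_k - Opt_k| the
likelihood is convex in omega for fixed Opt (the |y - Opt| features enter
linearly) but nonsmooth in Opt.  The maximizer is found by profile
likelihood: an inner quasi-Newton logit fit for omega nested in an outer
Nelder-Mead search over Opt.  Standard errors come from the observed
information (numerical Hessian of the joint log-likelihood at the optimum).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from ._rng import substream
from .environment import Environment
from .merit import (
    AbsDevReward,
    MeritParams,
    product_quality,
    total_merit,
)

__all__ = [
    "ChoiceDataset",
    "FitStructure",
    "MeritFitResult",
    "AlphaFitResult",
    "simulate_choice_experiment",
    "fit_merit_params",
    "fit_alpha_weights",
    "willingness_to_pay",
]


@dataclass(frozen=True)
class ChoiceDataset:
    """Binary choice tasks: columns respondent, A_<trait>, B_<trait>, chosen."""

    table: pd.DataFrame
    traits: tuple[str, ...]
    box: Mapping[str, tuple[float, float]]
    seed: int
    scale: float
    true_tag: str | None = None

    def __post_init__(self) -> None:
        cols = set(self.table.columns)
        for t in self.traits:
            for side in ("A", "B"):
                if f"{side}_{t}" not in cols:
                    raise ValueError(f"dataset missing column {side}_{t}")
        if "chosen" not in cols:
            raise ValueError("dataset missing 'chosen' column")
        if not set(self.table["chosen"].unique()) <= {"A", "B"}:
            raise ValueError("'chosen' must be 'A' or 'B' in every row")

    def profiles(self, side: str, traits: Sequence[str] | None = None) -> np.ndarray:
        traits = tuple(traits) if traits is not None else self.traits
        return self.table[[f"{side}_{t}" for t in traits]].to_numpy(dtype=float)

    @property
    def n(self) -> int:
        return len(self.table)


def _weighted_traits(params: MeritParams) -> set[str]:
    out = set(params.quality.coef) | set(params.profit.base) | set(
        params.profit.multipliers
    )
    for block in (params.performance, params.emotional, params.altruistic):
        out |= {t for t, w in block.omega.items() if w > 0}
    out |= set(params.easygoing.omega)
    return out


def simulate_choice_experiment(
    params: MeritParams,
    e: Environment,
    box: Mapping[str, tuple[float, float]],
    n: int,
    scale: float,
    seed: int,
    utility: str = "total_merit",
    producer_env: Environment | None = None,
    true_tag: str | None = None,
) -> ChoiceDataset:
    """Simulate ``n`` binary choice tasks with logistic choice probabilities.

    Profiles are drawn uniformly in the per-trait ``box`` (the search area).
    ``utility`` selects the latent utility: the owner's total merit
    (default) or the role-weighted ``"adaptedness"`` combination
    alpha_p TM_ep + alpha_n TM_e + alpha_c PQ, used for estimating the
    alpha weights.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if scale <= 0:
        raise ValueError("scale must be > 0")
    traits = params.trait_labels
    missing = set(traits) - set(box)
    if missing:
        raise ValueError(f"box missing traits: {sorted(missing)}")
    lo = np.array([box[t][0] for t in traits], dtype=float)
    hi = np.array([box[t][1] for t in traits], dtype=float)
    weighted = _weighted_traits(params)
    for t, a, b in zip(traits, lo, hi):
        if b < a:
            raise ValueError(f"box interval inverted for trait {t!r}")
        if b == a and t in weighted:
            raise ValueError(
                f"degenerate design: zero-width box for weighted trait {t!r}"
            )
    rng = substream(seed, "choice-experiment")
    yA = rng.uniform(lo, hi, size=(n, len(traits)))
    yB = rng.uniform(lo, hi, size=(n, len(traits)))

    def _utility(y: np.ndarray) -> np.ndarray:
        if utility == "total_merit":
            return np.asarray(total_merit(y, e, params), dtype=float)
        if utility == "adaptedness":
            if producer_env is None:
                raise ValueError("adaptedness utility requires producer_env")
            ap, an, ac = params.weights.alpha
            return (
                ap * np.asarray(total_merit(y, producer_env, params), float)
                + an * np.asarray(total_merit(y, e, params), float)
                + ac * np.asarray(product_quality(y, params), float)
            )
        raise ValueError(f"unknown utility {utility!r}")

    p_a = expit((_utility(yA) - _utility(yB)) / scale)
    chosen = np.where(rng.uniform(size=n) < p_a, "A", "B")
    data = {"respondent": np.arange(n)}
    for j, t in enumerate(traits):
        data[f"A_{t}"] = yA[:, j]
    for j, t in enumerate(traits):
        data[f"B_{t}"] = yB[:, j]
    data["chosen"] = chosen
    return ChoiceDataset(
        table=pd.DataFrame(data),
        traits=tuple(traits),
        box={t: (float(box[t][0]), float(box[t][1])) for t in traits},
        seed=seed,
        scale=float(scale),
        true_tag=true_tag,
    )


@dataclass(frozen=True)
class FitStructure:
    """Which parameters of which reward block are free in the fit."""

    block: str  # "performance" | "emotional" | "altruistic"
    traits: tuple[str, ...]
    fit_opt: bool = True
    opt_fixed: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.block not in ("performance", "emotional", "altruistic"):
            raise ValueError(f"unknown merit block {self.block!r}")
        if not self.traits:
            raise ValueError("at least one free trait required")
        if not self.fit_opt:
            missing = set(self.traits) - set(self.opt_fixed)
            if missing:
                raise ValueError(f"opt_fixed missing traits: {sorted(missing)}")


@dataclass(frozen=True)
class MeritFitResult:
    omega: dict[str, float]
    opt: dict[str, float]
    se_omega: dict[str, float] | None
    se_opt: dict[str, float] | None
    loglik: float
    converged: bool
    separation: bool
    n_outer_iter: int
    params: MeritParams | None = None


def _choice_loglik(u: np.ndarray, chose_a: np.ndarray) -> float:
    s = np.where(chose_a, 1.0, -1.0)
    return float(-np.sum(np.logaddexp(0.0, -s * u)))


def _fit_omega_given_opt(
    yA: np.ndarray, yB: np.ndarray, chose_a: np.ndarray,
    opt: np.ndarray, scale: float, w0: np.ndarray,
) -> tuple[np.ndarray, float, bool]:
    """Convex inner logit fit: maximize the likelihood over omega."""
    X = (np.abs(yB - opt) - np.abs(yA - opt)) / scale

    def negll(w: np.ndarray) -> float:
        return -_choice_loglik(X @ w, chose_a)

    def grad(w: np.ndarray) -> np.ndarray:
        p = expit(X @ w)
        return -X.T @ (chose_a.astype(float) - p)

    res = minimize(negll, w0, jac=grad, method="BFGS",
                   options={"gtol": 1e-8, "maxiter": 500})
    # BFGS may stop on precision loss with the optimum found; judge
    # convergence by the gradient norm relative to the sample size
    ok = bool(res.success) or float(
        np.linalg.norm(grad(res.x))
    ) < 1e-4 * math.sqrt(len(chose_a))
    return res.x, -res.fun, ok


def _numerical_hessian(f, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    p = len(x)
    H = np.empty((p, p))
    h = step * np.maximum(1.0, np.abs(x))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def fit_merit_params(
    data: ChoiceDataset,
    structure: FitStructure,
    base_params: MeritParams | None = None,
    init: Mapping[str, float] | None = None,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> MeritFitResult:
    """Maximum-likelihood estimates of (omega, Opt) from binary choices.

    omega enters the logit linearly through |y - Opt| features (inner convex
    fit); Opt is profiled out by a derivative-free Nelder-Mead search.
    Perfect separation is flagged rather than raised; SEs are then
    unavailable.  tau_max is not identifiable from choice differences and is
    never estimated.
    """
    if data.n == 0:
        raise ValueError("choice dataset is empty")
    traits = structure.traits
    yA = data.profiles("A", traits)
    yB = data.profiles("B", traits)
    chose_a = (data.table["chosen"] == "A").to_numpy()
    scale = data.scale
    k = len(traits)
    w0 = np.full(k, 0.5)

    centers = np.array(
        [0.5 * (data.box[t][0] + data.box[t][1]) for t in traits], dtype=float
    )
    if init is not None:
        centers = np.array([init.get(t, c) for t, c in zip(traits, centers)])

    n_outer = 0
    if structure.fit_opt:
        def profile_negll(opt: np.ndarray) -> float:
            _, ll, _ = _fit_omega_given_opt(yA, yB, chose_a, opt, scale, w0)
            return -ll

        widths = np.array(
            [data.box[t][1] - data.box[t][0] for t in traits], dtype=float
        )
        res = minimize(
            profile_negll, centers, method="Nelder-Mead",
            options={
                "xatol": tol * max(1.0, float(widths.max())),
                "fatol": tol,
                "maxiter": max_iter * max(1, k),
                "initial_simplex": None,
            },
        )
        opt_hat = res.x
        n_outer = int(res.nit)
        outer_ok = bool(res.success)
    else:
        opt_hat = np.array([structure.opt_fixed[t] for t in traits], dtype=float)
        outer_ok = True

    omega_hat, ll, inner_ok = _fit_omega_given_opt(
        yA, yB, chose_a, opt_hat, scale, w0
    )

    # separation heuristic: unbounded coefficients or perfect prediction
    X = (np.abs(yB - opt_hat) - np.abs(yA - opt_hat)) / scale
    p_hat = expit(X @ omega_hat)
    predicted = p_hat > 0.5
    separation = bool(
        np.all(predicted == chose_a)
        and np.all(np.abs(np.where(chose_a, p_hat, 1 - p_hat) - 1.0) < 1e-6)
    ) or bool(np.abs(omega_hat).max() > 1e4)

    se_omega = se_opt = None
    if not separation:
        if structure.fit_opt:
            def joint_ll(theta: np.ndarray) -> float:
                w = theta[:k]
                o = theta[k:]
                Xo = (np.abs(yB - o) - np.abs(yA - o)) / scale
                return _choice_loglik(Xo @ w, chose_a)
            theta = np.concatenate([omega_hat, opt_hat])
        else:
            def joint_ll(theta: np.ndarray) -> float:
                return _choice_loglik(X @ theta, chose_a)
            theta = omega_hat
        H = _numerical_hessian(joint_ll, theta)
        try:
            cov = np.linalg.inv(-H)
            diag = np.diag(cov)
            if np.all(diag > 0):
                ses = np.sqrt(diag)
                se_omega = {t: float(ses[i]) for i, t in enumerate(traits)}
                if structure.fit_opt:
                    se_opt = {t: float(ses[k + i]) for i, t in enumerate(traits)}
        except np.linalg.LinAlgError:
            pass

    fitted_params = None
    if base_params is not None:
        old_block: AbsDevReward = getattr(base_params, structure.block)
        new_block = AbsDevReward(
            omega={**dict(old_block.omega),
                   **{t: float(max(w, 0.0)) for t, w in zip(traits, omega_hat)}},
            opt={**dict(old_block.opt),
                 **{t: float(o) for t, o in zip(traits, opt_hat)}},
            tau_max=old_block.tau_max,
        )
        fitted_params = replace(base_params, **{structure.block: new_block})

    return MeritFitResult(
        omega={t: float(w) for t, w in zip(traits, omega_hat)},
        opt={t: float(o) for t, o in zip(traits, opt_hat)},
        se_omega=se_omega,
        se_opt=se_opt,
        loglik=float(ll),
        converged=bool(inner_ok and outer_ok and not separation),
        separation=separation,
        n_outer_iter=n_outer,
        params=fitted_params,
    )


@dataclass(frozen=True)
class AlphaFitResult:
    alpha: tuple[float, float, float]
    identifiable: bool
    loglik: float
    raw_coef: tuple[float, float, float]


def fit_alpha_weights(
    datasets: ChoiceDataset | Sequence[ChoiceDataset],
    params: MeritParams,
    e: Environment,
    producer_env: Environment,
    tol: float = 1e-9,
) -> AlphaFitResult:
    """Estimate the role weights (alpha_p, alpha_n, alpha_c) from choices.

    The three component merits TM_ep, TM_e and PQ of each profile are the
    utility features of a binary logit; the fitted coefficients are
    projected onto the simplex by clipping negatives to zero and
    renormalizing to sum 1.  Collinear component merits are flagged as
    non-identifiable.
    """
    if isinstance(datasets, ChoiceDataset):
        datasets = [datasets]
    if not datasets:
        raise ValueError("no datasets supplied")
    feats = []
    chose = []
    scale = datasets[0].scale
    for ds in datasets:
        yA = ds.profiles("A", params.trait_labels)
        yB = ds.profiles("B", params.trait_labels)

        def comps(y: np.ndarray) -> np.ndarray:
            return np.column_stack([
                np.asarray(total_merit(y, producer_env, params), float),
                np.asarray(total_merit(y, e, params), float),
                np.asarray(product_quality(y, params), float),
            ])

        feats.append((comps(yA) - comps(yB)) / ds.scale)
        chose.append((ds.table["chosen"] == "A").to_numpy())
    X = np.vstack(feats)
    chose_a = np.concatenate(chose)

    sv = np.linalg.svd(X, compute_uv=False)
    identifiable = bool(sv[0] > 0 and sv[-1] / sv[0] > 1e-8)

    def negll(b: np.ndarray) -> float:
        return -_choice_loglik(X @ b, chose_a)

    def grad(b: np.ndarray) -> np.ndarray:
        p = expit(X @ b)
        return -X.T @ (chose_a.astype(float) - p)

    res = minimize(negll, np.full(3, 0.3), jac=grad, method="BFGS",
                   options={"gtol": max(tol, 1e-10), "maxiter": 500})
    raw = res.x
    clipped = np.clip(raw, 0.0, None)
    total = clipped.sum()
    if total <= 0:
        identifiable = False
        alpha = (0.0, 0.0, 0.0)
    else:
        a = clipped / total
        alpha = (float(a[0]), float(a[1]), float(a[2]))
    return AlphaFitResult(
        alpha=alpha,
        identifiable=identifiable,
        loglik=float(-res.fun),
        raw_coef=(float(raw[0]), float(raw[1]), float(raw[2])),
    )


def willingness_to_pay(omega: float, money_coefficient: float) -> float:
    """Price an owner would pay per unit trait improvement: omega / money coef."""
    if money_coefficient == 0:
        raise ValueError("money coefficient must be nonzero")
    return omega / money_coefficient
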