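"""Merit functions and the total merit of an animal.

Each desire category contributes one merit function:

* profit: a linear profit equation phi_v(y) = fixed(v) + sum_k c_k(v) y_k,
  where each coefficient may depend linearly on named influencing variables
  (e.g. the milk-yield coefficient on the milk price);
* performance / emotional / altruistic rewards: tau_max - sum_k
  omega_k |y_k - Opt_k| over the relevant traits, maximal when the animal
  sits exactly at the owner's optima;
* easygoingness: perceived cost C(y) = sum_k (omega_k - omega_k^mon) y_k
  over traits whose perceived cost exceeds the true monetary cost;
* product quality PQ(y): a linear consumer score.

The total merit is TM_e(y) = phi_v(y) + lambda_e (R_e(y) - C_e(y)), with
R_e the w-weighted sum of the three rewards.  All functions are
label-addressed (trait order is irrelevant) and vectorized over rows of y.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .environment import Environment, InfluencingVariables

logger = logging.getLogger("nichegoal")

__all__ = [
    "LinearProfit",
    "ProductQuality",
    "AbsDevReward",
    "EasygoingCost",
    "MeritWeights",
    "MeritParams",
    "profit_merit",
    "performance_merit",
    "emotional_merit",
    "altruistic_merit",
    "easygoing_cost",
    "nonmonetary_reward",
    "total_merit",
    "product_quality",
    "monetary_trait_costs",
]

_ALPHA_TOL = 1e-12


@dataclass(frozen=True)
class LinearProfit:
    """phi_v(y) = fixed + sum_j fm_j v_j + sum_k (base_k + sum_j m_kj v_j) y_k."""

    base: Mapping[str, float] = field(default_factory=dict)
    multipliers: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    fixed: float = 0.0
    fixed_multipliers: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ProductQuality:
    """Linear consumer quality score PQ(y) = q0 + sum_k q_k y_k."""

    coef: Mapping[str, float] = field(default_factory=dict)
    q0: float = 0.0


@dataclass(frozen=True)
class AbsDevReward:
    """Reward tau_max - sum_k omega_k |y_k - Opt_k| over its traits."""

    omega: Mapping[str, float] = field(default_factory=dict)
    opt: Mapping[str, float] = field(default_factory=dict)
    tau_max: float = 0.0

    def __post_init__(self) -> None:
        for lab, w in self.omega.items():
            if w < 0:
                raise ValueError(f"omega must be >= 0: {lab} = {w}")
            if lab not in self.opt:
                raise ValueError(f"omega given without Opt for trait {lab!r}")


@dataclass(frozen=True)
class EasygoingCost:
    """Perceived minus monetary per-unit costs; traits with omega < omega_mon
    are dropped from the sum (the owner perceives no extra cost there)."""

    omega: Mapping[str, float] = field(default_factory=dict)
    omega_mon: Mapping[str, float] = field(default_factory=dict)

    def included_traits(self) -> tuple[str, ...]:
        out = []
        for lab, w in self.omega.items():
            wm = self.omega_mon.get(lab, 0.0)
            if w > wm:
                out.append(lab)
            elif w < wm:
                logger.info(
                    "easygoing cost: trait %r has perceived cost %g below "
                    "monetary cost %g; excluded from the cost sum",
                    lab, w, wm,
                )
        return tuple(out)


@dataclass(frozen=True)
class MeritWeights:
    """lambda_e, reward weights (w1, w2, w3) and role weights (a_p, a_n, a_c)."""

    lambda_: float = 1.0
    w: tuple[float, float, float] = (1.0, 1.0, 1.0)
    alpha: tuple[float, float, float] = (0.0, 1.0, 0.0)

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ValueError("lambda_e must be >= 0")
        if any(x < 0 for x in self.w):
            raise ValueError("reward weights w must be >= 0")
        if any(a < 0 for a in self.alpha):
            raise ValueError("alpha weights must be >= 0")
        if abs(sum(self.alpha) - 1.0) > _ALPHA_TOL:
            raise ValueError(
                f"alpha weights must sum to 1 (got {sum(self.alpha)!r})"
            )


@dataclass(frozen=True)
class MeritParams:
    """All merit-function parameters for one owner group (subniche)."""

    trait_labels: tuple[str, ...]
    profit: LinearProfit = field(default_factory=LinearProfit)
    quality: ProductQuality = field(default_factory=ProductQuality)
    performance: AbsDevReward = field(default_factory=AbsDevReward)
    emotional: AbsDevReward = field(default_factory=AbsDevReward)
    altruistic: AbsDevReward = field(default_factory=AbsDevReward)
    breed_id: str = ""
    easygoing: EasygoingCost = field(default_factory=EasygoingCost)
    weights: MeritWeights = field(default_factory=MeritWeights)

    def __post_init__(self) -> None:
        known = set(self.trait_labels)
        if len(known) != len(self.trait_labels):
            raise ValueError("trait labels must be unique")
        referenced = (
            set(self.profit.base)
            | set(self.profit.multipliers)
            | set(self.quality.coef)
            | set(self.performance.omega)
            | set(self.emotional.omega)
            | set(self.altruistic.omega)
            | set(self.easygoing.omega)
            | set(self.easygoing.omega_mon)
        )
        unknown = referenced - known
        if unknown:
            raise ValueError(
                f"merit parameters reference undefined traits: {sorted(unknown)}"
            )

    def index(self, label: str) -> int:
        return self.trait_labels.index(label)


def _as_rows(y: np.ndarray) -> tuple[np.ndarray, bool]:
    arr = np.asarray(y, dtype=float)
    if arr.ndim == 1:
        return arr[None, :], True
    return arr, False


def _maybe_scalar(vals: np.ndarray, squeeze: bool):
    return float(vals[0]) if squeeze else vals


def profit_coefficients(
    params: MeritParams, v: InfluencingVariables
) -> tuple[np.ndarray, float]:
    """Per-trait profit coefficients c_k(v) and the fixed term at ``v``."""
    K = len(params.trait_labels)
    c = np.zeros(K)
    for lab, base in params.profit.base.items():
        c[params.index(lab)] = base
    for lab, mults in params.profit.multipliers.items():
        k = params.index(lab)
        for var, m in mults.items():
            try:
                c[k] += m * v.value(var)
            except KeyError:
                raise KeyError(
                    f"profit coefficient for trait {lab!r} references "
                    f"influencing variable {var!r}, absent from environment"
                ) from None
    fixed = params.profit.fixed
    for var, m in params.profit.fixed_multipliers.items():
        try:
            fixed += m * v.value(var)
        except KeyError:
            raise KeyError(
                f"profit fixed term references influencing variable {var!r}, "
                "absent from environment"
            ) from None
    return c, float(fixed)


def profit_merit(y: np.ndarray, v: InfluencingVariables, params: MeritParams):
    """Monetary profit phi_v(y) of an animal with phenotype y."""
    rows, squeeze = _as_rows(y)
    c, fixed = profit_coefficients(params, v)
    return _maybe_scalar(rows @ c + fixed, squeeze)


def _absdev_reward(y: np.ndarray, block: AbsDevReward, params: MeritParams):
    rows, squeeze = _as_rows(y)
    vals = np.full(rows.shape[0], block.tau_max, dtype=float)
    for lab, w in block.omega.items():
        k = params.index(lab)
        vals -= w * np.abs(rows[:, k] - block.opt[lab])
    return _maybe_scalar(vals, squeeze)


def performance_merit(y: np.ndarray, params: MeritParams):
    """Reward for physical/mental performance, peaked at the owner's optima."""
    return _absdev_reward(y, params.performance, params)


def emotional_merit(y: np.ndarray, params: MeritParams):
    """Reward for satisfying emotional needs via pattern scores (e.g. cuteness)."""
    return _absdev_reward(y, params.emotional, params)


def altruistic_merit(y: np.ndarray, params: MeritParams):
    """Reward for adhering to the traditional breed type (may be constant 0)."""
    return _absdev_reward(y, params.altruistic, params)


def easygoing_cost(y: np.ndarray, params: MeritParams):
    """Perceived extra cost of keeping the animal, linear in y."""
    rows, squeeze = _as_rows(y)
    vals = np.zeros(rows.shape[0])
    for lab in params.easygoing.included_traits():
        k = params.index(lab)
        w = params.easygoing.omega[lab] - params.easygoing.omega_mon.get(lab, 0.0)
        vals += w * rows[:, k]
    return _maybe_scalar(vals, squeeze)


def nonmonetary_reward(y: np.ndarray, params: MeritParams):
    """R_e(y) = w1 R^Perf + w2 R^Emot + w3 R^Altr."""
    w1, w2, w3 = params.weights.w
    return (
        w1 * performance_merit(y, params)
        + w2 * emotional_merit(y, params)
        + w3 * altruistic_merit(y, params)
    )


def total_merit(y: np.ndarray, e: Environment, params: MeritParams):
    """TM_e(y) = phi_v(y) + lambda_e (R_e(y) - C_e(y))."""
    lam = params.weights.lambda_
    val = profit_merit(y, e.influencing, params)
    if lam != 0.0:
        val = val + lam * (nonmonetary_reward(y, params) - easygoing_cost(y, params))
    return val


def product_quality(y: np.ndarray, params: MeritParams):
    """Consumer product-quality score PQ(y)."""
    rows, squeeze = _as_rows(y)
    q = np.zeros(len(params.trait_labels))
    for lab, coef in params.quality.coef.items():
        q[params.index(lab)] = coef
    return _maybe_scalar(rows @ q + params.quality.q0, squeeze)


def monetary_trait_costs(
    params: MeritParams, mu: np.ndarray, v: InfluencingVariables
) -> np.ndarray:
    """Gradient of the profit function at ``mu`` (per-trait monetary values).

    For the linear profit equation this first-order Taylor coefficient is
    exactly c_k(v), independent of ``mu``; it is the natural source for the
    monetary costs omega^mon entering the easygoingness cost.
    """
    c, _ = profit_coefficients(params, v)
    return c
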