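"""Owner environments and breed niches.

An *environment* describes one prospective owner: a desire profile ``d``
(how much the owner cares about profit, performance, emotional support,
easygoingness and altruistic aims, each category holding named dimensions)
together with influencing variables ``v`` (owner traits, physical
environment, market prices, legislative conditions).  A breed's *niche* is a
probability distribution over environments, represented as a size-weighted
mixture of subniches.  Each subniche is either a finite list of environment
atoms with probabilities (questionnaire-style discrete owner types) or a
multivariate Gaussian over a declared subset of numeric dimensions with all
other dimensions fixed (continuous influencing variables such as market
prices).

Subniche sizes (numbers of owner places) evolve exponentially at a
per-subniche annual growth rate; this is the simplest dynamic consistent
with niches growing or shrinking over the planning horizon and gives the
closed-form projection used by the validity check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from ._rng import substream

__all__ = [
    "DesireProfile",
    "InfluencingVariables",
    "Environment",
    "AtomDistribution",
    "GaussianDistribution",
    "Subniche",
    "Niche",
    "sample_environments",
    "project_niche_size",
    "drop_endangered_subniches",
]

DESIRE_CATEGORIES = ("profit", "performance", "emotional", "easygoing", "altruistic")
VARIABLE_CATEGORIES = ("owner", "physical_env", "market", "legislative")

_ATOM_PROB_TOL = 1e-12


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate {what} label: {lab!r}")
        seen.add(lab)


@dataclass(frozen=True)
class DesireProfile:
    """Nonnegative importance scores for the five desire categories.

    Each category maps dimension labels to scores >= 0.  Labels are unique
    across categories so dimensions can be addressed by name alone.
    """

    profit: Mapping[str, float] = field(default_factory=dict)
    performance: Mapping[str, float] = field(default_factory=dict)
    emotional: Mapping[str, float] = field(default_factory=dict)
    easygoing: Mapping[str, float] = field(default_factory=dict)
    altruistic: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = []
        for cat in DESIRE_CATEGORIES:
            for lab, val in getattr(self, cat).items():
                if val < 0:
                    raise ValueError(
                        f"desire score must be >= 0: {cat}.{lab} = {val}"
                    )
                labels.append(lab)
        _check_unique(labels, "desire dimension")

    def as_dict(self) -> dict[str, float]:
        """Flat label -> score mapping across all categories."""
        out: dict[str, float] = {}
        for cat in DESIRE_CATEGORIES:
            out.update(getattr(self, cat))
        return out


@dataclass(frozen=True)
class InfluencingVariables:
    """Named real values in the four influencing-variable categories."""

    owner: Mapping[str, float] = field(default_factory=dict)
    physical_env: Mapping[str, float] = field(default_factory=dict)
    market: Mapping[str, float] = field(default_factory=dict)
    legislative: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = []
        for cat in VARIABLE_CATEGORIES:
            labels.extend(getattr(self, cat))
        _check_unique(labels, "influencing variable")
        for lab, val in self.market.items():
            if val < 0:
                raise ValueError(f"market price must be >= 0: {lab} = {val}")

    def as_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for cat in VARIABLE_CATEGORIES:
            out.update(getattr(self, cat))
        return out

    def value(self, label: str) -> float:
        for cat in VARIABLE_CATEGORIES:
            mapping = getattr(self, cat)
            if label in mapping:
                return float(mapping[label])
        raise KeyError(f"influencing variable not defined: {label!r}")


@dataclass(frozen=True)
class Environment:
    """One owner environment e = (d, v), immutable once constructed."""

    desires: DesireProfile
    influencing: InfluencingVariables

    def __post_init__(self) -> None:
        overlap = set(self.desires.as_dict()) & set(self.influencing.as_dict())
        if overlap:
            raise ValueError(
                f"labels shared between desires and influencing variables: {sorted(overlap)}"
            )

    def as_dict(self) -> dict[str, float]:
        out = self.desires.as_dict()
        out.update(self.influencing.as_dict())
        return out

    def value(self, label: str) -> float:
        d = self.desires.as_dict()
        if label in d:
            return float(d[label])
        return self.influencing.value(label)

    def with_values(self, values: Mapping[str, float]) -> "Environment":
        """Copy with the given dimension values replaced (label-addressed)."""
        des = {cat: dict(getattr(self.desires, cat)) for cat in DESIRE_CATEGORIES}
        infl = {
            cat: dict(getattr(self.influencing, cat)) for cat in VARIABLE_CATEGORIES
        }
        for lab, val in values.items():
            placed = False
            for cat in DESIRE_CATEGORIES:
                if lab in des[cat]:
                    des[cat][lab] = float(val)
                    placed = True
                    break
            if not placed:
                for cat in VARIABLE_CATEGORIES:
                    if lab in infl[cat]:
                        infl[cat][lab] = float(val)
                        placed = True
                        break
            if not placed:
                raise KeyError(f"dimension not present in environment: {lab!r}")
        return Environment(DesireProfile(**des), InfluencingVariables(**infl))


@dataclass(frozen=True)
class AtomDistribution:
    """Finite support distribution over environments."""

    atoms: tuple[tuple[Environment, float], ...]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("atom distribution needs at least one atom")
        probs = np.array([p for _, p in self.atoms], dtype=float)
        if np.any(probs < 0):
            raise ValueError("atom probabilities must be >= 0")
        if abs(probs.sum() - 1.0) > _ATOM_PROB_TOL:
            raise ValueError(
                f"atom probabilities must sum to 1 (got {probs.sum()!r})"
            )

    def sample(self, rng: np.random.Generator, n: int) -> list[Environment]:
        probs = np.array([p for _, p in self.atoms], dtype=float)
        probs = probs / probs.sum()
        idx = rng.choice(len(self.atoms), size=n, p=probs)
        return [self.atoms[i][0] for i in idx]


@dataclass(frozen=True)
class GaussianDistribution:
    """Gaussian over declared numeric dimensions, other dimensions fixed.

    ``labels`` name the varying dimensions of ``base``; a draw replaces those
    values with a multivariate-normal sample.  Market-price dimensions are
    truncated at zero so the influencing-variable invariant (prices >= 0)
    always holds.
    """

    base: Environment
    labels: tuple[str, ...]
    mean: tuple[float, ...]
    cov: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        m = len(self.labels)
        if len(self.mean) != m:
            raise ValueError("mean length must match number of labels")
        cov = np.asarray(self.cov, dtype=float)
        if cov.shape != (m, m):
            raise ValueError("cov must be square with side len(labels)")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("cov must be symmetric")
        eig = np.linalg.eigvalsh((cov + cov.T) / 2)
        if eig.min() < -1e-10 * max(1.0, abs(eig).max()):
            raise ValueError("cov must be positive semidefinite")
        for lab in self.labels:
            self.base.value(lab)  # raises KeyError if undeclared

    def sample(self, rng: np.random.Generator, n: int) -> list[Environment]:
        cov = np.asarray(self.cov, dtype=float)
        draws = rng.multivariate_normal(np.asarray(self.mean, float), cov, size=n)
        market = set(self.base.influencing.market)
        envs = []
        for row in draws:
            vals = {}
            for lab, v in zip(self.labels, row):
                if lab in market:
                    v = max(v, 0.0)
                vals[lab] = float(v)
            envs.append(self.base.with_values(vals))
        return envs


@dataclass(frozen=True)
class Subniche:
    """A homogeneous group of owner places within a niche."""

    label: str
    distribution: AtomDistribution | GaussianDistribution
    size: float
    growth_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ValueError(f"subniche size must be >= 0: {self.label}")

    def projected_size(self, t: float) -> float:
        """Expected number of owner places after ``t`` years."""
        return self.size * math.exp(self.growth_rate * t)


@dataclass(frozen=True)
class Niche:
    """Envisaged niche: size-weighted mixture of subniches + producer env."""

    subniches: tuple[Subniche, ...]
    producer_env: Environment

    def __post_init__(self) -> None:
        if not self.subniches:
            raise ValueError("niche needs at least one subniche")
        _check_unique([s.label for s in self.subniches], "subniche")

    @property
    def sizes(self) -> np.ndarray:
        return np.array([s.size for s in self.subniches], dtype=float)

    @property
    def weights(self) -> np.ndarray:
        """Mixture weights proportional to current subniche sizes."""
        sizes = self.sizes
        total = sizes.sum()
        if total <= 0:
            raise ValueError("empty niche: all subniche sizes are zero")
        return sizes / total

    def subniche(self, label: str) -> Subniche:
        for s in self.subniches:
            if s.label == label:
                return s
        raise KeyError(f"no subniche labelled {label!r}")


def sample_environments(niche: Niche, n: int, seed: int) -> list[Environment]:
    """Draw ``n`` i.i.d. environments from the niche mixture.

    Each draw picks a subniche with probability proportional to its current
    size, then samples from that subniche's environment distribution.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    weights = niche.weights  # raises on empty niche
    rng = substream(seed, "niche-environments")
    idx = rng.choice(len(niche.subniches), size=n, p=weights)
    out: list[Environment | None] = [None] * n
    for u, sub in enumerate(niche.subniches):
        where = np.flatnonzero(idx == u)
        if where.size == 0:
            continue
        draws = sub.distribution.sample(rng, int(where.size))
        for pos, env in zip(where, draws):
            out[pos] = env
    return out  # type: ignore[return-value]


def project_niche_size(niche: Niche, t: float) -> float:
    """Expected niche size after ``t`` years: sum of m0_u * exp(g_u * t)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return float(sum(s.projected_size(t) for s in niche.subniches))


def drop_endangered_subniches(
    niche: Niche, horizon: float, threshold: float
) -> Niche:
    """Remove subniches whose projected size at ``horizon`` is below ``threshold``.

    Operationalizes niche design: owner groups that will have all but
    disappeared by the planning horizon are excluded from the envisaged
    niche.  Order of the remaining subniches is preserved.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    kept = tuple(
        s for s in niche.subniches if s.projected_size(horizon) >= threshold
    )
    if not kept:
        raise ValueError(
            "no viable subniche: every subniche falls below the threshold at "
            "the horizon; the envisaged niche would not sustain the breed"
        )
    return replace(niche, subniches=kept)
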