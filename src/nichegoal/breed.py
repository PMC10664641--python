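"""Phenotype space, breed state and genetic parameters.

Traits live in one of six categories (production, performance,
conformation & movement, behaviour, functional, supplemental).  Phenotypes
are modelled as multivariate Gaussian with mean ``mu_b(e)`` and constant
phenotypic covariance ``P``; environment dependence of the mean is limited
to an affine reaction norm on declared physical-environment variables
(genotype-by-environment interaction on means).  The constant-mean model is
the default and is what the optimizer searches over.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._rng import substream
from .environment import Environment

__all__ = [
    "TRAIT_CATEGORIES",
    "Trait",
    "TraitSpace",
    "GeneticParameters",
    "ReactionNorm",
    "BreedState",
    "PhenotypeSample",
    "mean_in_environment",
    "sample_phenotypes",
]

TRAIT_CATEGORIES = (
    "production",
    "performance",
    "conformation_movement",
    "behaviour",
    "functional",
    "supplemental",
)


@dataclass(frozen=True)
class Trait:
    label: str
    category: str
    unit: str = ""

    def __post_init__(self) -> None:
        if self.category not in TRAIT_CATEGORIES:
            raise ValueError(
                f"unknown trait category {self.category!r} for {self.label!r}; "
                f"expected one of {TRAIT_CATEGORIES}"
            )


@dataclass(frozen=True)
class TraitSpace:
    traits: tuple[Trait, ...]

    def __post_init__(self) -> None:
        if not self.traits:
            raise ValueError("trait space needs at least one trait")
        labels = [t.label for t in self.traits]
        if len(set(labels)) != len(labels):
            raise ValueError("trait labels must be unique")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(t.label for t in self.traits)

    @property
    def K(self) -> int:
        return len(self.traits)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"trait not defined: {label!r}") from None


def _check_symmetric(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be a square matrix")
    if not np.allclose(mat, mat.T, atol=1e-8 * max(1.0, np.abs(mat).max())):
        raise ValueError(f"{name} must be symmetric")
    return (mat + mat.T) / 2


@dataclass(frozen=True)
class GeneticParameters:
    """Genetic (G) and phenotypic (P) covariance matrices, K x K.

    P must be positive definite, G positive semidefinite, and genetic
    variances cannot exceed phenotypic variances (heritability <= 1).
    """

    G: np.ndarray
    P: np.ndarray

    def __post_init__(self) -> None:
        G = _check_symmetric(self.G, "G")
        P = _check_symmetric(self.P, "P")
        if G.shape != P.shape:
            raise ValueError("G and P must have the same shape")
        try:
            np.linalg.cholesky(P)
        except np.linalg.LinAlgError:
            raise ValueError("P must be positive definite") from None
        eig = np.linalg.eigvalsh(G)
        if eig.min() < -1e-8 * max(1.0, abs(eig).max()):
            raise ValueError("G must be positive semidefinite")
        if np.any(np.diag(G) > np.diag(P) * (1 + 1e-10) + 1e-12):
            raise ValueError(
                "diag(G) must not exceed diag(P): heritabilities must be <= 1"
            )
        object.__setattr__(self, "G", G)
        object.__setattr__(self, "P", P)

    @property
    def K(self) -> int:
        return self.G.shape[0]

    @property
    def heritabilities(self) -> np.ndarray:
        return np.diag(self.G) / np.diag(self.P)


@dataclass(frozen=True)
class ReactionNorm:
    """Affine map from declared physical-environment variables to mean shifts.

    ``matrix`` is K x M: trait-mean shift per unit of each declared variable,
    applied around ``reference`` values (shift = B @ (v - v_ref)).
    """

    variables: tuple[str, ...]
    matrix: np.ndarray
    reference: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != len(self.variables):
            raise ValueError(
                "reaction-norm matrix must be K x M with M = number of variables"
            )
        object.__setattr__(self, "matrix", mat)
        if self.reference is not None and len(self.reference) != len(self.variables):
            raise ValueError("reference length must match variables")

    def shift(self, e: Environment) -> np.ndarray:
        vals = []
        for lab in self.variables:
            try:
                vals.append(e.value(lab))
            except KeyError:
                raise KeyError(
                    f"environment is missing reaction-norm variable {lab!r}"
                ) from None
        v = np.asarray(vals, dtype=float)
        if self.reference is not None:
            v = v - np.asarray(self.reference, dtype=float)
        return self.matrix @ v


@dataclass(frozen=True)
class BreedState:
    """Current state of a breed: trait means, genetics, optional goal."""

    trait_space: TraitSpace
    mu_c: np.ndarray
    genetics: GeneticParameters
    reaction_norm: ReactionNorm | None = None
    current_goal: np.ndarray | None = None

    def __post_init__(self) -> None:
        K = self.trait_space.K
        mu = np.asarray(self.mu_c, dtype=float)
        if mu.shape != (K,):
            raise ValueError(f"mu_c must have length K={K}")
        object.__setattr__(self, "mu_c", mu)
        if self.genetics.K != K:
            raise ValueError("genetics dimension must match trait space")
        if self.reaction_norm is not None and self.reaction_norm.matrix.shape[0] != K:
            raise ValueError("reaction-norm matrix must have K rows")
        if self.current_goal is not None:
            goal = np.asarray(self.current_goal, dtype=float)
            if goal.shape != (K,):
                raise ValueError(f"current_goal must have length K={K}")
            object.__setattr__(self, "current_goal", goal)


@dataclass(frozen=True)
class PhenotypeSample:
    """n x K matrix of sampled trait values."""

    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[1] != len(self.labels):
            raise ValueError("values must be n x K with K = number of labels")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def mean_in_environment(state: BreedState, e: Environment) -> np.ndarray:
    """Trait means mu_b(e): current means plus the reaction-norm shift."""
    if state.reaction_norm is None:
        return state.mu_c.copy()
    return state.mu_c + state.reaction_norm.shift(e)


def sample_phenotypes(
    state: BreedState, e: Environment, n: int, seed: int
) -> PhenotypeSample:
    """Draw ``n`` i.i.d. Gaussian phenotypes with mean mu_b(e), covariance P."""
    if n < 1:
        raise ValueError("n must be >= 1")
    mean = mean_in_environment(state, e)
    rng = substream(seed, "phenotypes")
    try:
        vals = rng.multivariate_normal(
            mean, state.genetics.P, size=n, method="cholesky"
        )
    except np.linalg.LinAlgError:
        raise ValueError("P must be positive definite to sample phenotypes") from None
    return PhenotypeSample(values=vals, labels=state.trait_space.labels)
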