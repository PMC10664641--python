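"""Multi-generation simulation of the breeding program under an index.

Trait means follow the deterministic expectation of the multivariate
breeder's equation, mu_{t+1} = mu_t + i G b / sqrt(b' P b) with constant G
and P (the infinitesimal-model expectation; no finite-population noise on
means).  Niche adaptedness is recomputed every generation, and the
population size responds to the adaptedness gap against a competitor
reference level through the monotone link

    n_{t+1} = min(n_t * exp(kappa (a_t - a_ref)),  c_b * m_t+1),

capped by the breed's expected share c_b of the projected niche size.  The
validity condition requires the expected breed share of the niche and the
simulated population both to stay at or above the minimum viable
population size N_min.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .adaptedness import AdaptednessEstimate, adaptedness_niche
from .breed import BreedState
from .environment import Niche, project_niche_size
from .merit import MeritParams
from .optimize import expected_response, index_variance_check

__all__ = [
    "ValidityParams",
    "Trajectory",
    "simulate_breeding_program",
    "check_validity",
]


@dataclass(frozen=True)
class ValidityParams:
    """Inputs to the long-term viability condition of the envisaged niche."""

    c_b: float  # expected breed share of the niche, 0..1
    N_min: float  # minimum viable population size (count)
    a_ref: float  # competitor adaptedness reference (merit units)
    kappa: float  # growth-rate sensitivity per merit unit

    def __post_init__(self) -> None:
        if not 0 <= self.c_b <= 1:
            raise ValueError("c_b must be in [0, 1]")
        if self.N_min < 0:
            raise ValueError("N_min must be >= 0")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")


@dataclass(frozen=True)
class Trajectory:
    """Per-generation records, generation 0 (current state) through T."""

    table: pd.DataFrame
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        required = {"generation", "adaptedness", "adaptedness_se",
                    "pop_size", "index_var", "valid"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"trajectory missing columns: {sorted(missing)}")

    @property
    def T(self) -> int:
        return len(self.table) - 1

    def means(self, t: int) -> np.ndarray:
        row = self.table.iloc[t]
        return np.array([row[lab] for lab in self.labels], dtype=float)


def check_validity(
    validity: ValidityParams, niche: Niche, t: float
) -> tuple[bool, float]:
    """Condition (i): c_b * m_t(E_b) >= N_min; returns (valid, signed margin)."""
    expected = validity.c_b * project_niche_size(niche, t)
    margin = expected - validity.N_min
    return margin >= 0, margin


def simulate_breeding_program(
    state: BreedState,
    b: np.ndarray,
    intensity: float,
    T: int,
    niche: Niche,
    params_by_subniche: dict[str, MeritParams],
    validity: ValidityParams,
    n0: float,
    seed: int = 0,
    method: str = "closed_form",
    years_per_generation: float = 1.0,
    n_env: int = 200,
    n_pheno: int = 10_000,
    goal_mu: np.ndarray | None = None,
) -> Trajectory:
    """Run the breeding program T generations under index weights ``b``.

    Means move deterministically by the expected per-generation response;
    adaptedness, population size, index genetic variance and the validity
    flag are recorded each generation.  When ``goal_mu`` is given the
    program stops selecting once the goal is reached: the last step toward
    it is shortened so the means never overshoot an interior optimum (with
    the goal exactly at radius T*i the recursion is unchanged and the final
    means coincide with the goal).  Adaptedness uses the same seed each
    generation (common random numbers) so generations are exactly
    comparable.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if n0 <= 0:
        raise ValueError("n0 must be > 0")
    delta = expected_response(state.genetics, b, intensity)
    rows = []
    mu = state.mu_c.copy()
    cap0 = validity.c_b * project_niche_size(niche, 0.0)
    n = min(float(n0), cap0)
    idx_var, _ = index_variance_check(state.genetics, b)
    for t in range(T + 1):
        years = t * years_per_generation
        st = dataclasses.replace(state, mu_c=mu.copy())
        est: AdaptednessEstimate = adaptedness_niche(
            st, niche, params_by_subniche, method=method,
            n_env=n_env, n_pheno=n_pheno, seed=seed,
        )
        niche_ok, margin = check_validity(validity, niche, years)
        valid = bool(niche_ok and n >= validity.N_min)
        row = {"generation": t}
        for lab, m in zip(state.trait_space.labels, mu):
            row[lab] = float(m)
        row.update({
            "adaptedness": est.value,
            "adaptedness_se": est.se,
            "pop_size": float(n),
            "niche_margin": float(margin),
            "index_var": float(idx_var),
            "valid": valid,
        })
        rows.append(row)
        if t < T:
            step = delta
            if goal_mu is not None:
                remaining = np.asarray(goal_mu, float) - mu
                dn = float(np.linalg.norm(delta))
                scale = float(remaining @ delta) / dn**2 if dn > 0 else 0.0
                step = delta * min(max(scale, 0.0), 1.0)
            mu = mu + step
            growth = math.exp(validity.kappa * (est.value - validity.a_ref))
            cap = validity.c_b * project_niche_size(
                niche, (t + 1) * years_per_generation
            )
            n = min(n * growth, cap)
    return Trajectory(
        table=pd.DataFrame(rows), labels=state.trait_space.labels
    )
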