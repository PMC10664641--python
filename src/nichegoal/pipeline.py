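"""High-level pipeline stages over a Scenario.

Thin orchestration used by the command-line interface, the test-suite
smoke checks and the reproduction script: each function takes a Scenario
plus a seed and runs one stage of the workflow (choice simulation,
preference fitting, adaptedness evaluation, goal optimization, index
derivation, breeding-program simulation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .adaptedness import adaptedness_niche, niche_objective
from .environment import AtomDistribution
from .optimize import GoalResult, optimize_goal
from .preferences import (
    AlphaFitResult,
    ChoiceDataset,
    FitStructure,
    MeritFitResult,
    fit_merit_params,
    simulate_choice_experiment,
)
from .scenarios import Scenario
from .simulate import Trajectory, simulate_breeding_program

__all__ = [
    "representative_environment",
    "simulate_scenario_choices",
    "fit_scenario_preferences",
    "evaluate_adaptedness",
    "optimize_scenario_goal",
    "run_breeding_program",
]


def representative_environment(sc: Scenario, subniche: str):
    """A deterministic representative environment of a subniche.

    First atom for finite distributions; the Gaussian base environment at
    its mean for continuous ones.
    """
    sub = sc.niche.subniche(subniche)
    dist = sub.distribution
    if isinstance(dist, AtomDistribution):
        return dist.atoms[0][0]
    vals = dict(zip(dist.labels, dist.mean))
    return dist.base.with_values(vals)


def _choice_box(sc: Scenario) -> dict[str, tuple[float, float]]:
    from .optimize import default_search_box

    return default_search_box(
        sc.state.trait_space.labels, sc.state.mu_c,
        sc.state.genetics.P, sc.settings.search_k_sd,
    )


def focused_params(params, block: str):
    """Merit parameters for a single-block choice experiment.

    Choice experiments can only identify a limited number of attributes at
    a time, so each merit function is estimated in its own experiment: the
    focal reward block is kept (at unit weight) and every other merit
    component is switched off.
    """
    from dataclasses import replace

    from .merit import EasygoingCost, LinearProfit, MeritWeights, ProductQuality

    w = tuple(1.0 if b == block else 0.0
              for b in ("performance", "emotional", "altruistic"))
    return replace(
        params,
        profit=LinearProfit(),
        quality=ProductQuality(),
        easygoing=EasygoingCost(),
        weights=MeritWeights(lambda_=1.0, w=w, alpha=params.weights.alpha),
    )


def simulate_scenario_choices(
    sc: Scenario, subniche: str, seed: int, n: int | None = None,
    block: str | None = "auto",
) -> ChoiceDataset:
    """Simulate a discrete-choice experiment for one subniche's owners.

    By default the experiment is focused on the subniche's dominant reward
    block (other merit components held out of the design), mirroring the
    practice of estimating each merit function in a separate experiment;
    pass ``block=None`` for a full total-merit experiment.
    """
    params = sc.merit_by_subniche[subniche]
    tag = f"{sc.name}:{subniche}"
    if block == "auto":
        structure = default_fit_structure(sc, subniche)
        block = structure.block if structure is not None else None
    if block is not None:
        params = focused_params(params, block)
        tag = f"{tag}:{block}"
    env = representative_environment(sc, subniche)
    return simulate_choice_experiment(
        params=params,
        e=env,
        box=_choice_box(sc),
        n=n if n is not None else sc.settings.n_choices,
        scale=sc.settings.choice_scale,
        seed=seed,
        true_tag=tag,
    )


def default_fit_structure(sc: Scenario, subniche: str) -> FitStructure | None:
    """Free parameters for the subniche's dominant reward block, if any."""
    params = sc.merit_by_subniche[subniche]
    for block in ("emotional", "performance", "altruistic"):
        omega = getattr(params, block).omega
        free = tuple(t for t, w in omega.items() if w > 0)
        if free:
            return FitStructure(block=block, traits=free)
    return None


def fit_scenario_preferences(
    sc: Scenario, subniche: str, data: ChoiceDataset
) -> MeritFitResult | None:
    structure = default_fit_structure(sc, subniche)
    if structure is None:
        return None
    return fit_merit_params(
        data, structure, base_params=sc.merit_by_subniche[subniche]
    )


def evaluate_adaptedness(
    sc: Scenario, seed: int, method: str = "closed_form"
) -> pd.DataFrame:
    """Niche adaptedness overall and per subniche, as a tidy table."""
    rows = []
    est = adaptedness_niche(
        sc.state, sc.niche, sc.merit_by_subniche, method=method,
        n_env=sc.settings.n_env, n_pheno=sc.settings.n_pheno, seed=seed,
    )
    rows.append({"scope": "niche", "method": est.method,
                 "value": est.value, "se": est.se, "n": est.n})
    import dataclasses

    for sub in sc.niche.subniches:
        single = dataclasses.replace(sc.niche, subniches=(sub,))
        est_s = adaptedness_niche(
            sc.state, single, sc.merit_by_subniche, method=method,
            n_env=sc.settings.n_env, n_pheno=sc.settings.n_pheno, seed=seed,
        )
        rows.append({"scope": f"subniche:{sub.label}", "method": est_s.method,
                     "value": est_s.value, "se": est_s.se, "n": est_s.n})
    return pd.DataFrame(rows)


def optimize_scenario_goal(sc: Scenario, seed: int) -> GoalResult:
    """Maximize the closed-form niche adaptedness over the permissible set."""
    objective = niche_objective(
        sc.state, sc.niche, sc.merit_by_subniche,
        n_env=sc.settings.n_env, seed=seed,
    )
    pset = sc.permissible_set()
    return optimize_goal(
        objective, pset,
        n_starts=sc.settings.n_starts, seed=seed,
        tol=sc.settings.tol, gen=sc.state.genetics,
    )


def run_breeding_program(
    sc: Scenario, goal: GoalResult, seed: int,
    n0: float | None = None, T: int | None = None,
) -> Trajectory:
    if goal.index_b is None:
        raise ValueError("goal result carries no index weights")
    if n0 is None:
        n0 = sc.validity.c_b * float(sum(s.size for s in sc.niche.subniches))
        n0 = max(n0, 1.0)
    return simulate_breeding_program(
        state=sc.state,
        b=goal.index_b,
        intensity=sc.settings.intensity,
        T=T if T is not None else sc.settings.generations,
        niche=sc.niche,
        params_by_subniche=sc.merit_by_subniche,
        validity=sc.validity,
        n0=n0,
        seed=seed,
        method="closed_form",
        goal_mu=goal.mu_i,
        years_per_generation=sc.settings.generation_interval_years,
        n_env=sc.settings.n_env,
        n_pheno=sc.settings.n_pheno,
    )
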