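"""Scenario (de)serialization and file I/O.

Scenarios round-trip through a strict JSON document: unknown keys are
rejected with the path into the document, label mismatches are reported
with both sides, and no scientific parameter has a silent default.  Floats
are written with ``repr`` precision so save -> load -> save is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from .breed import (
    BreedState,
    GeneticParameters,
    ReactionNorm,
    Trait,
    TraitSpace,
)
from .environment import (
    DESIRE_CATEGORIES,
    VARIABLE_CATEGORIES,
    AtomDistribution,
    DesireProfile,
    Environment,
    GaussianDistribution,
    InfluencingVariables,
    Niche,
    Subniche,
)
from .merit import (
    AbsDevReward,
    EasygoingCost,
    LinearProfit,
    MeritParams,
    MeritWeights,
    ProductQuality,
)
from .optimize import HalfspaceExclusion
from .scenarios import OptimizationSettings, Scenario
from .simulate import ValidityParams

__all__ = [
    "ConfigError",
    "scenario_to_dict",
    "scenario_from_dict",
    "save_scenario",
    "load_scenario",
    "config_hash",
    "environments_to_frame",
    "merit_table",
]


class ConfigError(ValueError):
    """A scenario document failed validation; message includes the path."""


def _require(d: Mapping[str, Any], key: str, path: str) -> Any:
    if key not in d:
        raise ConfigError(f"{path}.{key} required")
    return d[key]


def _check_keys(d: Mapping[str, Any], allowed: set[str], path: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown keys at {path}: {sorted(unknown)}")


def _floats(d: Mapping[str, Any]) -> dict[str, float]:
    return {str(k): float(v) for k, v in d.items()}


# ---------------------------------------------------------------- environment

def _desires_to_dict(d: DesireProfile) -> dict:
    return {cat: _floats(getattr(d, cat)) for cat in DESIRE_CATEGORIES
            if getattr(d, cat)}


def _desires_from_dict(d: Mapping, path: str) -> DesireProfile:
    _check_keys(d, set(DESIRE_CATEGORIES), path)
    try:
        return DesireProfile(**{cat: _floats(d.get(cat, {}))
                                for cat in DESIRE_CATEGORIES})
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from None


def _vars_to_dict(v: InfluencingVariables) -> dict:
    return {cat: _floats(getattr(v, cat)) for cat in VARIABLE_CATEGORIES
            if getattr(v, cat)}


def _vars_from_dict(d: Mapping, path: str) -> InfluencingVariables:
    _check_keys(d, set(VARIABLE_CATEGORIES), path)
    try:
        return InfluencingVariables(**{cat: _floats(d.get(cat, {}))
                                       for cat in VARIABLE_CATEGORIES})
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from None


def _env_to_dict(e: Environment) -> dict:
    return {"desires": _desires_to_dict(e.desires),
            "influencing": _vars_to_dict(e.influencing)}


def _env_from_dict(d: Mapping, path: str) -> Environment:
    _check_keys(d, {"desires", "influencing"}, path)
    return Environment(
        _desires_from_dict(_require(d, "desires", path), f"{path}.desires"),
        _vars_from_dict(_require(d, "influencing", path), f"{path}.influencing"),
    )


def _dist_to_dict(dist) -> dict:
    if isinstance(dist, AtomDistribution):
        return {"type": "atoms",
                "atoms": [{"environment": _env_to_dict(env), "prob": p}
                          for env, p in dist.atoms]}
    return {"type": "gaussian",
            "base": _env_to_dict(dist.base),
            "labels": list(dist.labels),
            "mean": list(dist.mean),
            "cov": [list(row) for row in dist.cov]}


def _dist_from_dict(d: Mapping, path: str):
    kind = _require(d, "type", path)
    if kind == "atoms":
        _check_keys(d, {"type", "atoms"}, path)
        atoms = []
        for i, a in enumerate(_require(d, "atoms", path)):
            _check_keys(a, {"environment", "prob"}, f"{path}.atoms[{i}]")
            atoms.append((
                _env_from_dict(_require(a, "environment", f"{path}.atoms[{i}]"),
                               f"{path}.atoms[{i}].environment"),
                float(_require(a, "prob", f"{path}.atoms[{i}]")),
            ))
        try:
            return AtomDistribution(tuple(atoms))
        except ValueError as exc:
            raise ConfigError(f"{path}: {exc}") from None
    if kind == "gaussian":
        _check_keys(d, {"type", "base", "labels", "mean", "cov"}, path)
        try:
            return GaussianDistribution(
                base=_env_from_dict(_require(d, "base", path), f"{path}.base"),
                labels=tuple(_require(d, "labels", path)),
                mean=tuple(float(x) for x in _require(d, "mean", path)),
                cov=tuple(tuple(float(x) for x in row)
                          for row in _require(d, "cov", path)),
            )
        except (ValueError, KeyError) as exc:
            raise ConfigError(f"{path}: {exc}") from None
    raise ConfigError(f"{path}.type must be 'atoms' or 'gaussian', got {kind!r}")


def _niche_to_dict(niche: Niche) -> dict:
    return {
        "subniches": [
            {"label": s.label, "size": s.size, "growth_rate": s.growth_rate,
             "distribution": _dist_to_dict(s.distribution)}
            for s in niche.subniches
        ],
        "producer_env": _env_to_dict(niche.producer_env),
    }


def _niche_from_dict(d: Mapping, path: str) -> Niche:
    _check_keys(d, {"subniches", "producer_env"}, path)
    subs = []
    for i, s in enumerate(_require(d, "subniches", path)):
        p = f"{path}.subniches[{i}]"
        _check_keys(s, {"label", "size", "growth_rate", "distribution"}, p)
        try:
            subs.append(Subniche(
                label=str(_require(s, "label", p)),
                size=float(_require(s, "size", p)),
                growth_rate=float(_require(s, "growth_rate", p)),
                distribution=_dist_from_dict(
                    _require(s, "distribution", p), f"{p}.distribution"),
            ))
        except ValueError as exc:
            raise ConfigError(f"{p}: {exc}") from None
    try:
        return Niche(
            subniches=tuple(subs),
            producer_env=_env_from_dict(
                _require(d, "producer_env", path), f"{path}.producer_env"),
        )
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from None


# ---------------------------------------------------------------- breed state

def _matrix_to_list(m: np.ndarray) -> list[list[float]]:
    return [[float(x) for x in row] for row in np.asarray(m)]


def _state_to_dict(state: BreedState) -> dict:
    out: dict[str, Any] = {
        "traits": [{"label": t.label, "category": t.category, "unit": t.unit}
                   for t in state.trait_space.traits],
        "mu_c": [float(x) for x in state.mu_c],
        "genetics": {"G": _matrix_to_list(state.genetics.G),
                     "P": _matrix_to_list(state.genetics.P)},
    }
    if state.reaction_norm is not None:
        rn = state.reaction_norm
        out["reaction_norm"] = {
            "variables": list(rn.variables),
            "matrix": _matrix_to_list(rn.matrix),
            "reference": list(rn.reference) if rn.reference is not None else None,
        }
    if state.current_goal is not None:
        out["current_goal"] = [float(x) for x in state.current_goal]
    return out


def _state_from_dict(d: Mapping, path: str) -> BreedState:
    _check_keys(d, {"traits", "mu_c", "genetics", "reaction_norm",
                    "current_goal"}, path)
    traits = []
    for i, t in enumerate(_require(d, "traits", path)):
        p = f"{path}.traits[{i}]"
        _check_keys(t, {"label", "category", "unit"}, p)
        try:
            traits.append(Trait(label=str(_require(t, "label", p)),
                                category=str(_require(t, "category", p)),
                                unit=str(t.get("unit", ""))))
        except ValueError as exc:
            raise ConfigError(f"{p}: {exc}") from None
    gen_d = _require(d, "genetics", path)
    _check_keys(gen_d, {"G", "P"}, f"{path}.genetics")
    try:
        genetics = GeneticParameters(
            G=np.asarray(_require(gen_d, "G", f"{path}.genetics"), float),
            P=np.asarray(_require(gen_d, "P", f"{path}.genetics"), float),
        )
    except ValueError as exc:
        raise ConfigError(f"{path}.genetics: {exc}") from None
    rn = None
    if d.get("reaction_norm") is not None:
        rd = d["reaction_norm"]
        p = f"{path}.reaction_norm"
        _check_keys(rd, {"variables", "matrix", "reference"}, p)
        try:
            rn = ReactionNorm(
                variables=tuple(_require(rd, "variables", p)),
                matrix=np.asarray(_require(rd, "matrix", p), float),
                reference=(tuple(float(x) for x in rd["reference"])
                           if rd.get("reference") is not None else None),
            )
        except ValueError as exc:
            raise ConfigError(f"{p}: {exc}") from None
    try:
        return BreedState(
            trait_space=TraitSpace(tuple(traits)),
            mu_c=np.asarray(_require(d, "mu_c", path), float),
            genetics=genetics,
            reaction_norm=rn,
            current_goal=(np.asarray(d["current_goal"], float)
                          if d.get("current_goal") is not None else None),
        )
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from None


# --------------------------------------------------------------------- merit

def _absdev_to_dict(b: AbsDevReward) -> dict:
    return {"omega": _floats(b.omega), "opt": _floats(b.opt),
            "tau_max": b.tau_max}


def _absdev_from_dict(d: Mapping, path: str) -> AbsDevReward:
    _check_keys(d, {"omega", "opt", "tau_max"}, path)
    try:
        return AbsDevReward(omega=_floats(d.get("omega", {})),
                            opt=_floats(d.get("opt", {})),
                            tau_max=float(d.get("tau_max", 0.0)))
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from None


def _merit_to_dict(m: MeritParams) -> dict:
    return {
        "trait_labels": list(m.trait_labels),
        "profit": {
            "base": _floats(m.profit.base),
            "multipliers": {k: _floats(v) for k, v in m.profit.multipliers.items()},
            "fixed": m.profit.fixed,
            "fixed_multipliers": _floats(m.profit.fixed_multipliers),
        },
        "quality": {"coef": _floats(m.quality.coef), "q0": m.quality.q0},
        "performance": _absdev_to_dict(m.performance),
        "emotional": _absdev_to_dict(m.emotional),
        "altruistic": _absdev_to_dict(m.altruistic),
        "breed_id": m.breed_id,
        "easygoing": {"omega": _floats(m.easygoing.omega),
                      "omega_mon": _floats(m.easygoing.omega_mon)},
        "weights": {"lambda": m.weights.lambda_,
                    "w": list(m.weights.w),
                    "alpha": list(m.weights.alpha)},
    }


def _merit_from_dict(d: Mapping, path: str) -> MeritParams:
    _check_keys(d, {"trait_labels", "profit", "quality", "performance",
                    "emotional", "altruistic", "breed_id", "easygoing",
                    "weights"}, path)
    prof = d.get("profit", {})
    _check_keys(prof, {"base", "multipliers", "fixed", "fixed_multipliers"},
                f"{path}.profit")
    qual = d.get("quality", {})
    _check_keys(qual, {"coef", "q0"}, f"{path}.quality")
    easy = d.get("easygoing", {})
    _check_keys(easy, {"omega", "omega_mon"}, f"{path}.easygoing")
    wts = _require(d, "weights", path)
    _check_keys(wts, {"lambda", "w", "alpha"}, f"{path}.weights")
    try:
        return MeritParams(
            trait_labels=tuple(_require(d, "trait_labels", path)),
            profit=LinearProfit(
                base=_floats(prof.get("base", {})),
                multipliers={k: _floats(v)
                             for k, v in prof.get("multipliers", {}).items()},
                fixed=float(prof.get("fixed", 0.0)),
                fixed_multipliers=_floats(prof.get("fixed_multipliers", {})),
            ),
            quality=ProductQuality(coef=_floats(qual.get("coef", {})),
                                   q0=float(qual.get("q0", 0.0))),
            performance=_absdev_from_dict(d.get("performance", {}),
                                          f"{path}.performance"),
            emotional=_absdev_from_dict(d.get("emotional", {}),
                                        f"{path}.emotional"),
            altruistic=_absdev_from_dict(d.get("altruistic", {}),
                                         f"{path}.altruistic"),
            breed_id=str(d.get("breed_id", "")),
            easygoing=EasygoingCost(omega=_floats(easy.get("omega", {})),
                                    omega_mon=_floats(easy.get("omega_mon", {}))),
            weights=MeritWeights(
                lambda_=float(_require(wts, "lambda", f"{path}.weights")),
                w=tuple(float(x) for x in _require(wts, "w", f"{path}.weights")),
                alpha=tuple(float(x)
                            for x in _require(wts, "alpha", f"{path}.weights")),
            ),
        )
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from None


# ------------------------------------------------------------------ scenario

def scenario_to_dict(sc: Scenario) -> dict:
    s = sc.settings
    return {
        "name": sc.name,
        "seed": sc.seed,
        "state": _state_to_dict(sc.state),
        "niche": _niche_to_dict(sc.niche),
        "merit_by_subniche": {lab: _merit_to_dict(m)
                              for lab, m in sc.merit_by_subniche.items()},
        "validity": {"c_b": sc.validity.c_b, "N_min": sc.validity.N_min,
                     "a_ref": sc.validity.a_ref, "kappa": sc.validity.kappa},
        "settings": {
            "horizon_years": s.horizon_years,
            "generation_interval_years": s.generation_interval_years,
            "intensity": s.intensity,
            "search_k_sd": s.search_k_sd,
            "n_starts": s.n_starts,
            "tol": s.tol,
            "n_env": s.n_env,
            "n_pheno": s.n_pheno,
            "n_choices": s.n_choices,
            "choice_scale": s.choice_scale,
        },
        "exclusions": [
            {"label": x.label, "coeffs": _floats(x.coeffs),
             "threshold": x.threshold, "direction": x.direction}
            for x in sc.exclusions
        ],
    }


def scenario_from_dict(d: Mapping) -> Scenario:
    path = "scenario"
    _check_keys(d, {"name", "seed", "state", "niche", "merit_by_subniche",
                    "validity", "settings", "exclusions"}, path)
    state = _state_from_dict(_require(d, "state", path), f"{path}.state")
    niche = _niche_from_dict(_require(d, "niche", path), f"{path}.niche")
    merit = {}
    for lab, md in _require(d, "merit_by_subniche", path).items():
        p = f"{path}.merit_by_subniche.{lab}"
        declared = tuple(_require(md, "trait_labels", p))
        if declared != state.trait_space.labels:
            raise ConfigError(
                f"{p}: trait labels {declared} do not match the trait "
                f"space {state.trait_space.labels}"
            )
        merit[lab] = _merit_from_dict(md, p)
    vd = _require(d, "validity", path)
    _check_keys(vd, {"c_b", "N_min", "a_ref", "kappa"}, f"{path}.validity")
    sd = _require(d, "settings", path)
    _check_keys(sd, {"horizon_years", "generation_interval_years", "intensity",
                     "search_k_sd", "n_starts", "tol", "n_env", "n_pheno",
                     "n_choices", "choice_scale"}, f"{path}.settings")
    exclusions = []
    for i, xd in enumerate(d.get("exclusions", [])):
        p = f"{path}.exclusions[{i}]"
        _check_keys(xd, {"label", "coeffs", "threshold", "direction"}, p)
        exclusions.append(HalfspaceExclusion(
            label=str(_require(xd, "label", p)),
            coeffs=_floats(_require(xd, "coeffs", p)),
            threshold=float(_require(xd, "threshold", p)),
            direction=str(xd.get("direction", "below")),
        ))
    try:
        return Scenario(
            name=str(_require(d, "name", path)),
            seed=int(d.get("seed", 0)),
            state=state,
            niche=niche,
            merit_by_subniche=merit,
            validity=ValidityParams(
                c_b=float(_require(vd, "c_b", f"{path}.validity")),
                N_min=float(_require(vd, "N_min", f"{path}.validity")),
                a_ref=float(_require(vd, "a_ref", f"{path}.validity")),
                kappa=float(_require(vd, "kappa", f"{path}.validity")),
            ),
            settings=OptimizationSettings(
                **{k: (int(v) if k in ("n_starts", "n_env", "n_pheno",
                                       "n_choices") else float(v))
                   for k, v in sd.items()}
            ),
            exclusions=tuple(exclusions),
        )
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from None


def _dumps(doc: dict) -> str:
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def save_scenario(sc: Scenario, path: str | Path) -> None:
    Path(path).write_text(_dumps(scenario_to_dict(sc)), encoding="utf-8")


def load_scenario(path: str | Path) -> Scenario:
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path}: not valid JSON: {exc}") from None
    return scenario_from_dict(doc)


def environments_to_frame(envs) -> "pd.DataFrame":
    """Sampled environments as a table, one row per draw, one column per dim."""
    import pandas as pd

    return pd.DataFrame([e.as_dict() for e in envs])


def merit_table(params: MeritParams) -> "pd.DataFrame":
    """Per-trait merit parameters as a tidy table (for CSV export)."""
    import pandas as pd

    rows = []
    for t in params.trait_labels:
        rows.append({
            "trait": t,
            "profit_base": params.profit.base.get(t, 0.0),
            "quality_q": params.quality.coef.get(t, 0.0),
            "omega_perf": params.performance.omega.get(t, 0.0),
            "opt_perf": params.performance.opt.get(t, float("nan")),
            "omega_emot": params.emotional.omega.get(t, 0.0),
            "opt_emot": params.emotional.opt.get(t, float("nan")),
            "omega_altr": params.altruistic.omega.get(t, 0.0),
            "opt_altr": params.altruistic.opt.get(t, float("nan")),
            "omega_easy": params.easygoing.omega.get(t, 0.0),
            "omega_mon": params.easygoing.omega_mon.get(t, 0.0),
        })
    return pd.DataFrame(rows)


def config_hash(sc: Scenario) -> str:
    """Stable short hash of the scenario document (for output provenance)."""
    return hashlib.sha256(_dumps(scenario_to_dict(sc)).encode()).hexdigest()[:16]
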