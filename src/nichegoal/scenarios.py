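"""Fully specified toy scenarios for every pipeline stage.

Each scenario bundles a trait space, breed state, niche, per-subniche merit
parameters (the ground truth for recovery experiments), validity parameters
and optimization settings.  Trait counts, parameter magnitudes and subniche
structures are fixture choices intended to be realistic for the breed type
they sketch, not measurements of any actual breed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .breed import (
    BreedState,
    GeneticParameters,
    ReactionNorm,
    Trait,
    TraitSpace,
)
from .environment import (
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
from .optimize import (
    HalfspaceExclusion,
    PermissibleSet,
    SearchArea,
    build_response_area,
    default_search_box,
)
from .simulate import ValidityParams

__all__ = [
    "OptimizationSettings",
    "Scenario",
    "make_companion_dog_scenario",
    "make_dairy_scenario",
    "make_two_env_bodyweight_scenario",
    "make_scenario",
    "SCENARIO_MAKERS",
]


@dataclass(frozen=True)
class OptimizationSettings:
    horizon_years: float = 15.0
    generation_interval_years: float = 5.0
    intensity: float = 1.0
    search_k_sd: float = 2.0
    n_starts: int = 6
    tol: float = 1e-9
    n_env: int = 200
    n_pheno: int = 10_000
    n_choices: int = 2000
    choice_scale: float = 1.0

    @property
    def generations(self) -> int:
        return max(1, int(self.horizon_years // self.generation_interval_years))


@dataclass(frozen=True)
class Scenario:
    name: str
    state: BreedState
    niche: Niche
    merit_by_subniche: dict[str, MeritParams]
    validity: ValidityParams
    settings: OptimizationSettings = field(default_factory=OptimizationSettings)
    seed: int = 0
    exclusions: tuple[HalfspaceExclusion, ...] = ()

    def __post_init__(self) -> None:
        labels = self.state.trait_space.labels
        for sub in self.niche.subniches:
            if sub.label not in self.merit_by_subniche:
                raise ValueError(
                    f"scenario {self.name!r}: subniche {sub.label!r} has no "
                    "merit parameters"
                )
        for lab, params in self.merit_by_subniche.items():
            if params.trait_labels != labels:
                raise ValueError(
                    f"scenario {self.name!r}: merit params for {lab!r} use a "
                    "different trait ordering than the trait space"
                )

    def permissible_set(self) -> PermissibleSet:
        box = default_search_box(
            self.state.trait_space.labels,
            self.state.mu_c,
            self.state.genetics.P,
            self.settings.search_k_sd,
        )
        search = SearchArea(box=box, exclusions=self.exclusions)
        response = build_response_area(
            self.state.genetics,
            self.state.mu_c,
            self.settings.intensity,
            self.settings.generations,
            labels=self.state.trait_space.labels,
        )
        return PermissibleSet(search=search, response=response)


def _cov_from_sd_corr(sd: np.ndarray, corr: np.ndarray) -> np.ndarray:
    return np.outer(sd, sd) * corr


def make_companion_dog_scenario(seed: int = 0) -> Scenario:
    """A companion dog breed: owners are the consumers, profit negligible.

    Six traits, two owner groups (apartment owners with noise-sensitive
    neighbours vs. house-with-garden owners) as atom subniches with opposing
    optima for barking.  The role weights put almost everything on the
    owner's total merit (lambda = 1), a small weight on the producer.  A
    health-score floor is an ethical exclusion.
    """
    traits = TraitSpace((
        Trait("cuteness", "conformation_movement", "score 0-10"),
        Trait("barking", "behaviour", "score 0-10"),
        Trait("trainability", "performance", "score 0-10"),
        Trait("longevity", "functional", "years"),
        Trait("health_score", "functional", "score 0-100"),
        Trait("body_size", "conformation_movement", "cm"),
    ))
    labels = traits.labels
    sd = np.array([1.5, 1.2, 1.5, 2.0, 8.0, 4.0])
    corr = np.array([
        [1.0, 0.0, 0.1, 0.0, 0.0, -0.2],
        [0.0, 1.0, -0.3, 0.0, 0.0, 0.0],
        [0.1, -0.3, 1.0, 0.0, 0.1, 0.0],
        [0.0, 0.0, 0.0, 1.0, 0.5, -0.2],
        [0.0, 0.0, 0.1, 0.5, 1.0, -0.1],
        [-0.2, 0.0, 0.0, -0.2, -0.1, 1.0],
    ])
    P = _cov_from_sd_corr(sd, corr)
    h2 = np.array([0.30, 0.35, 0.25, 0.15, 0.20, 0.45])
    gcorr = np.array([
        [1.0, 0.0, 0.1, 0.0, 0.0, -0.25],
        [0.0, 1.0, -0.35, 0.0, 0.0, 0.0],
        [0.1, -0.35, 1.0, 0.0, 0.1, 0.0],
        [0.0, 0.0, 0.0, 1.0, 0.55, -0.25],
        [0.0, 0.0, 0.1, 0.55, 1.0, -0.1],
        [-0.25, 0.0, 0.0, -0.25, -0.1, 1.0],
    ])
    gsd = sd * np.sqrt(h2)
    G = _cov_from_sd_corr(gsd, gcorr)
    mu_c = np.array([5.0, 5.0, 5.0, 11.0, 70.0, 40.0])
    state = BreedState(trait_space=traits, mu_c=mu_c,
                       genetics=GeneticParameters(G=G, P=P))

    def owner_env(noise_sensitive: float, garden: float) -> Environment:
        return Environment(
            DesireProfile(
                profit={"income": 0.1},
                performance={"leisure_activities": 0.5},
                emotional={"companionship": 0.9, "aesthetics": 0.7},
                easygoing={"low_effort": 0.6},
                altruistic={"tradition": 0.1},
            ),
            InfluencingVariables(
                owner={"experience": 0.5},
                physical_env={"noise_sensitive_neighbours": noise_sensitive,
                              "fenced_garden": garden},
                market={"puppy_price": 1500.0},
                legislative={"dangerous_dog_act": 0.0},
            ),
        )

    apartment = Subniche(
        label="apartment",
        distribution=AtomDistribution(((owner_env(1.0, 0.0), 1.0),)),
        size=60_000.0,
        growth_rate=0.01,
    )
    garden = Subniche(
        label="garden",
        distribution=AtomDistribution(((owner_env(0.0, 1.0), 1.0),)),
        size=40_000.0,
        growth_rate=-0.005,
    )
    producer_env = owner_env(0.0, 1.0)
    niche = Niche(subniches=(apartment, garden), producer_env=producer_env)

    def dog_params(barking_opt: float, barking_w: float,
                   cute_opt: float) -> MeritParams:
        # omegas are on a money-comparable scale (EUR per score unit per
        # year); tau_max per block = sum of omega * 2 SD keeps rewards
        # positive on the default search box
        perf = AbsDevReward(
            omega={"trainability": 30.0, "barking": barking_w},
            opt={"trainability": 7.0, "barking": barking_opt},
            tau_max=30.0 * 2 * 1.5 + barking_w * 2 * 1.2,
        )
        emot = AbsDevReward(
            omega={"cuteness": 120.0},
            opt={"cuteness": cute_opt},
            tau_max=120.0 * 2 * 1.5,
        )
        return MeritParams(
            trait_labels=labels,
            profit=LinearProfit(
                base={"longevity": 0.0, "body_size": -20.0,
                      "health_score": 8.0},
                fixed=-800.0,
            ),
            quality=ProductQuality(coef={"health_score": 1.0,
                                         "cuteness": 20.0}, q0=0.0),
            performance=perf,
            emotional=emot,
            altruistic=AbsDevReward(),  # constant zero: no traditionalists here
            breed_id="companion_dog",
            easygoing=EasygoingCost(
                omega={"barking": 20.0, "body_size": 10.0},
                omega_mon={"barking": 5.0, "body_size": 6.0},
            ),
            weights=MeritWeights(lambda_=1.0, w=(0.4, 0.6, 0.0),
                                 alpha=(0.1, 0.9, 0.0)),
        )

    merit = {
        "apartment": dog_params(barking_opt=2.0, barking_w=80.0, cute_opt=7.5),
        "garden": dog_params(barking_opt=4.0, barking_w=25.0, cute_opt=6.5),
    }
    # competitor breeds sit near the current adaptedness level, so the
    # population is roughly stable before the program starts
    validity = ValidityParams(c_b=0.05, N_min=1000.0, a_ref=-1300.0,
                              kappa=0.005)
    exclusions = (
        HalfspaceExclusion(label="health_floor",
                           coeffs={"health_score": 1.0},
                           threshold=65.0, direction="below"),
    )
    return Scenario(
        name="companion_dog", state=state, niche=niche,
        merit_by_subniche=merit, validity=validity,
        settings=OptimizationSettings(choice_scale=100.0),
        seed=seed, exclusions=exclusions,
    )


def make_dairy_scenario(seed: int = 0) -> Scenario:
    """A dairy cattle breed: owners are the breeders, profit dominates.

    Five traits, one Gaussian subniche over the milk price and feed quality,
    a linear profit equation whose milk coefficient follows the milk price,
    a small lambda (perceived rewards matter a little even to producers) and
    a reaction norm of milk yield on feed quality.
    """
    traits = TraitSpace((
        Trait("milk_yield", "production", "kg/yr"),
        Trait("longevity", "functional", "yr"),
        Trait("udder_score", "conformation_movement", "score"),
        Trait("temperament", "behaviour", "score"),
        Trait("stature", "conformation_movement", "cm"),
    ))
    labels = traits.labels
    sd = np.array([1200.0, 1.2, 1.0, 1.0, 4.0])
    corr = np.array([
        [1.0, -0.3, 0.1, 0.0, 0.25],
        [-0.3, 1.0, 0.2, 0.1, -0.1],
        [0.1, 0.2, 1.0, 0.0, 0.1],
        [0.0, 0.1, 0.0, 1.0, 0.0],
        [0.25, -0.1, 0.1, 0.0, 1.0],
    ])
    P = _cov_from_sd_corr(sd, corr)
    h2 = np.array([0.30, 0.10, 0.25, 0.15, 0.45])
    gcorr = np.array([
        [1.0, -0.35, 0.1, 0.0, 0.3],
        [-0.35, 1.0, 0.25, 0.1, -0.1],
        [0.1, 0.25, 1.0, 0.0, 0.1],
        [0.0, 0.1, 0.0, 1.0, 0.0],
        [0.3, -0.1, 0.1, 0.0, 1.0],
    ])
    G = _cov_from_sd_corr(sd * np.sqrt(h2), gcorr)
    mu_c = np.array([8000.0, 5.0, 5.0, 5.0, 145.0])

    base_env = Environment(
        DesireProfile(
            profit={"income": 0.9},
            easygoing={"low_effort": 0.5},
            emotional={"good_looking_herd": 0.2},
        ),
        InfluencingVariables(
            owner={"is_breeder": 1.0},
            physical_env={"feed_quality": 0.0},
            market={"milk_price": 0.40},
            legislative={"emission_tax": 0.0},
        ),
    )
    state = BreedState(
        trait_space=traits, mu_c=mu_c,
        genetics=GeneticParameters(G=G, P=P),
        reaction_norm=ReactionNorm(
            variables=("feed_quality",),
            matrix=np.array([[400.0], [0.0], [0.0], [0.0], [0.0]]),
            reference=(0.0,),
        ),
    )
    farms = Subniche(
        label="farms",
        distribution=GaussianDistribution(
            base=base_env,
            labels=("milk_price", "feed_quality"),
            mean=(0.40, 0.0),
            cov=((0.004, 0.0), (0.0, 0.25)),
        ),
        size=5000.0,
        growth_rate=-0.01,
    )
    niche = Niche(subniches=(farms,), producer_env=base_env)
    params = MeritParams(
        trait_labels=labels,
        profit=LinearProfit(
            base={"milk_yield": 0.0, "longevity": 120.0, "udder_score": 15.0,
                  "stature": -4.0},
            multipliers={"milk_yield": {"milk_price": 1.0}},
            fixed=-1500.0,
        ),
        quality=ProductQuality(coef={"milk_yield": 0.02}, q0=0.0),
        performance=AbsDevReward(
            omega={"temperament": 30.0}, opt={"temperament": 6.0},
            tau_max=30.0 * 2 * 1.0,
        ),
        emotional=AbsDevReward(
            omega={"stature": 10.0}, opt={"stature": 150.0},
            tau_max=10.0 * 2 * 4.0,
        ),
        altruistic=AbsDevReward(),
        breed_id="dairy",
        easygoing=EasygoingCost(
            omega={"stature": 6.0}, omega_mon={"stature": 4.0},
        ),
        weights=MeritWeights(lambda_=0.1, w=(0.6, 0.4, 0.0),
                             alpha=(0.0, 0.9, 0.1)),
    )
    validity = ValidityParams(c_b=0.5, N_min=500.0, a_ref=1650.0, kappa=0.0005)
    return Scenario(
        name="dairy", state=state, niche=niche,
        merit_by_subniche={"farms": params}, validity=validity,
        settings=OptimizationSettings(
            horizon_years=15.0, generation_interval_years=5.0,
            n_env=100, choice_scale=300.0,
        ),
        seed=seed,
    )


def make_two_env_bodyweight_scenario(seed: int = 0) -> Scenario:
    """One body-weight trait, two environments with opposing optima.

    A small body weight is preferred by one owner group, a large one by the
    other, and feed quality shifts the realized weight through a reaction
    norm: the classic illustration of environment-dependent optima and the
    niche-averaged compromise.
    """
    traits = TraitSpace((Trait("body_weight", "conformation_movement", "kg"),))
    P = np.array([[9.0]])
    G = np.array([[3.6]])  # h2 = 0.4
    mu_c = np.array([25.0])

    def env(feed: float, pref: float) -> Environment:
        return Environment(
            DesireProfile(emotional={"suits_me": pref}),
            InfluencingVariables(physical_env={"feed_quality": feed}),
        )

    e1 = env(0.0, 1.0)
    e2 = env(1.0, 1.0)
    state = BreedState(
        trait_space=traits, mu_c=mu_c,
        genetics=GeneticParameters(G=G, P=P),
        reaction_norm=ReactionNorm(
            variables=("feed_quality",),
            matrix=np.array([[4.0]]),
            reference=(0.0,),
        ),
    )
    sub1 = Subniche("light_preferring",
                    AtomDistribution(((e1, 1.0),)), size=500.0)
    sub2 = Subniche("heavy_preferring",
                    AtomDistribution(((e2, 1.0),)), size=500.0)
    niche = Niche(subniches=(sub1, sub2), producer_env=e1)

    def params(opt: float) -> MeritParams:
        return MeritParams(
            trait_labels=traits.labels,
            emotional=AbsDevReward(
                omega={"body_weight": 1.0}, opt={"body_weight": opt},
                tau_max=2 * 3.0,
            ),
            weights=MeritWeights(lambda_=1.0, w=(0.0, 1.0, 0.0),
                                 alpha=(0.0, 1.0, 0.0)),
        )

    merit = {"light_preferring": params(20.0), "heavy_preferring": params(30.0)}
    validity = ValidityParams(c_b=1.0, N_min=100.0, a_ref=0.0, kappa=0.0)
    return Scenario(
        name="two_env_bodyweight", state=state, niche=niche,
        merit_by_subniche=merit, validity=validity,
        settings=OptimizationSettings(
            horizon_years=10.0, generation_interval_years=2.0,
        ),
        seed=seed,
    )


SCENARIO_MAKERS = {
    "companion_dog": make_companion_dog_scenario,
    "dairy": make_dairy_scenario,
    "two_env_bodyweight": make_two_env_bodyweight_scenario,
}


def make_scenario(name: str, seed: int = 0) -> Scenario:
    try:
        maker = SCENARIO_MAKERS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIO_MAKERS)}"
        ) from None
    return maker(seed)
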