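# nichegoal

Breeding-goal optimization for animal breeds whose owners do not breed for
profit alone.

The classical route to a breeding goal maximizes a profit function
φ(μ) over the trait means μ and derives economic index weights
**b** = P⁻¹G**a** (the Smith–Hazel index) from its gradient **a**.  That
route fails for companion breeds, hobby breeds and increasingly for
livestock, because owners also want performance they can handle, animals
that satisfy emotional needs (cuteness, elegance), easygoing animals, and
sometimes adherence to a traditional breed type.  `nichegoal` implements a
niche-based generalization:

1. **Niche model.** A breed's envisaged niche is a distribution over owner
   *environments* **e** = (**d**, **v**): a desire profile **d** (profit,
   performance, emotional, easygoing, altruistic dimensions) plus
   influencing variables **v** (owner traits, physical environment, market
   prices, legislation).  The niche is a size-weighted mixture of
   subniches — owner groups represented either as discrete environment
   atoms or as Gaussians over numeric dimensions — with per-subniche
   exponential size dynamics 𝔪ₜ = 𝔪₀·exp(g·t).
2. **Merit.** The total merit of an animal with phenotype **y** for an
   owner in environment **e** is
   TMₑ(**y**) = φᵥ(**y**) + λₑ(Rₑ(**y**) − Cₑ(**y**)), with a linear profit
   equation φᵥ, reward kernels of the form τ − Σₖ ωₖ|yₖ − Optₖ| for
   performance, emotional and altruistic desires, and a perceived-cost term
   Cₑ for easygoingness.
3. **Adaptedness.** a(μ, **e**) = αₚ·𝔼TMₑₚ(**y**′) + αₙ·𝔼TMₑ(**y**) +
   α꜀·𝔼PQ(**y**), with **y** ~ N(μ(**e**), P).  Under the Gaussian
   phenotype model every expectation is closed-form (the |y−Opt| terms are
   folded-normal means).  Averaging over the niche mixture gives the
   adaptedness function that replaces the profit function as the objective.
4. **Estimation.** Merit parameters are recovered from discrete choice
   experiments: binary forced choices between trait profiles drawn
   uniformly in the search area, with logistic choice probabilities on the
   merit difference; maximum likelihood by a convex inner logit fit for ω
   nested in a derivative-free search over Opt, with observed-information
   standard errors.  The role weights (αₚ, αₙ, α꜀) come from a separate
   choice experiment on component merits.
5. **Optimization.** The goal is maximized over the *permissible set*: a
   search box (current means ± 2 phenotypic SD) intersected with the
   response ellipsoid {μ : (μ−μ꜀)ᵀ(GP⁻¹G)⁻¹(μ−μ꜀) ≤ (T·i)²} of states
   reachable in T generations at selection intensity i, minus labelled
   welfare exclusions.  The desired-gain index
   **b** = P⁻¹G(GᵀP⁻¹G)⁻¹Δμ then realizes the straight-line path to the
   goal, and a deterministic multivariate breeder's-equation simulation
   verifies the trajectory, the population-size dynamics and the validity
   condition c_b·𝔪ₜ ≥ N_min.

When the owners' sole desire is income (linear profit, λ = 0, all weight
on the owner's merit), the optimized desired-gain index is collinear with
the Smith–Hazel index — the framework contains the traditional approach as
a special case, and the test suite checks this.

## Worked example

Three fully specified synthetic scenarios ship with the package
(`companion_dog`, `dairy`, `two_env_bodyweight`).  The companion-dog
scenario has six traits and two owner groups — apartment owners with
noise-sensitive neighbours (barking optimum 2) and house-with-garden
owners (barking optimum 4):

```python
import nichegoal as ng
from nichegoal.pipeline import (evaluate_adaptedness,
                                optimize_scenario_goal,
                                run_breeding_program)

sc = ng.make_companion_dog_scenario(seed=1)
print(evaluate_adaptedness(sc, seed=1))
goal = optimize_scenario_goal(sc, seed=1)
traj = run_breeding_program(sc, goal, seed=1)
```

prints (values in merit units ≈ EUR/year; negative because keeping a dog
costs money — only differences matter):

```
             scope      method        value  se  n
             niche closed_form -1216.594279 0.0  0
subniche:apartment closed_form -1252.162677 0.0  0
   subniche:garden closed_form -1163.241683 0.0  0
```

The optimized intermediate goal, desired gains and index weights:

```
cuteness      mu_c=    5.00  goal=    5.78  delta= +0.779  b=+0.2169
barking       mu_c=    5.00  goal=    4.65  delta= -0.352  b=-0.2193
trainability  mu_c=    5.00  goal=    5.25  delta= +0.248  b=+0.0375
longevity     mu_c=   11.00  goal=   11.39  delta= +0.387  b=-0.0287
health_score  mu_c=   70.00  goal=   71.53  delta= +1.525  b=+0.0273
body_size     mu_c=   40.00  goal=   35.26  delta= -4.736  b=-0.2011
adaptedness: -1035.6 active: ('response_ellipsoid',)
```

The goal sits on the response-ellipsoid boundary (the planning horizon is
the binding constraint): cuter, quieter, healthier, smaller dogs.  The
breeding program simulation confirms the means reach the goal and the
population grows as adaptedness beats the competitor reference level:

```
 generation  adaptedness  pop_size  valid
          0     -1216.59   5000.00   True
          1     -1154.88   5104.43   True
          2     -1094.47   5217.97   True
          3     -1035.60   5340.99   True
```

The same workflow is available from the shell:

```bash
nichegoal run-all --scenario companion_dog --seed 1 --outdir out/
```

writes the scenario, choice-experiment data, fitted preference parameters,
the optimized goal, index weights and the program trajectory as CSV/JSON,
byte-identical across repeated runs with the same seed.

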