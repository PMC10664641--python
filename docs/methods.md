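# Methods

This note records the modelling choices behind `nichegoal`: the model and
its assumptions, the parameters that matter, what the synthetic scenarios
emulate, numerical details, and known limitations.

## Environments and niches

An environment is one prospective owner, split into a desire profile
(five categories: profit, performance, emotional, easygoing, altruistic;
each a set of named nonnegative importance scores) and influencing
variables (owner traits, physical environment, market prices, legislative
conditions).  All dimensions are label-addressed; merit parameters bind to
labels, never to positions.

A niche is a mixture of subniches weighted by their current sizes (owner
places).  No distributional form for environments is inherent to the
theory, so the package supports the two simplest forms that cover
practice: finite atoms (questionnaire-style discrete owner types, exact
expectations) and multivariate Gaussians over a declared subset of numeric
dimensions with everything else fixed (continuous influencing variables
such as prices; Monte-Carlo expectations).  Gaussian draws of market-price
dimensions are truncated at zero to keep prices nonnegative; with
realistic price means several SDs above zero the truncation is
inconsequential.

Subniche sizes evolve as 𝔪ₜ = 𝔪₀·exp(g·t) with a constant per-year growth
rate g — the simplest dynamic consistent with owner groups growing or
shrinking over a planning horizon.  "Endangered" subniches are
operationalized as those whose projected size at the horizon falls below a
threshold; a limit statement (size tending to zero) is not directly
checkable in finite time.  Time variation of the environment distribution
*within* a subniche (owners changing preferences) is not modelled.

## Phenotypes

Phenotypes are multivariate Gaussian with mean μ(e) and constant
phenotypic covariance P.  Environment dependence of the mean is restricted
to an affine reaction norm on declared physical-environment variables;
the constant-mean model is the default and is the space the optimizer
searches.  This choice buys closed-form adaptedness (below) and a clean
Monte-Carlo cross-check; it gives up non-Gaussian traits and nonlinear
genotype-by-environment interaction.  Supplemental traits (sex, QTL
genotypes) are carried as ordinary real-valued columns.

## Merit functions

* Profit: linear profit equation φᵥ(y) = fixed(v) + Σₖ cₖ(v)·yₖ, each
  coefficient optionally linear in named influencing variables.  Linearity
  matches profit-equation practice and makes the traditional-approach
  equivalence exact.  The per-trait monetary values (first-order Taylor
  coefficients of profit) are exactly the cₖ(v) and seed the monetary
  costs ω^mon.
* Performance / emotional / altruistic rewards: τ_max − Σₖ ωₖ|yₖ − Optₖ|.
  τ_max only shifts the merit level (it keeps merits positive); it cancels
  from all choice probabilities and from every comparison, and is
  therefore a fixed user parameter, never estimated.  Scenario default:
  Σₖ ωₖ·(2 phenotypic SD of trait k), which keeps rewards positive across
  the default search box.
* Easygoingness: perceived cost Σₖ (ωₖ − ωₖ^mon)·yₖ over traits whose
  perceived cost exceeds the monetary cost; traits with ωₖ < ωₖ^mon are
  dropped from the sum with a log note rather than an error (the owner
  simply perceives no extra cost there).
* Product quality: a linear consumer score.  Emotional "pattern scores"
  (e.g. cuteness) are ordinary traits supplied as data; scoring animals
  from images is out of scope.
* Total merit: TMₑ(y) = φᵥ(y) + λₑ(Rₑ(y) − Cₑ(y)), with Rₑ the
  (w₁, w₂, w₃)-weighted reward sum.  λₑ ≈ 0 suits producers (a small
  positive value keeps their non-monetary interests represented), λₑ = 1
  suits consumers.  The weights w are fixed constants per owner group,
  which trivially satisfies the independence assumption needed to move
  expectations through the reward sum; random-coefficient owners are not
  modelled.

## Adaptedness

a(μ, e) = αₚ·𝔼TMₑₚ(y′) + αₙ·𝔼TMₑ(y) + α꜀·𝔼PQ(y), with the producer term
evaluated at the producer environment's influencing variables and trait
means.  One MeritParams object serves both owner and producer terms within
a subniche; producers with genuinely different preferences would be
modelled as their own subniche.  Under Gaussian phenotypes each
𝔼|yₖ − Optₖ| is the folded-normal mean

    E|Y − c| = s·√(2/π)·exp(−δ²/2s²) + δ·(2Φ(δ/s) − 1),  δ = m − c,

so the closed form needs only the marginal SDs; linear terms pass through
the mean.  The closed form is preferred everywhere; the Monte-Carlo route
(plug-in SE of the mean, independent seed substreams for owner- and
producer-environment draws) exists as an independent check and for future
non-linear merits.

Niche adaptedness conditions on the niche's own mixture distribution —
atom subniches averaged exactly, Gaussian subniches by Monte Carlo over
sampled environments (the estimate is tagged `monte_carlo` whenever any
environment sampling is involved, so SE = 0 exactly characterizes fully
closed-form values).  An alternative semantics — truncating a
species-wide environment distribution to the niche — is noted but not
implemented.

For the companion-dog scenario the owners who provide the niche *are* the
consumers, so the large role weight sits on the owner total-merit term
(αₙ) and the product-quality weight α꜀ is zero; the producer keeps a small
αₚ.  This realizes the owner-as-consumer simplification of the adaptedness
expectation; PQ as a separate linear score is only meaningful when a
product distinct from the animal exists (the dairy scenario uses it).

## Preference estimation

Binary forced-choice conditional logit: P(choose A) =
logistic((TM(y_A) − TM(y_B))/scale), profiles uniform in the search box.
This is the simplest identifiable stated-preference model matching the
merit structure.  Identification notes:

* ω enters linearly through |y − Opt| features; for fixed Opt the
  likelihood is convex and fitted by BFGS on the exact log-likelihood.
  Opt makes the likelihood nonsmooth, so it is profiled out by Nelder-Mead
  (grid-free; the outer tolerance is set relative to the box width).
  Joint SEs come from the observed information (central-difference Hessian
  at the optimum).
* τ_max and any additive constants cancel from choice differences and are
  not estimated; the common scale is a design parameter assumed known.
* Opt is identified only if it lies inside the design box (otherwise the
  |y − Opt| feature is affine in y and only ω is identified).  Scenario
  optima are placed inside the default box.
* Each merit function is estimated in its own focused experiment (other
  merit components held out of the design); estimating one block from
  choices driven by the full total merit attenuates the coefficients, the
  standard omitted-variable effect in logit models.  The pipeline's
  `simulate_scenario_choices` therefore defaults to block-focused designs.
* The role weights α are estimated from a separate experiment whose
  utility is the α-weighted combination of component merits; the fitted
  coefficients are projected to the simplex (negatives clipped, then
  renormalized).  Collinear component merits — e.g. a producer environment
  that shifts merit only by a constant — are flagged as non-identifiable
  rather than silently fitted.
* Perfect separation is flagged, not raised; SEs are then unavailable.
* A narrowed second-round design is supported simply by re-running on a
  user-shrunk box; no automatic stopping rule is imposed.
* Willingness to pay per unit trait improvement is ω̂ divided by a fitted
  money coefficient when the design includes a price attribute.

## Permissible set and optimization

Search box: current means ± k phenotypic SD (default k = 2,
configurable).  Ethical exclusions are labelled half-spaces or boxes over
traits (threshold rules such as a health-score floor).  Response
ellipsoid: per generation the index response is Δ = i·G·b/√(bᵀPb); as b
sweeps all index vectors this traces the surface
(μ−μ꜀)ᵀ(GP⁻¹G)⁻¹(μ−μ꜀) = i², so T generations at constant intensity i
(and constant G, P — the simplest case; no Bulmer effect, no discounting)
reach the ellipsoid with radius T·i.  T = floor(horizon / generation
interval), both scenario inputs in years.  Membership is exact up to a
documented 1e−12 relative tolerance on the quadratic form; a singular G is
rejected with advice to reduce the trait set.

The optimizer works in coordinates where the ellipsoid is the unit ball
(μ = μ꜀ + r·M^{−1/2}z).  Each of several seeded feasible starts runs an
interior-point gradient polish (valid whenever all exclusions are
half-spaces, i.e. the feasible set is convex; the objective is normalized
to order 1 first) followed by projected compass search, which accepts only
feasible improving moves, radially projects steps leaving the ball, and
ignores improvements below 1e−12 relative (float noise).  The closed-form
objective is smooth and concave in μ (folded-normal means are smooth for
s > 0), so multi-start is a safeguard rather than a necessity; the compass
stage guards the polish against nonsmooth or nonconvex configurations.
Ties across starts break first-found; everything is deterministic given
the seed.  An empty permissible set (exclusions swallowing the reachable
set) raises with the advice to extend the planning horizon.

Desired-gain index: b = P⁻¹G(GᵀP⁻¹G)⁻¹Δμ, normalized to bᵀPb = 1 (unit
index variance; any positive scaling ranks identically).  The Smith–Hazel
index b = P⁻¹G·a is implemented as the benchmark: with a linear profit
objective and no binding box, the ellipsoid argmax is
Δμ* ∝ GP⁻¹G·a, hence the desired-gain index P⁻¹G·a — exactly the
traditional index.  bᵀGb is reported each generation; a value at or near
zero flags an inadmissible goal (the index would exhaust usable genetic
variance).

## Breeding-program simulation

Deterministic expectation-level recursion μₜ₊₁ = μₜ + i·G·b/√(bᵀPb)
(infinitesimal model, no finite-population noise on means); when a goal is
supplied the final step is shortened so the means stop at the goal instead
of overshooting an interior optimum.  Population dynamics use the simplest
monotone link between adaptedness and growth,
nₜ₊₁ = min(nₜ·exp(κ(aₜ − a_ref)), c_b·𝔪ₜ₊₁): κ (growth per merit unit)
and the competitor reference level a_ref are scenario inputs, isolated in
this one operation because no functional link is inherent to the theory.
Adaptedness is recomputed each generation with the same seed (common
random numbers), so the closed-form adaptedness sequence is exactly
monotone when means approach the optimum.  Validity per generation:
c_b·𝔪ₜ ≥ N_min and nₜ ≥ N_min, with the signed margin reported
(N_min ≈ the population size supporting an effective size of about 100).

## Synthetic scenarios

* `companion_dog` (K = 6): two atom subniches (apartment owners with
  noise-sensitive neighbours, barking optimum 2 and weight 80; garden
  owners, optimum 4 and weight 25), reward weights on a money-comparable
  scale (EUR/score/year), λ = 1, α = (0.1, 0.9, 0), a health-score floor
  of 65 as exclusion, horizon 15 y at 5 y/generation, i = 1.
* `dairy` (K = 5): one Gaussian subniche over milk price
  (mean 0.40, SD 0.063 EUR/kg) and feed quality (SD 0.5), profit-dominant
  (λ = 0.1), milk-yield profit coefficient equal to the milk price,
  reaction norm of 400 kg milk per feed-quality unit.
* `two_env_bodyweight` (K = 1): two owner groups preferring 20 vs 30 kg
  and a 4 kg/unit feed-quality reaction norm — the minimal illustration of
  environment-dependent optima and the niche-averaged compromise.

These emulate the *structure* of real problems — opposing optima across
owner groups, price-dependent economic values, genotype-by-environment
interaction — at desk scale.  They do not emulate real parameter
magnitudes, measurement error in choice data (choices are exactly
logistic), panel structure of respondents, or estimation error in G and P
(treated as known).  Passing tests therefore demonstrate internal
consistency and recoverability under the stated model, not field validity
for any actual breed.  Default sizes (2000 choices per experiment, 100–200
sampled environments per Gaussian subniche, 10⁴–10⁵ phenotype draws in
Monte-Carlo checks) keep every pipeline run in seconds on one CPU while
holding Monte-Carlo error well inside the tolerances the tests assert.

## Numerical details

* All randomness flows from one user seed through named CRC32-keyed
  SeedSequence substreams; no global RNG state.
* Folded-normal kernel: the standardized deviation is clipped at |z| = 40
  (Φ and the Gaussian density saturate long before); s = 0 returns |m − c|
  exactly.
* Logit convergence is judged by the gradient norm relative to √n when
  BFGS stops on precision loss.
* Config I/O is strict JSON: unknown keys and label mismatches are errors
  with a path into the document; floats serialize at `repr` precision so
  save → load → save is byte-identical.  Output CSV/JSON embed the seed
  and a scenario hash.

## Known limitations

Single breed (no competition for the same niche), constant G and P, no
discounting of future gains, no inbreeding or optimal-contribution
machinery, binary (not multinomial) choice designs without D-optimality,
affine-only reaction norms, and only the intermediate goal is computed —
the long-term goal beyond the planning horizon is intentionally out of
scope.
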