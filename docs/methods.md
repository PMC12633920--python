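# Methods

`secularsim` simulates an artificial society to probe a single theoretical
question: under what conditions does the feedback loop

> threats → insecurity → anxiety → religiously motivated prosocial behaviour
> → reduced insecurity

sustain a thriving, religious society — and under what conditions does a
secular central institution, which supplies security without religion,
dismantle that loop and secularise the society.

## Agents and state

Each agent carries eight state variables: age (years), gender, marital
status (with a reciprocal partner link), religiosity, wellbeing, insecurity
and sensitivity (all unitless in [0, 1]), and anxiety, defined at all times
as insecurity × sensitivity.  Agents occupy fixed positions in a 500 × 500
continuous square; "neighbours" are agents within a radius of 50.  The
society starts with 1,000 agents: ages drawn from a decreasing pyramid mass
(P(age = a) ∝ 100 − a on 0–100), religiosity and sensitivity from
Normal(0.5, 0.1) clamped to [0, 1], insecurity 0, wellbeing from the initial
age curve below, everyone single.

## The yearly cycle

Each simulated year runs: marriage formation; threat exposure (from year
100); the central institution (if scheduled before the prosocial stage);
reproduction (if scheduled before the prosocial stage); the prosocial stage
over all agents in a freshly shuffled order; the central institution and/or
reproduction when scheduled after; wellbeing drift with age, then with
insecurity; religiosity decay of the young; mortality; ageing and
record-keeping.  Under the `random` schedule a single seeded coin per year
places reproduction before or after the prosocial stage.  All randomness
derives deterministically from (run seed, year, stage), so trajectories are
bit-identical across repetitions and independent of batch execution order.

### Threats, anxiety and prosocial behaviour

A yearly threat value is added to every agent's insecurity (capped at 1);
in the stochastic variant the year's value is Uniform(0, 2 × threat), same
mean.  An agent aged ≥ 12 performs a prosocial act when anxiety ×
religiosity strictly exceeds `pb_threshold`.  The act costs the performer
`pb_wellbeing_cost` wellbeing, lowers the performer's insecurity by
`pb_dec_insec_self`, and benefits up to `num_neigh_benefited` neighbours
drawn uniformly from those within the radius whose religiosity exceeds the
performer's minus the parochial-prosociality tolerance (tolerance 1
disables parochialism).  Beneficiaries lose `pb_dec_insec_neigh`
insecurity.  Performers and beneficiaries still in the socialisation window
(age ≤ 25) gain religiosity (`pb_inc_rel_self` / `pb_inc_rel_neigh`) — the
credibility-enhancing-display mechanism.  Agents in the window also lose a
fraction `rel_dec_perc` of religiosity every year (multiplicative;
an additive variant exists as a robustness flag); religiosity freezes for
life after age 25.  Acts within a year are sequential: an early act can calm
a later would-be performer.  This ordering is randomised every year to avoid
order artefacts.

### Wellbeing and mortality

Wellbeing drifts with age as Δ = C − 4C·u^Exp2 for u = (age − T)/(100 − T) ≥ 0
(equal to C at the age threshold T, −3C at age 100).  Below the threshold
the curve is continued with a signed power, Δ = C + 4C·|u|^Exp1, so the gain
is largest at age 0 and meets C at T; the raw expression has a negative base
there and is undefined for real exponents.  Wellbeing also responds to
insecurity piecewise linearly through (0, +WB.Max.Inc), (WB.Insec.Th, 0) and
(1, −WB.Max.Dec); the implementation uses the line consistent with those
stated endpoint semantics, with the literal (increasing) gain branch
available behind `eq3_as_printed`.  Both deltas are applied with clamping to
[0, 1].  Yearly death probability is a polynomial in wellbeing — near 1 at
wellbeing 0, ≤ 0.02 at wellbeing 1, monotone non-increasing; the shipped
coefficients reproduce the silhouette of a 1950s-style life table
re-parameterised on wellbeing, and users can supply their own coefficient
vector (the same applies to the initial-wellbeing age curve).

### Marriage and reproduction

Singles strictly older than 15 are paired in random order with a uniformly
chosen single of the opposite gender whose age differs by at most
`marriage_age_diff`.  Each married female aged 15–49 may bear one child per
year with probability 1/(1 + e^(−b(x − a))), where x is the couple's
weighted mean of wellbeing (weight 1) and insecurity (weight 0.5): higher
insecurity raises fertility, the model's deliberate "insecure environments
prioritise reproduction" assumption.  Each parent loses rep_cost × own
wellbeing; the child's initial wellbeing is the sum of the two losses, and
the child copies religiosity, insecurity and sensitivity from one uniformly
chosen parent.

### Central institution

From year 200, every agent's insecurity drops by `ci_benefit` per year and
every agent strictly older than 18 pays `ci_wb_cost` wellbeing — a stylised
tax-funded welfare state.  The institution never touches religiosity
directly; secularisation in CI runs is always mediated by the collapse of
prosocial-act frequency.  Note an ordering subtlety: the deterministic
"relief extinguishes prosociality" regime requires the institution to act
between threat exposure and the prosocial stage (`ci_timing = before_pb`);
with relief after the stage, the year's fresh threat still triggers acts.

## Reference-model calibration

The reference model (RM) switches threats and prosocial behaviour off and
tunes the nine demographic parameters (reproduction cost, fertility midpoint
a and steepness b, wellbeing age threshold, intercept C, the two exponents,
the security wellbeing gain, and the marriage age window) so the population
stays approximately constant: the objective is the mean over seeded
replicates of Σ_t (pop_{t+1}/pop_t − 1)² over 500 years, with extinct or
runaway candidates truncated and penalised.  A bounded differential-evolution
search with restarts and common random numbers minimises it; the winner is
frozen as `profiles/reference_model.yaml` (score 0.0082; over 20 unseen
seeds the profile yields no extinction and a median year-600 population of
≈ 1,170 from 1,000).

Two caveats a user should understand.  First, the objective is insensitive
to everything the RM never exercises: with insecurity pinned at 0 the
fertility steepness b is essentially unidentified (any (a, b) giving the
same replacement fertility at the RM operating point scores alike), yet b
controls how strongly insecurity boosts fertility once threats are on.
Second, a deterministic drift of ±0.1 %/yr lies below the objective's
stochastic noise floor (|ratio − 1| ≈ 0.004 from demographic noise at
population 1,000), so "approximately constant" spans final populations from
≈ 700 to ≈ 2,000.  Both indeterminacies propagate to any quantity defined
against the fixed success bar of 2,500 agents, which is why scaled sweep
percentages should be read as regime indicators, not point estimates.

## Population ceiling (super-individuals)

The model has no density dependence, so a thriving society grows
exponentially without limit (test runs exceed 10⁷ individuals).  To bound
runtime, a configurable ceiling (`max_population`, default 20,000; the
experiment driver uses 2,000) triggers a rescaling: a random half of the
population units (couples kept together) is culled and the reported
population scale doubles, so each simulated agent thereafter represents
several persons.  Per-capita demographic and behavioural rates are
unaffected; spatial density drops, but beneficiary selection saturates at
`num_neigh_benefited` ≪ neighbourhood size, so the prosocial dynamics are
insensitive to this.  Classification outcomes were checked to be stable
between ceilings of 2,000 and 5,000.

## Experiments and analytics

Latin-hypercube designs over the published behavioural ranges (three
progressively narrowed spaces, plus the central-institution space) are run
under each reproduction/CI schedule with per-sample seeds shared across
schedules (matched comparisons).  Every run is classified from its 25-year
samples: success (population > 2,500 at year 600), population trend and
religiosity trend via Pearson correlation against year from year 200
(17 points, two-sided p < 0.1), and pace-of-secularisation flags for
thriving societies with declining religiosity (all; year-600 religiosity
< 0.5; < 0.125).  Constant series are reported non-significant; an extinct
society is dying by definition.  The sensitivity assessor compares, per
equal-width parameter bin, the percentage of focal runs against the
percentage of reference runs (observed − expected, in percentage points),
singly and over pairwise half-ranges, and proposes narrowed ranges as the
smallest contiguous bin union whose summed difference exceeds 10 points.

## What the synthetic conditions do and do not show

All inputs are generated by the simulator itself under the study conditions
(1,000 agents, 600-year horizon, threats from year 100, institutions from
year 200, the published sampling ranges).  Sweeps in the test suite and the
acceptance script use 500 and 200 Latin-hypercube samples respectively
instead of the published 10,000 — the binomial noise on a percentage is then
≈ ±2–4 points.  Passing checks demonstrate the qualitative regimes (the
prosocial equilibrium, the reproduction-timing asymmetry, institution-driven
secularisation, the forgetting/reinforcement balance) under this package's
own calibration; they do not certify the original headline percentages,
which depend on an unpublished calibrated profile through the
indeterminacies described above.

## Numerical choices

Trait initialisation clamps normal draws to [0, 1] rather than resampling.
Triggering and the success rule use strict inequalities; ties at a threshold
do not fire.  Integer-valued design parameters (beneficiary count) are
rounded after sampling.  All per-agent loops (marriage, reproduction, the
prosocial stage, the fused end-of-year update) are numba kernels over
struct-of-arrays state; the fused kernel is asserted element-for-element
equal to the composition of the public single-step operations.  Stream
seeding uses a splitmix64 hash of (seed, year, stage).  An empty society is
a valid no-op; trajectories of extinct societies are zero-padded.
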