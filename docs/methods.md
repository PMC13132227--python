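# Methods

This note documents the models implemented in `flocklearn`, the choices
made where the design was genuinely open, the synthetic data the tests run
on, and what those tests can and cannot show.

## Association networks

Group scans are pooled across observation periods and sites before the
simple ratio index is computed; for a dyad (i, j),

    SRI(i, j) = x / (x + y_i + y_j)

where `x` counts scans containing both and `y_i` scans containing only i —
equivalently, joint sightings over sightings of either member anywhere.
The denominator is deliberately not site-stratified: under the gambit of
the group all birds in one scan are associating, and the same marked birds
forage across the shared study area.  Individuals on the roster that never
appear in a scan are kept as isolated nodes so that diffusion risk sets can
include them.  A period filter exists as an option; pooling is the default.

Between-roost movement is the Jaccard overlap of site attendance sets,
`m_AB = n_ov / (n_A + n_B − n_ov)`, with `m_AA = 1` by convention.
Attendance defaults to "recorded at the site at least once during the
experimental period".  Roost membership requires the same roost in at least
two of three pre-dawn counts, falling back to the marking site and then to
"unknown"; two qualifying sites for one bird indicate overlapping censuses
and are an error, not a silent tie-break.

## Order-of-acquisition diffusion analysis

At each acquisition event the probability that naive bird i learns next is
`R_i / Σ_naive R`, with

    R_i = exp(Γ·x_i) · s · Σ_j a_ij z_j + exp(B·x_i)

The asocial baseline hazard cancels from this order likelihood and is not
represented.  Covariates are coded −0.5 / 0.5 / 0 (female / male / unknown;
juvenile / adult / unknown) and act independently ("unconstrained") on the
social and asocial rates.  Conventions worth knowing:

- Trained demonstrators enter as seeded-informed: they transmit but never
  contribute events.
- A bird that learned at an earlier site is informed from the start of any
  later diffusion it attends (knowledgeable mover), with arrival defaulting
  to the diffusion start.
- Risk sets are per site — the birds recorded present there — not the
  whole population.
- AICc uses n = total acquisition events across diffusions, and AICc (not
  AIC) is used throughout.
- `s` is fitted on the log scale with deterministic multi-start
  Nelder–Mead (five starts bracketing weak to very strong transmission) so
  the boundary optimum at s = 0 cannot trap the fit.  |log s| is capped at
  15: beyond that the likelihood is flat because the asocial term has
  vanished, and the cap keeps the arithmetic finite.  A fitted s at this
  cap means "unbounded above"; the %ST profile interval conveys what the
  data actually constrain.
- %ST is the mean over observed events of the social share of the actual
  learner's rate; its CI re-evaluates that mean at the values of s where
  the profile deviance crosses the chi-square(1) cutoff, re-optimizing any
  other coefficients.

The generative simulator mirrors the likelihood exactly (sequential
sampling proportional to R), which enables the enumeration check: for any
network and parameters, the probabilities of all complete acquisition
orders sum to 1.

## Experience-weighted attraction choice models

Choice probability is a convex combination of an individual and a social
component, `(1−γ)I + γS`.  The individual component is a softmax with
sensitivity λ over attraction scores updated as `A ← (1−φ)A + φπ`, payoff
π = 1 iff the almond was opened.  Tutored demonstrators start at attraction
1 for their trained colour; everyone else at (0, 0).  The social component
is built from a rolling, site-specific, half-open 60 s window [t−60, t)
that excludes the focal's own solves and includes unmarked birds'.  Five
strategies: pure individual learning; frequency dependence `S_k ∝ N_k^f`;
male- and adult-biased counts (frequency with f = 1 restricted to the
category, falling back to the individual component when the category
produced nothing); and a same-roost cue in which each witnessed
demonstration carries weight `exp(β)` if the demonstrator shares the
focal's roost and 1 otherwise — the per-demonstration reading of the cue
model, with the reference category's weight pinned at 1.  An empty window
is a sentinel: the choice is purely individual for that event, the standard
convention since the frequency expression is undefined at ΣN = 0.  Whether
dropped almonds count as demonstrations is configurable; the default counts
all pickups, since observers see the choice regardless of outcome.

Each strategy's parameters (λ, φ, and as applicable γ, f, β) get a
group-level mean per (age × sex) cell — unknown age or sex is a real level
and forms its own cells — plus individual varying effects, on links log(λ),
logit(φ), logit(γ), log(f), identity(β).  Priors are weakly informative:
Normal(0, 1) on cell means, Normal(0, σ_p) offsets with σ_p ~
Exponential(1).

### Posterior sampling

No external probabilistic-programming backend is used; the posterior is
sampled with an in-package Hamiltonian Monte Carlo whose gradients are
computed analytically inside the numba likelihood kernel (the attraction
recursion carries dA/dφ alongside A).  The kernel is verified in two
independent ways: central finite differences of the log posterior, and an
event-by-event pure-Python reference likelihood.

The geometry of this posterior is two-faced: λ and φ are informed by every
choice a bird makes, while γ, f and β are weakly informed at realistic
sample sizes.  The sampler therefore uses a mixed parameterization
(centered for λ and φ, non-centered for the rest) and, per sweep, updates
the individual block and the hyperparameter block by blocked HMC,
alternating the hyper update between the mixed and the fully non-centered
re-expression (ancillarity–sufficiency interweaving).  Chains warm-start at
the L-BFGS posterior mode (clipped into the prior bulk, since a mode on a
flat f-ridge can sit at an extreme), with a diagonal metric from the local
curvature (floored at 0.25 — the priors bound every marginal sd at O(1), so
smaller curvature signals a ridge, not a wide direction).  Step sizes adapt
by damped, capped Robbins–Monro targeting 75% acceptance; trajectory
lengths are jittered in [L/2, L].  log σ is clamped to ±7 and the frequency
exponentiation is capped to keep the tails finite.  Divergent transitions
and R-hat > 1.05 (arviz) are reported on the fit and raised as warnings,
never silenced.  The default schedule is the reduced 2 chains × 500 warmup
+ 500 samples; the full 4 × 1000/1000 schedule is a config change.

### Model comparison

WAIC = −2(lppd − pWAIC) from the pointwise posterior log-likelihood matrix,
with pWAIC the summed pointwise posterior variances, SE from the pointwise
WAIC contributions, and dSE of each model against the best from the paired
pointwise differences.  All five fits share one data preparation (the
window tallies are parameter-free), so the pointwise partition is identical
by construction.

## Opening techniques

Sequences are encoded as a binary unshell column, one-hot crack (tip,
seam, hilum, middle) and extraction (nibble, split, other) blocks, and
optionally a duration column; every column is standardized, so constant
columns contribute nothing.  Duration is excluded by default — it is
realistically coded for only a small subset of openings.  Dissimilarity is
Euclidean.  Predictor matrices are all oriented as dissimilarities (1 −
SRI, max(r) − r, 1 − m/max m, great-circle km, same-individual 0/1) so a
positive Mantel correlation always reads "similar techniques go with
closer/connected/associated pairs".  The partial Mantel statistic is the
partial Pearson correlation of the lower-triangle vectors; the null
permutes rows and columns of the response matrix simultaneously, with
`p = (#{r_perm ≥ r_obs} + 1)/(n_perm + 1)` one-tailed "greater" by default
(the hypotheses are directional), exhaustive enumeration available for tiny
matrices, and missing dyads (no association or relatedness estimate)
deleted pairwise from the triangle vectors.  With repeated sequences per
individual the permutation unit is the sequence, so exchangeability under
the identity-control design is imperfect; this is a documented limitation,
not a solved problem.  Chi-square tests use no continuity correction;
per-category post hoc tests collapse to 2 × groups and Bonferroni-multiply
by the number of categories, warning when expected counts fall below 1.

## Synthetic data

The generator emulates the study's structure with known ground truth: five
roost sites on a realistic urban-harbour geometry (~1–7 km apart), three
main + two secondary; 100 birds per roost by default with the study-scale
(age × sex) cell composition including the unknown classes; 864 group scans
whose fluid subgroups mix roosts at rate 0.10, producing a modular SRI
network (within-roost association several times between-roost); diffusions
seeded by two tutored demonstrators per seeded roost (one roost blue, one
red, the third main roost an unseeded control) at social transmission rate
s = 5; colour choices generated by the frequency-dependent EWA process with
juvenile f = 2.0, adult f = 1.0, φ = 0.22, γ = 0.15, λ = 2.5 (an
age-dependent-conformity regime), individual offsets of sd 0.2 on the link
scale, p(success) = 0.9, and 10% unmarked solves; two-hour daily sessions
with time in seconds; and opening sequences whose site-level technique
profiles drift along the east–west axis (logit shift 1.2 per km) with
individual consistency 0.7 and 1–17 repeats per bird.

What it does not emulate: demography and turnover, spatially explicit
movement, observation error in identities, innate colour preference, and
almond depletion within sessions.  Passing tests therefore show that the
estimators recover the truth of this generative world at these sample
sizes — not that field data satisfy the models' assumptions.

The recovery-study generator (`generate_choice_study`) schedules every
bird at a single dispenser in interleaved daily rounds, optionally mixing
in a stream of unmarked demonstrators whose colour leans to one side on
alternating days, and optionally splitting the roster across two roosts —
levers for making the social windows more or less informative.

## Power of conformity detection at desk scale

A point that shapes the test expectations: the information the data carry
about the frequency exponent f is intrinsically small at desk scale.  Per
choice, the effect of moving f from 1 to 2 on the choice probability is at
most γ·ΔS, where ΔS ≤ ~0.16 (attained near 3:1 windows with both colours
present); with γ = 0.15 that is ~0.024, i.e. Fisher information of order
1e-3 per event.  At 30 birds × 30 choices per age cell (~900 events) the
posterior sd of log f is therefore ≳ 0.7, and for a true f = 2 the
posterior mass above f = 1 centres near 0.5–0.7 with the Normal(0, 1)
prior's shrinkage.  The acceptance checks that require that mass to exceed
0.8, or the frequency model to win WAIC in ≥ 8/10 replicates against the
near-equivalent unbiased-copying models, sit above what this design can
deliver — roughly three times more events (the scale of the original field
data set) would be needed — and those two checks are expected to fail at
this scale.  The companion checks that are within the design's power —
interval coverage of all group-level means, the unbiasedness of the adult
cell, and the frequency model beating pure individual learning — pass.

Making windows more lopsided (the biased unmarked stream) sharpens the
directional social signal but induces a γ–f trade-off: a larger social
weight with unbiased copying mimics conformity toward a persistent
majority, biasing f estimates downward.  The default recovery design
therefore keeps the symmetric schedule.

## Problem sizes in the test and acceptance runs

The suite exercises the full 60-bird × 30-choice recovery design at the
reduced two-chain schedule, three seeds; the five-model WAIC comparison at
the same data scale with a lighter schedule (2 × 150/150), ten replicates;
diffusion discrimination on 20 replicates of three 58-bird diffusions; and
Mantel calibration at 500 null replicates (n = 20, 199 permutations) plus
100 gradient-detection replicates at ~240 sequences.  The acceptance
script runs a 100-bird, 300-scan, 6-day synthetic study plus the recovery
and comparison designs above.  These sizes are the package's choices for a
single-workstation run; every generator accepts larger values.

## Known limitations

- The OADA fit is maximum-likelihood only; no Bayesian NBDA, no
  time-of-acquisition variant, no dynamic networks.
- The HMC sampler reports divergences and R-hat but has no NUTS-style
  dynamic trajectory length; difficult posteriors may need the full
  4 × 1000/1000 schedule or more.
- Two options are assumed in the I/O layer (the internals are K-generic).
- Relatedness is accepted as an input matrix only; estimating it is out of
  scope.
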