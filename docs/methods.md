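# Methods

## The measurement

A session consists of three 900-second phases: a solo phase (PRE), a
face-to-face phase (F2F) in which a second bird is visible and audible,
and a second solo phase (POST).  Analysis operates on annotated call
events (caller, onset, offset, vocal type) and, within each session
phase, on the sequence of *transitions* between consecutive calls.  A
transition is an *exchange* when the caller changes and *repeated*
otherwise; its interval is offset-to-onset, so overlapping calls yield
negative intervals.  Transitions are built strictly within a
(session, phase) block and pooled across sessions without session
covariates; exact onset ties (never observed at 1 ms precision) are
broken by caller id.

## Log-interval mixture decomposition

Intervals are log-transformed in base 10 — chosen so that the antilog
of a component mean reads directly in seconds (e.g. `10^-0.728 =
0.187 s`) — after excluding non-positive intervals.  Negative intervals
are overlaps; a zero interval has no logarithm and is excluded on the
same grounds (it occurs with probability zero in annotated data, though
the simulator's listen-before-calling rule can produce it by
construction).  Exclusions are counted and reported.

The two-component unequal-variance Gaussian mixture is fitted by EM
(scikit-learn's `GaussianMixture`), best of 10 initializations,
convergence tolerance 1e-8 on the per-sample log-likelihood change, up
to 5000 iterations, variance floor 1e-6 (log10 s)².  The number of
components is fixed at two by design — short (response-like) and long
(independent calling) — and never selected from the data.  Components
are relabelled after fitting so `mean_short < mean_long`.  Caveats of a
forced two-component fit: on unimodal data EM still splits the sample
into two broad overlapping components (roughly ±1 SD apart), so a
fitted "short" component is evidence of a response mode only when it is
both substantial in weight and concentrated in variance; the tests
encode that distinction.

## Percentile-interval comparison

Two conditions are compared through their fitted component normals: per
repetition one value is drawn from each, the difference recorded, and
the central 95% interval taken as the 2.5th/97.5th empirical
percentiles (linear interpolation between order statistics) of 10,000
differences.  A difference is "significant" only if the interval
excludes zero; no p-value is computed.  The closed form for the
difference of independent normals,
`(mu_a - mu_b) ± 1.96 sqrt(var_a + var_b)`, is the infinite-repetition
limit and anchors the tests (Monte-Carlo SE of a 2.5th percentile at
10,000 reps is ~0.0064 for the main comparison).  The difference
direction is recorded explicitly with each interval because sign
matters when matching bounds across differently ordered comparisons.
Note that when the two means are equal, zero is the median of the
difference distribution and is covered by the central interval
essentially always — not 95% of the time; the 95% figure describes the
interval's mass, not a coverage probability for zero.

One published input deserves a flag: the POST-phase short component is
reported as mean −0.074, variance 0.334, an order of magnitude apart
from every other short-component mean (~−0.7) yet numerically
consistent with the interval reported from it.  The package reproduces
the computation from the values as printed and takes no position on
their provenance.

## Pseudo-turn-taking null

The null asks whether the short exchange mode could arise from two
independent callers.  Each subject's F2F track is re-paired with the
facing bird's track from a different session of the *same ordered
pair* (subject/facing roles preserved — the strictest reading of
pair-consistency), using a seeded uniform random derangement of the
pair's session indices so no pseudo session reproduces a real one.
Tracks keep their own phase-relative clocks; no time offset is added.
Marginal call-time multisets are exactly conserved by construction.
Each ordered pair therefore needs at least two sessions; the
experiment's design (four sessions per pair, subject role alternating)
provides two per ordered pair.

## Call-count model

Subject call counts per (subject, trial, phase) cell are modelled as
Poisson with log link, phase as the fixed effect (PRE as reference, so
F2F and POST coefficients are log rate ratios), and independent
Gaussian random intercepts for subject and trial.  "Trial" is the
session (the sampling unit); both random intercepts are retained in the
null model, which drops only the phase effect.  The marginal likelihood
uses the Laplace approximation: for candidate variances, Newton
iteration finds the joint conditional mode of fixed effects and random
intercepts on the penalized Poisson log-likelihood, and the
random-effect block of the Hessian supplies the curvature correction;
the two log-variances are optimized by Nelder-Mead.  This matches the
default approximation of standard mixed-model fitters, and the test
suite cross-checks log-likelihood and coefficients against lme4's
`glmer` (agreement to ~1e-4) and against an ordinary Poisson GLM in the
zero-variance limit.  AIC is `-2 loglik + 2k` with `k` = fixed effects
plus two variance parameters; model selection is minimum AIC with exact
ties going to the first candidate and recorded.  A fit whose variance
collapses to ~0 is flagged singular but returned.

## Simulator

The generator emulates the study's conditions: 900 s phases, 24.7 ms
calls, and two interval regimes.  Each bird calls spontaneously as a
renewal process with log10-normal gaps (default mean 0.45, SD 0.6 on
the log10 scale, i.e. median ~2.8 s); on hearing the partner's call
offset it schedules, with probability `response_prob` (default 0.5), a
response after a log10-normal latency (default mean −0.73, SD 0.15,
i.e. median ~0.186 s).  Responses trigger on the partner's *offset*
because measured intervals are offset-to-onset: a response latency maps
directly onto the exchange interval it produces, which makes mixture
recovery a sharp test.  Constraints: a refractory window (default
50 ms ≥ one call) suppresses responses and defers spontaneous calls; a
spontaneous call or response never starts while the partner is audibly
mid-call (it is deferred to the partner's offset), so between-bird
overlap is impossible when latencies exceed the call duration — the
analogue of the near-absence of overlap in the real data.  A pending
spontaneous call is rescheduled, not cancelled, after a response fires,
keeping marginal rates interpretable.

`baseline_rate` rescales the spontaneous-gap distribution so its mean
gap is `1/baseline_rate`; `None` keeps the natural rate of the default
gap distribution (~0.14 calls/s, ~123 calls per solo phase), and `0`
silences spontaneous calling.  `simulate_experiment` reproduces the
sampling design (six birds, all 15 pairs, four sessions each, subject
role alternating, 60 three-phase sessions) with optional per-phase and
per-subject rate multipliers for count-model recovery studies.  The
"strong contagion" condition used in the null-behaviour tests is
`response_prob = 0.7`.

What the simulator does *not* emulate: real annotation noise, vocal
types other than calls, diurnal or motivational nonstationarity,
asymmetric dyads, anticipatory (as opposed to reactive) timing, and
flocks of more than two birds (the API accepts bird lists but only
dyads are exercised).  Passing tests therefore demonstrate that the
pipeline recovers the generative structure it assumes — not that real
birds follow that structure.

## Numerical and testing choices

- All randomness flows from explicit seeds; the pipeline derives
  per-stage seeds from one root seed, and reports are byte-identical
  across reruns.
- Test problem sizes were chosen to keep Monte-Carlo noise well inside
  the asserted tolerances: 5,000-draw mixture fits (20 seeded
  replicates), 20 pooled simulated sessions (~9,000 exchange
  transitions) for end-to-end latency recovery, five replicate
  experiments for count-model recovery.
- The pseudo-density monotonicity property is asserted over (0, 5] s in
  0.5 s bins; beyond that, bins are Poisson-sparse and 3-sigma bumps
  arise by chance.
- Annotator matching (undescribed in most labelling workflows) is
  greedy nearest-onset within a 0.5 s window, one-to-one, closest pair
  first; unmatched segments count as disagreements, and `n_all` counts
  matched pairs once plus unmatched segments from either side.
  Agreement requires identical vocal type AND caller.
- Degenerate inputs: mixture fits refuse fewer than four values or an
  all-identical sample; comparisons refuse unconverged fits and
  non-positive variances; a constant delta vector yields a zero-width
  confidence interval; an empty interval list has no within-threshold
  fraction.
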