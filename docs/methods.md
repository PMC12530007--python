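# Methods

## Model overview

`thialloc` models a female salmonid from one year before her first
spawning.  Her physiological state is the pair (c_g, c_m): free-thiamine
concentration in the gonads and TDP concentration in the muscles, nmol/g
wet weight, both clamped to a ceiling c_x = 30 nmol/g.  Each day she
allocates the entire free-thiamine pool of her blood, c_b · w_b nmol,
between the two tissues with a fraction alpha to muscles (converted to TDP
with efficiency q_m = 0.9) and 1 − alpha to gonads.  Renal excretion
removes thiamine from each tissue at a mass-specific rate k(c) that
depends on that tissue's concentration.  Muscle TDP buys daily survival,
gonadal thiamine buys offspring recruitment at spawning, and (for
iteroparous females) muscle TDP also buys survival of the post-spawning
migration.  The allocation strategy alpha(day, year, c_g, c_m) is the
decision variable; it is optimized by stochastic dynamic programming and
then handed to a forward Monte-Carlo simulator.

The model does not track liver storage, a TMP pool, energetics, food
intake, temperature, density dependence, or male strategy.  Thiamine
input is exogenous: it neither responds to the allocation strategy nor to
muscle state, reflecting the view that limitation is a property of the
environment (food-web transfer, thiaminase exposure, antioxidant
consumption) rather than of the individual.

## State dynamics

The daily update is an explicit Euler step on tissue *amounts* (nmol):

    A_g' = c_g w_g + (1 − alpha) c_b w_b − k_g(c_g) w_g
    A_m' = c_m w_m + q_m alpha c_b w_b − k_m(c_m) w_m

evaluated at the start-of-day state, floored at zero (loss cannot exceed
content), and divided by the *next* day's tissue mass, so somatic and
gonadal growth dilute concentrations.  Concentrations clamp at c_x; the
clamp discards surplus inflow and both floor and clamp events are counted.
Writing the balance in amounts rather than concentrations keeps the
bookkeeping dimensionally consistent when masses change; with excretion
disabled the combined gonad + muscle amount gain per day is exactly
c_b w_b (alpha q_m + 1 − alpha), which the tests assert to 1e-9 over a
200-day growing-tissue chain.

## Response functions

* Recruitment: r(c_g) = (c_g/c_x)^v.
* Daily survival: p(c_m) = p0 + (px − p0)(c_m/c_x)^u.  The bounds are
  derived, not set: p0^365 = 0.001 and px^365 = 0.25, i.e. a female pinned
  at zero muscle TDP survives a year with probability 0.001, one at the
  ceiling with probability 0.25.
* Migration survival: p_f(c_m) = (c_m/c_x)^l with l = 0.2.
* Loss rate, three laws:
  - `sigmoid` (baseline): k = k_x [((b−1)/(b+1)) b^((0.5c_x − c)/0.5c_x) + 1]^−1,
    shape b = 200 by default — renal reabsorption retains thiamine at low
    concentration, active secretion clears it at high concentration, with
    a steep transition at the half-ceiling.
  - `reabsorption_passive`: k = a c^{b_c} below a threshold c_t and
    k = k_x c / c_x above it, with a = k_x c_t / (c_x c_t^{b_c}) fixed by
    continuity at c_t (asserted to 1e-12).  This is the no-active-secretion
    variant used when comparing against field data; presets span
    b_c ∈ {3, 6}, c_t ∈ {6, 10} nmol/g.
  - `linear`: k = k_x c / c_x, the null model with no transporter
    saturation.
  Maximal rates are k_x = 0.5 (gonads) and 0.35 (muscles) nmol/g/day — the
  phosphorylated muscle form is lost 30% more slowly.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| c_x | 30 nmol/g | tissue concentration ceiling |
| k_x_g, k_x_m | 0.5, 0.35 nmol/g/d | maximal loss rates |
| q_m | 0.9 | free-thiamine → TDP conversion efficiency |
| u, v | 0.025, 0.025 | survival / recruitment shape exponents |
| l | 0.2 | migration-survival exponent |
| b | 200 | sigmoid steepness |
| b_c, c_t | 3, 6 nmol/g | reabsorption shape / passive threshold |
| c_b_mean | 2 (limited) / 6 (replete) nmol/g | mean blood thiamine |
| c_b_halfwidth | 2 nmol/g | stochastic input half-range |
| beta_shape | (4, 4) | daily input distribution (symmetric, unimodal) |
| days_per_year, d_s | 365, 365 | calendar; spawning on the last day |
| i_max | 15 | maximum number of years |
| c_g_init, c_m_init | 0, 15 nmol/g | initial state of every female |
| N | 1000 | simulated population size |

The survival/recruitment exponents are small because both responses model
saturation of an enzymatic cofactor: most of the fitness gain accrues at
low concentrations.  u = v = 0.025 is the package baseline; it produces
every qualitative regime the model is known for (see below), and the
steeper alternatives remain available through
`presets.survival_recruitment_scenario(u, v)`.

Growth.  Somatic (= muscle) mass follows a saturating curve from 2 kg
toward 9 kg at rate 8e-4/day; blood is a fixed 6% of somatic mass; gonads
ramp linearly over the final 120 days of each year to a gonadosomatic
index of 0.20 at spawning, then reset to a 1 g epsilon mass when the eggs
(and their thiamine) leave.  A `fixed` growth mode freezes somatic mass
for capital breeders that do not grow after maturation.  The blood
fraction deserves a note: because the whole blood pool is the daily
allocatable input, c_b · blood_fraction · q_m is the maximal per-gram
muscle inflow.  At 6% the replete scenario (c_b = 6) equilibrates muscle
TDP near 22 nmol/g — approaching the ceiling while retaining the
between-female variation the correlation analysis needs — and the limited
scenario (c_b = 2) equilibrates just below the sigmoid's midpoint, with
some females drifting to very low levels.  Larger fractions pin the
replete population at the ceiling clamp (zero variance); much smaller ones
starve every scenario.

Spawning-day semantics.  The spawning reward r(c_g) · w_g(d_s) is
collected from the start-of-day state at d_s; daily survival multiplies
the within-year recursion on days 1..d_s−1; the year transition applies
the migration survival p_f (iteroparous) or ends the line (semelparous)
and resets gonads to (c_g = 0).  When d_s < days_per_year the model year
simply ends at spawning.

## Optimization numerics

Backward induction runs on a regular (c_g, c_m) grid (default step
0.5 nmol/g, 61 × 61 nodes) with an allocation grid of step 0.05.  The
expectation over the stochastic daily input uses equal-weight quantile
midpoints of the beta distribution (default 5 nodes; 1 node recovers a
mean-input backward pass).  Off-grid next states are evaluated by bilinear
interpolation of the value surface; because each tissue's transition
depends only on its own concentration, one day's expected value reduces to
two 1-D interpolation stencils applied to the rows and columns of the next
day's surface, which is what makes full-resolution runs fast.  Ties in
alpha break toward the smaller value (less muscle allocation).
Correctness is pinned by an exhaustive-enumeration oracle on randomly
generated tiny instances whose dynamics land exactly on grid nodes (unit
masses, zero loss, half-unit inputs), where the DP value must match brute
force to 1e-12; the value surface is additionally required to be monotone
in both state coordinates, and refining the allocation grid may never
decrease it.

The forward simulator draws each female's daily input independently
(continuous beta draws), looks her alpha up by bilinear interpolation of
the policy, and applies the same daily update.  Mortality is not applied
as removal — survival shapes the policy through the optimizer, but the
correlation panels need the full population — an optional flag records a
death year per female for demographic output.  Runs are bit-reproducible
given (seed, parameters, policy).

## Correlation analysis and the detection rule

Each simulated day, muscle TDP is regressed on gonadal thiamine (OLS,
gonads as predictor) across females with c_g > 0, but only when more than
2/3 of the population qualifies and the spread of included concentrations
exceeds 0.5 nmol/g *in both tissues*; a fitted day is reported when
R² > 0.2.  The both-tissues reading of the variation filter matters: after
the population completes its allocation switch, muscle spread collapses
toward numerical noise while gonadal spread balloons, and a
predictor-only filter would report a long tail of degenerate near-zero
slopes in every scenario.

A season is classified as carrying a correlation signal only when the
reporting is *sustained*: at least 10 reported days of a given sign.
Isolated reported days occur at an abrupt allocation switch (a 1–3-day
state-dependent stagger in switch timing briefly correlates the tissues
before stochastic input washes it out) and would never be sampled reliably
in the field.  The rule is fixed and applied uniformly to every scenario.
"Slope rises toward spawning" is evaluated over the allocation-transition
phase (up to the day population-mean alpha first falls below 0.05) with
Kendall's tau, because after the full switch the predictor variance
inflates mechanically and slopes shrink toward zero regardless of
mechanism.

Under these rules the model's qualitative regimes are:

* sigmoid loss, limited input → sustained positive slopes, rising toward
  spawning; replete input → sustained negative slopes;
* linear loss → no sustained signal at any input (abrupt, synchronized
  switch);
* reabsorption-only loss → sustained positive slopes at limited input for
  all four shape presets, none at replete input;
* semelparous females → signal only at limited input; none at
  intermediate or high input.

Empirical-style tissue tables are analyzed with Spearman rank
correlations (midranks for ties) per system and/or life stage; groups
under three rows are flagged and get no p-value.  No multiple-testing
correction is applied.

## Synthetic tissue tables

`generate_tissue_dataset` emulates the *structure* of a two-system salmon
tissue dataset — per-female muscle and gonad total thiamine, labeled by
system (limited vs replete), river (assigned round-robin from Baltic and
North-Atlantic river names), and migration stage — by running the full
optimize + simulate pipeline under each system's parameters and sampling
females at stage-specific calendar days (defaults: feeding ≈ 6 months,
river mouth ≈ 3 months, upstream ≈ 1 month before spawning, and the
spawning day itself; these are conventions of the generator, not data).
The default system parameters use the reabsorption-only law with b_c = 3,
c_t = 10, whose predicted correlation persists across the late stages.
Multiplicative lognormal measurement noise (default CV 10%, the scale of a
real thiamine assay) is applied per tissue.

One caveat the tests make explicit: the model population is far more
homogeneous than real fish (between-female spread ~0.15 nmol/g at a
~9 nmol/g mean, versus several-fold ranges in the field), so
assay-realistic noise obliterates the rank signal in synthetic data even
where the underlying correlation is rho ≈ 0.9.  End-to-end validation
therefore samples at noise_cv = 0, which checks the mechanism and the
analysis path; it does not show that the indicator would survive any given
empirical noise level — that depends on real between-female heterogeneity
the model does not attempt to match.  For the same reason simulated
concentration values should not be compared numerically with published
tissue measurements.

## Problem sizes

Full-resolution runs (61 × 61 state grid, 21 alpha levels, 5 input nodes,
15 years) take a few minutes per policy.  The package's end-to-end checks
and examples use a desk scale chosen to finish in seconds to minutes:
the same state grid with alpha step 0.1 and 3 input nodes, N = 500
females, and analysis of the first pre-spawning year.  All qualitative
regimes above are stable at this scale across seeds; `presets.desk_scale`
applies it without touching any science parameter.

## Known limitations

* Growth trajectories are generic saturating/linear shapes calibrated to a
  plausible gonadosomatic index, not fitted to any measured salmon series.
* The beta input distribution's shape (4, 4) and the state/allocation grid
  resolutions are package choices; the underlying study conditions leave
  them open.
* The gonad-ramp start creates a brief window where tiny gonad masses can
  saturate instantly under even small allocation; the epsilon reset mass
  (1 g) keeps concentrations defined but its exact value is arbitrary.
* Whether egg release removes maternal thiamine beyond the gonadal content
  is unmodeled; only gonad content leaves.
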