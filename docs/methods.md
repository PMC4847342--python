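# Methods

## Model structure

The core is an annual-cycle Markov cohort model of a **closed** national
adult population (aged 35+ in the 2011 base year, 2.3 million people by
default), cross-classified into 52 strata: 13 five-year age bands
(35–39 … 95+) × 2 sexes × 2 ethnic groupings (Māori / non-Māori). Four
health states are modelled — Healthy, CHD, Stroke, Dead — with Dead
absorbing, no recovery transitions, and no combined CHD+stroke state:
the first qualifying event assigns the state, and people with a prior
event who suffer the other disease remain in their first-assigned state
(a model-structure simplification shared by this model family; its
uncertainty is not captured by the probabilistic analysis).

Each stratum starts at the midpoint age of its band (e.g. 37 for 35–39)
and is initialised across Healthy/CHD/Stroke by the stratum's disease
prevalences. Cohort age advances one year per cycle and rates are always
looked up in the five-year band containing the *current* age, which
avoids step artefacts when a cohort crosses a band boundary. Simulation
stops at death of the cohort or age 100, whichever comes first;
person-years at ages ≥ 100 accrue nothing.

### Transition probabilities

All inputs are stored as annual **rates**; conversion to probabilities
(`p = 1 − exp(−r)`) happens only in the engine. Each destination rate is
converted independently and the stay-probability is the residual; a
negative residual (probabilities summing above one, which cannot happen
for realistic inputs) raises an error naming the stratum-year. Background
mortality — with the CVD-attributable share removed from the input —
applies in every alive state; in the disease states the disease's
case-fatality rate is added to the background rate before conversion.
Case fatality is a single annual rate (no first-year elevation, no
28-day acute sub-cycle).

Secular trends: CHD and stroke incidence and case fatality decline 2.0 %
per year, and background mortality 1.75 % (non-Māori) / 2.25 % (Māori)
per year, from 2011 out to 2026; thereafter all rates are held constant.

### Intervention effect chain

A target is a set of food categories with intake shares (fraction of
total dietary sodium) and within-category fractional cuts; the
population-level reduction is the share-weighted sum. On the default
8.4 g/day salt baseline this is converted to mmol/day of sodium
(1 g NaCl ≈ 17.11 mmol Na), ramped linearly over the phase-in period
(3 years mandatory, 5 voluntary; the ramp is evaluated at mid-cycle,
t + ½), translated to a systolic blood-pressure fall via an age-band
dose-response β (default 3.5 → 6.5 mmHg per 100 mmol/day from the
youngest to the oldest band), and then to relative risks of *first*
events via `RR = 0.5^(ΔSBP/H)`, with halving constants H defaulting to
19 → 31 mmHg (CHD) and 14 → 26 mmHg (stroke) across bands — the
conventional shapes: salt sensitivity rises with age, the SBP–risk
association weakens with age and is stronger for stroke than CHD. The
relative risks apply to incidence only, not to case fatality. All
coefficients are configuration (`effect_chain.yaml`), not code; the
shipped values are documented approximations, and a hook exists for
making the dose-response depend on baseline SBP centile (unused by
default).

## Economics

QALYs weight each alive person-year by
`1 − background_pYLD − disease_YLD(state)`, both morbidity terms being
prevalent years-lived-with-disability per capita / per prevalent case on
the 0–1 disability scale, looked up at the cohort's current age band.
Costs comprise: annual background cost in the Healthy state (CVD share
removed to avoid double counting), a first-year cost on each new disease
entrant, an annual subsequent-year cost on continuing prevalent cases, a
one-off last-six-months-of-life cost charged at the cycle of death, and a
programme cost charged annually during the phase-in. The public-share
scale-up (1.2 = 1/0.83) and the old-age multipliers (1.1 / 1.2 / 1.3 for
65–74 / 75–84 / 85+) are applied exactly once to every cost item,
including end-of-life costs. Both QALYs and costs are discounted at
3 %/year to 2011 (0 % and 6 % as scenarios).

By default each person alive at the start of a cycle accrues the full
cycle-year (half-cycle correction off); a `half_cycle` flag switches the
accrual basis to the average of start- and end-of-cycle occupancy. New
disease entrants cannot die of their disease in the entry cycle (case
fatality is applied from the next cycle), a one-half-cycle simplification
consistent with the no-half-cycle default.

Incremental results subtract the "do nothing" comparator run (identical
inputs, no intervention, no programme cost). Net cost decomposes exactly
into averted disease costs (negative), added background costs from extra
life-years (positive), end-of-life cost shifts, and the programme cost —
an accounting identity asserted in the tests. Per-adult results divide
each subgroup's incremental totals by its base-year population.

## Synthetic inputs

The generator (`sodiumcea.synthetic`, parameter set `NZ_LIKE_DEFAULTS`,
version 1) emulates the *structure* of the national administrative data
this model family consumes, not its values:

- **Population**: 2.3 M adults; band weights declining with age (strictly
  above 65), Māori share falling and female share rising with age.
- **Incidence**: log-linear in age (doubling every 2 bands = 10 years),
  CHD base 0.8/1000 at 35–39 with ×1.8 male and ×2.0 Māori excess;
  stroke base 0.4/1000, ×1.25 male, ×1.5 Māori.
- **Case fatality**: doubling every 3 bands from 0.020 (CHD) / 0.035
  (stroke), ×1.3 Māori. **Prevalence**: incidence × mean duration
  (10 y CHD, 7 y stroke), capped.
- **Background mortality**: Gompertz-like (doubling every 7.7 years of
  age), ×1.4 male, ×1.8 Māori.
- **Morbidity**: background pYLD 0.04 + 0.012/band (+0.03 Māori);
  per-case YLD 0.12 (CHD) / 0.22 (stroke).
- **Costs** (2011 NZ$-like): first year 15,000 / 22,000, subsequent years
  5,500 / 9,000 (CHD/stroke, the diseased person's full annual cost),
  healthy background 1,800 + 180/band, last six months 25,000.
- A small lognormal jitter (log-sd 0.05) per sex×ethnicity cell makes
  different seeds produce different but structurally identical worlds;
  jitter is deliberately constant across bands so the constructed age
  gradients — and the monotonicity invariants that rely on them — hold
  exactly. Generation is byte-reproducible given the seed.

What the generator does **not** emulate: real rate levels and
correlations, cohort effects, within-stratum heterogeneity, open-cohort
demography, or under-35s. Passing tests therefore demonstrate the
*machinery* (structure, accounting, monotonicities, cross-model
agreement), not empirical national results; absolute QALY and cost
figures from the default world are illustrative only.

### Intervention share table

The fraction of dietary sodium by food category is not publicly
available, so the default shares are synthetic and calibrated once so the
published category-level percentages are reproduced exactly: packaged
foods 62.5 % of sodium with a 36 % within-category cut, fast food /
restaurant 18.75 % at 40 %, discretionary 12.5 % at 40 % — composing to a
35 % overall reduction for the full target. Within packaged foods: bread
11 % (25 % cut), processed meats 9 % (45 %), sauces 8 % (45 %), snacks
3.5 % (41 %), other bakery 4.5 % (58 %), cheese 4.5 % (33 %), residual
packaged 22 % (cut solved at ≈29.9 % so the packaged aggregate is exactly
36 %). Published within-category ranges (e.g. bread 12–37 %) are
collapsed to one share-weighted reduction; the schema accepts
sub-categories for finer work. Intervention 7 is the fully additive
combination of the bread, processed-meat and sauce targets.

## Uncertainty specification

The PSA samples eight independent multiplicative parameters per draw and
re-runs both model arms: achieved sodium reduction (normal, sd 10 %
mandatory / 20 % voluntary — the mode difference reflecting the greater
compliance uncertainty of voluntary programmes), SBP dose-response
(lognormal, log-sd 0.25), CHD and stroke halving constants (0.15 each),
CHD and stroke disease costs (0.10 each), disease YLD (0.10) and healthy
background cost (0.03). These magnitudes are the package's uncertainty
specification, set so that effect-chain uncertainty dominates — which is
what makes QALY and cost increments strongly, linearly correlated across
draws (|r| ≈ 0.83 on defaults) while disease-cost uncertainty still ranks
among the top drivers of the cost tornado. Intervals are percentile
(2.5th–97.5th) with 2,000 draws by default; the tornado uses one-at-a-time
sweeps of each parameter to its 2.5th/97.5th percentile around the
expected-value base case, sorted by output range.

## Validation oracles

Two independent cross-checks run on the same input files:

- a **multi-state life table** that shares no transition-assembly code
  with the engine: exact competing-exponential survival within each year
  (the engine instead converts each destination independently and takes
  the residual) and trapezoidal person-years (the engine's default
  accrues full years at cycle start). On the standard validation
  intervention — a uniform 22.8 mmol/day sodium cut with no phase-in —
  the two models agree on QALYs gained within ~1.4 % on the default
  world (tolerance 7 %). Comparator life expectancy agrees within 1 %
  when the engine's half-cycle accrual flag is used, the matched
  person-year convention.
- an **individual-level microsimulation** that consumes the engine's own
  per-cycle transition probabilities, with common random numbers across
  arms; its mean QALY gain is an unbiased estimate of the cohort-model
  value and is asserted within 3 standard errors (n = 10,000).

## Numerical and design choices

- Competing first events within a cycle are resolved by independent
  rate-to-probability conversion with the residual on the diagonal; the
  MSLT's exact allocation quantifies the (small) difference.
- Integer population counts are produced by largest-remainder rounding,
  so stratum counts always sum exactly to the requested total.
- Degenerate inputs are handled explicitly: zero rates give identity
  transitions (Dead still absorbing), a zero-variance PSA parameter is a
  point mass, zero phase-in means full effect from the first cycle.
- Problem sizes in the shipped tests and acceptance script — 2.3 M
  cohort (cost-free: the engine is proportion-based), 400–2,000 PSA
  draws, 10,000 microsimulation individuals — were chosen as the sizes at
  which the reported quantities are stable to well within the asserted
  tolerances.
- Programme costs (regulation/reformulation support: $2.0 M/yr mandatory,
  $1.5 M/yr voluntary during phase-in) are order-of-magnitude
  placeholders; they are negligible against disease-cost flows at
  national scale, which is why all twenty default runs are cost-saving at
  0, 3 and 6 % discounting.

## Limitations

Beyond the synthetic-data caveats above: no stomach-cancer or renal
pathways for sodium, no potassium-substitution co-benefits, no consumer
substitution or industry flavour compensation, no productivity or other
non-health-system costs, no recurrent-event counting, and no uncertainty
on phase-in durations. The "do nothing" comparator removes existing
low-impact sodium programmes, so it is close to, but not identical with,
current practice.
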