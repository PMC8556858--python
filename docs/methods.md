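# Methods

## Model structure and assumptions

The model is a discrete-time Markov-type chain over six states
(not-using, using outside, using in-site, treatment/recovery, nonfatal
overdose, fatal overdose) with one deliberate departure from the
Markov property: entry into the in-site using state is capped by the
site's capacity, so that transition probability depends on how many
people are attempting entry at the same step.

Key structural choices, and why:

* **A use occupies exactly one 30-minute step.**  The source material
  for the model states only "four uses a day"; treating each use as an
  intra-step excursion (initiate, resolve, return within one step)
  keeps the expected use count at exactly `uses_per_day × 365 = 1460`
  per person-year and reproduces the saturation arithmetic for the
  site (capacity × open steps uses per year).  A person who overdoses
  nonfatally instead spends the following step in the recovery state.
* **Overdose hazard is attached to use events, not clock time.**  The
  per-use probabilities solve `1 − (1 − r)^1460 = p_annual`, i.e. the
  annual rates are read as per-person probabilities of at least one
  event.  Because the simulation counts *events* (people keep using
  after a nonfatal overdose, and the dead are replaced by entrants at
  a similar rate), the population-level expectation is
  `55 000 × 1460 × r` ≈ 1044 fatal and 3932 nonfatal events per year —
  the model's calibration values of ~1045/~3933.
* **Rate conversion by complement compounding.**  Annual treatment
  entry and relapse probabilities become per-step hazards via
  `q = 1 − (1 − p)^(1/17520)`.  Only this convention yields the
  ~13,000-person treatment equilibrium (`55 000 · q_in/q_out`); naive
  division by the step count would give 16,500.
* **Treatment entry applies from the not-using state each step.**
  Users spend the overwhelming majority of steps there, so the annual
  aggregate remains ≈15%.  Direct referral probabilities from the
  in-site and post-overdose states exist as parameters
  (`ops_referral_prob`, `od_referral_prob`) and default to 0, since no
  magnitude for them is established.
* **Rejected entrants use outside in the same step.**  Deferring the
  use instead would distort the fixed daily use budget.
* **No fatal overdoses inside the site.**  The in-site per-use
  overdose probability is `ops_od_proportion × (p_fatal + p_nonfatal)`
  and every in-site overdose is reversed.  At proportion 1 the site
  therefore converts fatal overdoses into survived ones one-for-one,
  which is why total nonfatal counts *rise* with capacity until
  in-site safety measures (proportion < 1) compensate.
* **Opening hours** are modeled as the first 40 of the 48 daily steps.
  Under the demand levels of interest the site is saturated whenever
  open, so which specific hours are open is immaterial.
* **New entrants** arrive as Poisson events at 3/day, landing in the
  not-using state, allocated over rings by population proportion —
  approximately balancing fatal exits.

## Geography

Distance from the site is discretized into 13 contiguous rings
matching the published visit-probability table; the printed table
skips the (3, 3.5] mile band, which is filled by geometric
interpolation of its neighbours (scale ≈ 0.0677), the value an
exponential decay law implies.  Ring membership uses the half-open
convention `(a, b]` with the first ring closed, so a distance exactly
on a boundary belongs to the inner ring.  A least-squares exponential
fit through `scale(0) = 1` on the log scale recovers a decay rate of
~0.82/mile from the tabulated scales (largest absolute residual
≈ 0.12 — the table is not exactly exponential).

## Synthetic data

The generator emulates only what is publicly known about the
restricted record-level data:

* annual counts (1033 fatal, 3788 nonfatal),
* cumulative spatial shares (30% of users within 1 mile, 38% within
  1.5 miles), enforced *exactly* on the analytic CDF of a
  two-component mixture — exponential near-site plus uniform far-field
  on (1.5, 10] miles — by solving two equations in the decay rate and
  mixture weight,
* the published demographic marginals (e.g. 73.48% male and 69.70%
  White among fatal events); nonfatal records carry no race/ethnicity
  because none was published.

Everything else is a stand-in: ages are truncated normals around the
published means with an assumed SD of 12 years; the far-field shape
beyond 1.5 miles is uniform; demographics are independent of distance
unless an optional race-distance gradient is switched on for
demonstrations.  Consequently, passing tests validate the calibrated
quantities (counts, the two spatial shares, marginals) and say nothing
about per-ring populations beyond 1.5 miles, true joint demographic
structure, or street-level geography.  The default ring profile is
produced by binning 50,000 sampled distances, so its per-ring
proportions carry sampling noise of a few tenths of a percent around
the calibrated CDF.

## Engine and numerical choices

Counts per (state × ring) advance with exact multinomial sampling:
binomial draws for initiation, treatment flows and outside-use
resolution (fatal first, then nonfatal conditioned on survival), and a
multivariate hypergeometric draw — realized as sequential conditional
hypergeometric draws over rings — for capacity-limited admission, so
the admitted subset is uniform over all attempters.  This is equal in
distribution to simulating each person independently; the per-agent
microsimulation engine implements the same rules agent-by-agent and is
held to agree with the count engine within Monte-Carlo error in the
test suite (500 agents, shared parameters).

Replicates are vectorized: one generator advances an
`(n_replicates × n_rings)` state, and a "stacked arms" mode lets the
rows of one batch carry different values of the swept parameter
(capacity, in-site proportion, treatment-entry hazard), since per-step
cost is nearly flat in batch width.  Rows remain independent
replicates; arms within a sweep therefore share a master seed but are
statistically independent.

Alongside realized counts the engine accumulates their conditional
expectations given the use/admission trajectory: expected fatal and
nonfatal events, expected fatalities averted
(`admissions × p_fatal_use`), and the expected net change in nonfatal
counts per admitted use (`p_in_site_od − p_nonfatal_use`).  By the
tower rule these have the same means as the realized counts, with
replicate variance smaller by orders of magnitude; under saturation
the averted series is deterministic.  Sweep tables report both the raw
and the variance-reduced (`*_vr`) differences; the break-even search
interpolates the variance-reduced series, because at capacity 30 the
raw nonfatal difference (per-replicate SD ≈ 63) cannot resolve a
crossing whose full swing across the candidate band is ~3 events.
The analytic saturation crossing is
`p* = p_nonfatal_use / (p_fatal_use + p_nonfatal_use) ≈ 0.790`,
i.e. a ~21% in-site overdose reduction.

Other numerical conventions: integer apportionment over rings uses
largest-remainder rounding (exact totals, deterministic tie-break by
ring index); a conservation invariant (alive + cumulative deaths =
initial + cumulative entrants) is asserted during simulation; the
treatment pool is seeded at the rounded equilibrium unless an explicit
`initial_treatment_count` is supplied; treatment-rate sweep arms all
start from the *baseline* rate's equilibrium, so the reported effects
include the one-year relaxation toward the new equilibrium.  Stage
order within a step (initiation → admission → resolution → recovery →
treatment flows → entrants) is fixed; the per-step hazards are small
enough that ordering effects are far below Monte-Carlo error.

## Problem sizes

Default experiment scales were chosen so the full suite runs on a
single core in minutes while keeping Monte-Carlo error well below the
effects measured: 300 replicates for calibration and treatment sweeps
(SEs of ~2 and ~4 events on means of ~1045 and ~3933), 100–200
replicates per capacity arm, and 10 replicates per proportion-sweep
arm (sufficient because the break-even uses the variance-reduced
series).  The microsimulation cross-check uses 500 agents over 60
days, where event counts are large enough for a 3-standard-error
comparison with real power.

## Known limitations

* Single site, annular geography; no road networks, travel times, or
  multiple facilities.
* No disease-transmission dynamics or agent-level memory of site
  exposure.
* Referral-to-treatment effects of the site default to zero; the
  treatment-rate sweep explores the population-level counterpart
  instead.
* Within-day use patterns are uniform; results depend on opening hours
  only through the total open time while the site is saturated.
* The equilibrium the treatment sweep relaxes from assumes the entry
  rate changed instantaneously at the start of the simulated year.
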