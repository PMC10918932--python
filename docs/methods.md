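# Methods

This note records the modelling choices behind `careflow`: the flow model
and its assumptions, the synthetic-data generator, the estimators, the
numerical conventions, and the limits of what the shipped tests demonstrate.

## The flow model

The system is an open queueing network of ten service nodes across care
levels 2–5. A patient is in exactly one place at a time: waiting in one
service's queue, occupying one service's capacity, or out of the system.
Time advances in one-day steps; within a day events resolve in a fixed
order — external arrivals, completions (with transition draws), admissions,
reneging, bookkeeping. The order is a package convention: with daily
granularity some ordering must be imposed, and completions-before-admissions
lets a freed slot be refilled the same day (a freed bed is turned over
within the day), while reneging-after-admissions means a patient is only
counted as abandoning if that day's admissions did not reach them. All
invariant and oracle tests exercise this exact ordering, so it is auditable.

Assumptions inherited from the modelled system design, deliberately kept:

- **FIFO queues.** Real mental-health waiting lists are priority-ordered;
  priority queues are out of scope here.
- **One service at a time.** Concurrent care episodes are excluded; the
  miner repairs overlapping episodes by truncating the earlier one at the
  later one's start (with a warning) to preserve this invariant.
- **Memoryless routing.** The next service depends only on the current
  service, not on patient history or attributes.

## Parameters and units

Per service: `arrival_rate` (external referrals/day), `capacity` (maximum
concurrent patients — caseload slots or beds; unlimited if null), `los`
(a duration distribution in days), `transitions` (a probability row over
services ∪ exit, sum 1 within 1e-9), and `renege` with `threshold_days`,
`hazard` and `destinations`. Reneging is *threshold + hazard*: a patient
becomes eligible after waiting more than `threshold_days`, then reneges
with probability `hazard` per day (1.0 = deterministically on the day the
threshold is crossed). The destination map is explicit per service rather
than hard-coded "one level up", because abandoning a community-service
queue can plausibly send a patient back to their GP as well as up to
crisis care; defaults send half of renegers to a designated escalation
service and half out of the pathway untreated.

Lengths of stay are lognormal by default (stays are strongly right-skewed:
many short contacts, long tails of extended care), parameterised by the
arithmetic mean in days and a log-scale sigma; geometric, exponential,
fixed and empirical-resample families are also available. Sampled durations
are scaled by any active intervention factor, then rounded to whole days
with a floor of one day — the same discretisation in the generator and the
simulator, so mined estimates are comparable to ground truth.

### Illustrative defaults

The real system's rates, stays and capacities are not public. The packaged
defaults are therefore synthetic and labelled as such: external demand
enters through general practice (10 and 6 referrals/day for high- and
low-intensity GP care, roughly an order of magnitude below the real
system's volume), the transition structure is sparse (GP feeds IAPT
assessment and MHP triage; triage fans out across the community services;
crisis and specialist feed inpatient care), and mean stays range from a
week (GP low, assessment, triage) to 78 weeks (community specialist — the
value the intervention presets manipulate). The rates were chosen once, for
statistical identifiability: every service receives enough completed
episodes in a ~50,000-patient log that parameter recovery to ±0.02
(transitions) and ±2% (arrival rates) is a ≈3-standard-error statement
rather than a coin flip. Capacities are derived, not hand-set: the
open-network traffic equations give each service's steady-state flow
`λ_eff`, and capacity is `ceil(1.15 × λ_eff × mean LOS)` — the unstressed
system runs just under saturation, so pandemic-scale demand multipliers
produce queues and reneging, which is the regime the scenario analysis is
about.

## Synthetic data generator

The generator emulates a linked pair of tables: patient attributes (sex,
age band, ethnicity, deprivation quintile, condition flags) drawn from
configurable category weights patterned on the study cohort's mix, and an
activity table with one row per service episode (referral, start and end
dates, outcome). Default generation is **capacity-free**: every referral
starts the same day, so lengths of stay and transitions are observed
without queueing distortion and mining can be validated against ground
truth exactly. A capacity-constrained mode runs the full simulator with
event tracing instead, producing logs with genuine waits and renege
records (reneged queue spells carry a referral date and an end date but no
start date).

What the generator does *not* emulate: geographic attributes, prescribing
records, monthly attribute refreshes, priority-based scheduling, concurrent
episodes, or covariate-dependent routing. Passing tests therefore
demonstrate internal consistency of the pipeline (mining inverts
generation; the simulator obeys queueing theory and conservation), not
fidelity to any real data set.

Two contradictory severity mappings circulate for this cohort (one treats
depression/PTSD/eating disorder as the chronic, severe set; the other
assigns those to moderate and autism/ADHD/addiction to severe). Both ship
as named configurations, and `classify_severity` takes the configuration
as an explicit argument — the package does not endorse a default.

## Estimators

- **Pathways**: episodes grouped per patient, ordered by start date
  (referral date for unstarted queue spells), file order as the intra-day
  tiebreak. A pathway ends at outcome `discharged` or `reneged_exited`;
  later records open a new pathway.
- **Arrival rate**: pathway-initiating episodes per service divided by the
  observation window in days.
- **Transitions**: relative frequencies over completed episodes only;
  censored episodes are excluded, which keeps routing estimates unbiased
  under end-of-study truncation. A service with zero completed episodes is
  flagged and given an exit-with-probability-one fallback row.
- **LOS**: empirical samples (end − start, days) by default; an optional
  lognormal fit matches log-moments.
- **Renege rate**: renege events per waiting patient-week, with waiting
  time accumulated from both admitted (start − referral) and reneged
  (renege date − referral) spells.
- **Graph statistics**: node share = episodes in service / all episodes;
  edge share = transitions on edge / all transitions; edge gap = median of
  (next start − previous end) in weeks.

## Scenarios and comparisons

Demand multipliers are step functions anchored at month boundaries — the
scenario sources state dated jumps and reversion points, not gradual
ramps — and multiply where windows overlap. Intervention capacity factors
round to whole slots (never below one); a stay intervention may be a
relative factor or an absolute target mean (the 78→70-week specialist cut
is encoded as the absolute target; the corresponding relative phrasing,
−10%, would give 70.2 weeks). Flow factors scale named edges and
renormalise the untouched entries of the row proportionally; a factor that
would push a single edge above probability one is rejected.

Comparison tables report `100 × (intervention − baseline)/baseline` on the
max and mean of the replication-mean weekly series over the post-lockdown
window; a zero baseline statistic yields a missing value, not an infinity.
Relative scaling divides each weekly series by its own value in the
reference week (1 April 2021 by default); series with a zero reference are
flagged and omitted.

One scope ambiguity is preserved as data: the demand-doubling set of
trajectory A ("GPs, crisis and inpatient, levels 2, 3 and 5") is encoded
as both GP services, IAPT social prescribing and therapy, MHP crisis and
inpatient care — with IAPT assessment kept on its separately specified
trajectory — and the service lists are editable in the preset YAML.
Similarly, the stay-reduction scope of mitigation A exists in two presets:
`intervention_a` (IAPT therapy plus all level-4 services) and
`intervention_a_table1` (IAPT therapy only).

## Numerical conventions

- Weeks are 7-day bins from the study start (1 April 2019 by default);
  queue size and occupancy are end-of-week snapshots, renege counts are
  weekly sums. The calendar uses ISO dates throughout.
- Replication seeds derive deterministically from the base seed via a seed
  sequence; `(parameters, horizon, seed)` fully determine a run, to the
  byte, and arrivals are drawn in a single batched call per replication.
- Quantile bands are empirical 2.5%/97.5% with linear interpolation across
  replications, elementwise per service-week.
- Warm-up (the pre-lockdown year, 52 weeks by default) is simulated and
  flagged; summaries exclude it on request. Runs start from an empty
  system by default; an optional warm start seeds each service to its
  traffic-equation occupancy with uniform residual stays. With very long
  stays (the 78-week specialist service) a cold-started occupancy is still
  filling years into the run — both arms of a comparison share this
  transient, but absolute occupancy levels early in a cold run understate
  steady state.
- The Erlang-C validation runs the engine as a time-rescaled M/M/c
  (offered load 4, six servers) with the mean stay expressed as 100 steps:
  a daily-step simulation cannot approximate a continuous queue whose mean
  service time is a single step, and the rescaling refines the effective
  step while leaving the tested mechanics — Poisson arrivals, capacity
  gate, FIFO admissions — untouched. Six averaged replications of four
  million steps bring the estimator's sampling error well inside the 5%
  comparison band.

## Problem sizes

The shipped checks use: ~50,000 generated patients (~110,000 episodes) for
parameter recovery; 10,000 days for the infinite-server occupancy check;
6 × 4,000,000 steps for Erlang-C; 50 randomised 100-day configurations for
conservation; and 35 replications of the five-year calendar (1,827 days,
261 weeks) for the preset-scenario experiment. These sizes were chosen so
each stochastic comparison has its sampling error well inside the stated
tolerance.

## Known limitations

- No priority queues, no concurrent service membership, no
  covariate-dependent transitions or waits — equity-stratified dynamics
  cannot be studied with this engine as shipped.
- Capacities and renege behaviour are not identifiable from capacity-free
  logs; converting mined estimates into a runnable parameterisation
  requires supplying them.
- The default parameters are illustrative. Absolute simulated volumes mean
  nothing outside the synthetic setting; only relative scenario contrasts
  carry over as qualitative system behaviour.
- Demand multipliers apply to external arrivals only; feedback from system
  state to demand (e.g. discouraged referrals) is not modelled.
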