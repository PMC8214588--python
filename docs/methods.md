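# Methods

## The model

`bootcua` implements a cohort Markov cost-utility model comparing standard
spasticity care plus add-on oromucosal THC:CBD spray (nabiximols) against
standard care alone in multiple sclerosis, from a healthcare-payer
perspective. Seven states: mild / moderate / severe spasticity on add-on
treatment (`SAT_*`), the same three severities on standard care alone
(`SOC_*`), and absorbing death. Severity is the NRS 0-10 spasticity score
banded as mild `[0, 3.3)`, moderate `[3.3, 6.6]`, severe `(6.6, 10]`; the
closed moderate band follows the verbal definition of the cut-offs ("below
3.3" / "above 6.6") and leaves neither gaps nor overlaps.

Cycles are 28 days; the horizon is 65 cycles (five years at 13 cycles/year),
with results reported at every whole-year horizon. Per cycle, the full 7x7
matrix is composed from

* a 3x3 on-treatment severity matrix (estimated from trial data for cycles
  1-5 and carried forward, per scenario, thereafter),
* a 3x3 standard-care severity matrix (an external long-term observational
  matrix, or placebo-stratum estimates in scenario S1),
* a treatment-discontinuation probability (0 in the titration cycle, 3.8%
  for cycles 2-4, 3.5% from cycle 5), and
* an age-driven all-cause mortality probability (linear ramp 0.020% to
  0.035% across the five years, identical in both arms).

Competing risks are applied in the order death, then discontinuation; a
discontinuing patient moves to the standard-care state of the *same*
severity (there is nowhere else for them to go in this state space) and pays
no further drug cost. Note one consequence: a discontinuing patient holds
their severity for that cycle instead of passing through the severity
matrix, so the two arms' within-cycle dynamics differ slightly even when
both arms are given identical severity matrices. The exact-symmetry check in
the test suite therefore switches discontinuation off.

Accrual uses start-of-cycle occupancy: the cohort earns a full cycle of cost
and utility in the state it occupies when the cycle opens, then transitions.
No half-cycle correction is applied — the model lineage this structure
follows does not use one, and the convention is explicit and testable.
Discounting is 3.0%/year for costs and 1.5%/year for QALYs with exact
elapsed time, `(1+r)^(-(c-1) * 28/365.25)`; the first cycle is undiscounted.
A completed-years stepping variant is available (`ModelConfig.annual_steps`)
since either reading is defensible.

The initial cohort is split 0 / 0.5 / 0.5 over mild/moderate/severe: the
trial enrolled moderate-to-severe patients only, and no published initial
distribution is available, so the even moderate/severe split is a documented
placeholder in `ModelConfig.initial_distribution`.

## Parameter estimation from trial data

Patient records carry one NRS summary per cycle (the mean of diary entries
in that 28-day window, precomputed upstream) and per-visit utilities
attributed to the concurrent severity state. Missing observations are never
imputed: a patient missing either endpoint of a cycle simply leaves that
row's at-risk count. Transition matrices are per-cycle row-wise MLEs
(observed destination frequencies); rows with zero at-risk patients fall
back to the identity row with a flag and a warning, so small bootstrap
replicates always produce a usable schedule. State utilities are pooled
means over all patients, cycles and strata — one utility set shared by both
arms, as the published analysis reports a single set (0.594 / 0.509 / 0.499).

Strata map to trial phases: cycle 1 is estimated from all enrolled patients
(everyone received add-on treatment in the single-blind phase), cycle 2 from
the randomised strata (the only patients observed across the wash-out), and
cycles 3-5 from the double-blind treatment stratum. For scenario S1 the
standard-care matrices come from the double-blind placebo stratum (cycles
3-5), back-filled to cycles 1-2 with the first available estimate and
carried forward beyond cycle 5 — the same carry-forward rule the base case
applies to the treatment arm. The published analysis does not spell out
S1's cycle-to-source mapping; this one is explicit and configurable.

## Costing

Drug cost follows the observed dose curve — 6.9 sprays/day (titration
cycle), 7.7 (cycles 2-5), then linearly 7.3 → 6.2 between cycles 6 and 14,
and 6.2 thereafter — priced continuously at the list price of EUR 466.40
per 3x90-spray pack (EUR 1.7274/spray). No wastage rule is published;
whole-pack rounding exists behind a flag for sensitivity exploration.
Standard-care cost per severity state is micro-costed from an eight-expert
Delphi panel: panel-mean quantity per resource item times its tariff,
identical in both arms. Expert aggregation is the arithmetic mean (the
conventional Delphi point estimate, and what the bootstrap perturbs); unit
costs are point values excluded from resampling, as their uncertainty is
judged minimal next to the spread in elicited resource use.

## The bootstrap PSA (and why not Monte Carlo)

Parameter uncertainty is propagated by resampling the *source data* rather
than by sampling parametric distributions. Each of the (default 1,000)
replicates:

1. redraws, with replacement and at original size, the patients of each
   stratum separately — the 53-patient double-blind treatment arm, the
   53-patient placebo arm, and the 84 single-blind-only patients — so every
   replicate preserves the trial's structure exactly;
2. re-estimates all transition matrices and utilities from the combined
   redrawn sample (scenario S1 additionally re-estimates the standard-care
   matrices from the redrawn placebo stratum);
3. redraws the 8 Delphi experts with replacement and re-costs the states;
4. rebuilds the schedules and runs both arms, recording per-horizon totals.

Because every parameter of a replicate comes from the same resampled
patients, correlations present in the data — notably between transition
probabilities and utilities — propagate into the joint distribution of
incremental costs and QALYs without distributional assumptions. Summaries
report the dominance probability (south-east quadrant share of the
cost-effectiveness plane), quadrant counts, the probability of any QALY
gain, and plain 2.5/97.5 percentile intervals (B = 1,000 does not call for
bias correction). Per-replicate ICER percentiles are reported as printed in
this literature, with quadrant counts alongside, because ratio percentiles
are ill-behaved when replicates straddle quadrants; replicates with exactly
zero QALY difference are excluded from the ICER interval and counted.

Replicate random streams are spawned from one root `SeedSequence`, so runs
are bit-reproducible and independent of evaluation order. A deliberately
trivial `identity_resample` hook lets the whole PSA pipeline be validated
against the deterministic point-estimate run.

The Monte Carlo comparator draws each parameter independently: Dirichlet
rows for transition matrices (concentration = row at-risk count x point
probability, structural zeros preserved), normal state utilities around the
pooled means with *patient-clustered* standard errors (observations within
a patient share a random level, so the naive independent-observation SE
would understate marginal sampling variance and confound the comparison),
and gamma state costs matching the mean and standard error of the
panel-mean cost. With coupling switched off in the generator, the two
engines agree on marginal variances (measured ratio of 5-year QALY-gain
variances ~1.1); what the comparator cannot carry is the *cross-parameter*
correlation.

One caution on where that difference shows up. Both engines use a single
parameter draw per replicate for both the cost and the QALY accumulation,
so the outcome-level correlation corr(dQ, -dC) is dominated by the shared
transition-uncertainty channel (better sampled matrices raise QALYs *and*
lower care costs) and is strongly positive for both engines whenever care
costs are severity-graded. The engines separate cleanly at parameter level:
across bootstrap replicates the utility estimates co-move with the
improvement probabilities when the data are coupled, while the Monte Carlo
comparator's draws are independent by construction. The test suite checks
exactly that contrast.

## The synthetic trial generator

No patient-level data from the source trial are deposited, so the package
ships a generator whose ground truth is known exactly; all statistical
guarantees are stated against that truth. It emulates the trial flow: 190
moderate-to-severe entrants (baseline NRS drawn uniformly from [4.5, 6.6]
for moderate and [7.5, 10] for severe entrants — patients with inadequate
relief from prior therapy enter with high scores, which also makes the 20%
responder criterion attainable at the trial's observed 70.5% rate), one
single-blind cycle on treatment, a responder gate (NRS improvement >= 20%
vs baseline), a wash-out cycle, re-qualification, and a 53/53 double-blind
randomisation for three further cycles. Severity follows a 3-state chain
per phase (defaults: the published on-treatment matrices back-converted to
conditional form; a distinct relapse-prone chain for placebo), and NRS
values are drawn inside the latent state's band so the estimators recover
the phase chains exactly in the large-sample limit.

The responder and wash-out gates select exact-count random subsets (134 and
106 by default) rather than per-patient Bernoulli draws: the published flow
has exactly as many re-qualifiers as randomisation slots, so Bernoulli
gating would fail the 53/53 randomisation on roughly half of all seeds,
whereas exact counts reproduce the printed patient flow (53/53/84 strata)
on every seed. Wash-out re-qualification is a configurable-probability gate
rather than a simulated NRS rebound; the published stopping rule for the
wash-out is ambiguous and irrelevant to the estimators.

Utilities are state mean + patient random effect (sd 0.08) + observation
noise (sd 0.05), clipped to [-1, 1]. A coupling coefficient `rho` ties each
patient's latent frailty to their transition draws (row probabilities
reweighted by `exp(-rho * z * severity)`), producing the utility-transition
correlation that motivates bootstrapping; `rho = 0` recovers the chains
exactly, and the default 0.5 represents moderate coupling. Consequences:
with `rho != 0` the estimators' large-sample limit is the frailty-averaged
chain, not the nominal one, so parameter-recovery and interval-coverage
checks run at `rho = 0`, and pooled utility estimates shift slightly toward
the utilities of frequently-visited states.

The Delphi generator emits eight experts with log-normal quantities around
severity-monotone per-item means and a fixed tariff table. The default item
set (drugs, visits, physiotherapy, home nursing, hospital days, tests) was
chosen once to give a realistic, steeply severity-graded care-cost profile
(about EUR 212 / 530 / 1,236 per cycle for mild/moderate/severe), under
which the default synthetic study reproduces the qualitative published
pattern: the add-on arm dominates from roughly year two onward, with the
probability of a QALY gain near 100%. The bundled standard-care matrix
`SYNTHETIC_SOC_MATRIX` is likewise a synthetic stand-in for the external
observational matrix, which is only available in supplementary material;
absolute cost and ICER levels from the synthetic defaults are therefore
illustrative, not a replication of the published point estimates.

What the generator does *not* emulate: informative dropout and missing-data
mechanisms (missingness arises only from the trial flow), diary-level NRS
variation within a cycle, utility mapping uncertainty, age effects on
utilities, or secular changes in care. Passing tests show the pipeline is
correct and the bootstrap well-calibrated *under the generating model*; they
cannot certify behaviour under real-data pathologies such as informative
missingness.

## Numerical choices and scaled problem sizes

Row-stochasticity is enforced at 1e-9 for schedules and 1e-12 for estimated
matrices; printed matrices are accepted if rows sum to (1 - discontinuation)
within 0.005 (print rounding) and renormalised exactly. Dirichlet sampling
skips rows with fewer than two positive concentrations (degenerate rows stay
at their point estimate). Percentiles use linear interpolation. Statistical
test sizes were scaled to keep the default suite fast while retaining power:
parameter recovery uses a 20,000-patient trial (every matrix row keeps over
a thousand at-risk patients), bootstrap-vs-sampling-SD calibration uses 200
regenerated trials against a 1,000-replicate bootstrap (acceptance band
[0.7, 1.4] on the SD ratio), and interval coverage uses 60 experiments of
200 replicates (pass at >= 80% empirical coverage for nominal 95%).

## Known limitations

* The published point estimates cannot be replicated without the
  supplementary inputs (observational standard-care matrices, initial
  severity split, Belgian unit-cost tables); with the synthetic stand-ins
  the model reproduces the qualitative results only.
* The wash-out cycle's transition estimate conditions on re-qualification;
  how the original analysis mapped the variable-length wash-out onto cycle
  2 is not documented.
* ICER percentile intervals mix signs when replicates straddle quadrants;
  they are reported for comparability, but the quadrant counts and the
  CE-plane cloud are the more faithful uncertainty summaries.
* Unit-cost and utility-mapping uncertainty are excluded from the PSA by
  design, mirroring the source analysis.
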