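# Methods

## Model

`sonoflow` simulates one terminating 540-minute day (09:00–18:00) of a
walk-in ultrasonography department as a discrete-event system. Entities are
patients; resources are physicians, each in their own examination room. The
day is analyzed by independent replications: the system starts empty, new
arrivals stop at minute 540, and the day flushes until every arrived patient
has been served.

**Arrivals.** A nonstationary renewal process over hourly blocks. Each block
carries its own fitted interarrival-time distribution, written in the Arena
input-modelling dialect (`[shift +] [scale ×] Family(p1[, p2])`). The engine
uses the *current-block rule*: the next interarrival gap is drawn from the
distribution of the block containing the current event time. A gap can cross
a block boundary; with working-day gaps of roughly 7–21 minutes this bias is
negligible. A drawn gap of zero is advanced by a 10⁻⁶-minute tick so event
ordering stays total.

**Examination types.** Each arrival draws one of ten procedure types from a
categorical distribution in printed-table order; the printed percentages sum
to 99.9 and are renormalized to 1. Each type has its own processing-time
distribution. Abdominal and urinary-system examinations require a full
bladder; that preparation is modelled as a series delay between arrival and
queue entry, with default `CONST(0)` (see *Known limitations*).

**Physician schedule.** Piecewise-constant capacity; in the baseline, four
physicians until minute 300 (14:00), three afterwards. Physician *i* is on
shift while scheduled capacity exceeds *i*. A physician whose shift ends
mid-service completes that service and takes no new patient; any patients in
that physician's dedicated queue are re-routed under the active routing rule.
During the flush the number of working physicians never drops below the final
scheduled value. No service is ever preempted.

**Routing.**

* *Dedicated* (current system): an arriving patient is served by the
  lowest-index idle on-shift physician; if all are busy they irrevocably join
  the shortest eligible per-physician queue (ties → lowest index). The
  lowest-index preference reproduces the strongly unequal per-physician
  utilization profile observed in fixed doctor–room systems.
* *Pooled* (alternative system): a single shared FIFO queue; a freed
  physician takes the queue head. When several physicians are idle the
  choice rotates round-robin over idle indices. The rotation is
  deterministic, consumes no randomness, and is what makes per-physician
  utilizations near-equal at every load — a lowest-index rule would retain a
  utilization gradient of 0.07–0.13 even near saturation, contrary to how a
  pooled team behaves.

**Event ordering.** Simultaneous events resolve as shift change < service
completion < arrival/queue entry, then by insertion sequence, making every
replication a pure function of (configuration, seed). All of a patient's
randomness (type, IoT branching, preparation, processing time) is consumed
at the arrival event in a fixed order, so two configurations compared under
the same seed see identical demand — common random numbers for paired
scenario comparisons.

**IoT demand modification.** Home wearable breast-ultrasound devices are
modelled by thinning: after type assignment, a breast-examination patient
never presents with probability 0.30. Presenting breast patients are
non-users with probability 0.70 (standard duration); device users split
evenly into shorter and longer examinations. The duration multipliers
default to 0.7 and 1.3 — the study direction ("shorter" / "longer") is
given but no magnitude, so these are explicit configuration parameters and
reports should state the values used. Thinning after type assignment leaves
the non-breast arrival process exactly unchanged.

## KPIs and output analysis

* **AWT** excludes the preparation delay: a patient filling their bladder is
  not yet waiting for a physician. With the default zero preparation,
  queue entry equals arrival.
* **WIP** integrates the number of patients present over the fixed window
  [0, 540] and divides by 540; a flush patient counts up to the window end.
* **Utilization** is busy time over on-shift time per physician. A
  physician still serving during the flush has the on-shift time extended to
  their last service completion, so utilization is bounded by 1 exactly.
  UtilADC is the unweighted mean over scheduled physicians.
* Cross-replication statistics use the sample standard deviation (n−1
  denominator), SE = S/√R and half-width `t(α/2, R−1)·S/√R` with exact t
  quantiles (no table interpolation). Replication sizing is the single-step
  pilot rule `R = ceil((t(α/2, R₀−1)·S₀/ε)²)` — pilot degrees of freedom,
  not iterated. Validation is a two-sided one-sample t-test against the
  observed system mean. One-way ANOVA compares scenario KPI vectors; the
  all-identical degenerate case is defined as F = 0. Post-hoc pairwise
  procedures are out of scope.

## Distribution dialect

Arena argument conventions, centralized in one table so they can be swapped:
`Expo(mean)`; `Gamma(β, α)` with mean α·β; `Erlang(β, k)` with mean k·β
(k a positive integer); `Beta(α₁, α₂)` on [0, 1], rescaled by the leading
multiplier (the multiplier is accepted for Beta only); `UNIF(low, high)`;
`CONST(v)`. The study does not print the original tool's parameter-order
convention; if the source used the opposite Gamma order, variances (not
means) would change. Negative values from the `-0.5 +` shifted expressions
are clamped to 0 rather than resampled — clamping preserves the draw count,
and the induced mean bias is bounded by `0.5 × P(base draw < 0.5)`
(estimated at well under 0.05 min for both affected blocks; the analytic
mean deliberately ignores truncation and the sampling property tests carry
the bound instead).

## Synthetic arrival logs

The historical registry is confidential, so `synth.generate_log` emulates
its structure: timestamped arrivals over a 24-hour day with a type per
patient. Generation is block-by-block — each block's renewal stream
restarts at the block start — rather than the engine's current-block rule,
because the overnight block (`UNIF(1, 358)`, mean gap ≈ 3 h) would
otherwise routinely leap over the entire morning. The registry has no
7–8 A.M. block; the overnight block is extended to 8 A.M. Restarting at
block starts slightly overweights the first gap of each block; for the
hourly-rate tests the residual renewal-theoretic bias (≈ (CV²−1)/2
arrivals) is carried in the tolerance. The generator reproduces hourly
intensities and the type mix; it does **not** emulate day-of-week or
seasonal level shifts (an optional per-day rate multiplier exists, default
off), patient identity, or any real calendar. Passing tests therefore show
that the pipeline handles data with the study's *distributional* structure,
not that it reproduces the historical registry.

## Problem sizes and numerical choices

Scenario comparisons in the tests use 112 replications per scenario — the
study's own replication count from the half-width sizing rule
(`(2.045·26.44/5.11)² = 111.96 → 112`). The Erlang-C cross-check compares
the pooled engine on an M/M/4 configuration (arrival mean 10 min, service
mean 14 min) against the closed-form steady-state delay; because an
empty-started 540-minute day sits measurably below steady state, the
comparison uses a ten-fold horizon with a 200-minute warm-up deleted, 200
replications. Paired-policy comparisons (pooling dominance, IoT thinning)
use 100–300 paired seeds. Quartiles in descriptive summaries use linear
interpolation. TOPSIS ties keep input order; an all-identical alternative
set yields closeness 0.5 and a degenerate flag.

## Known limitations

* The study reports a mean waiting time around 40 minutes at utilization
  ≈ 0.43; that level is only reachable with a substantial full-bladder
  preparation delay whose distribution is not published. With the default
  `CONST(0)` preparation the simulated waits are of the order of a minute,
  so absolute KPI levels are not comparable to the published table — the
  qualitative scenario ordering (S4 best, S5 worst, pooled ≤ dedicated) is,
  and is what the tests assert. The preparation delay is a first-class
  configuration parameter for calibration studies.
* The current system's true routing rule is not published; lowest-index /
  shortest-queue is chosen to reproduce the published unequal utilization
  profile. Room specialization by procedure is a plausible alternative.
* Emergency overflow to a second machine, the registration desk (available
  as a configurable constant delay, default zero), post-scan report review,
  weekends, and device accuracy / repeat visits are not modelled.
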