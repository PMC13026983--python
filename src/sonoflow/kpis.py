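"""KPIs, cross-replication statistics, replication sizing and validation.

A terminating simulation of the clinic day is analyzed by independent
replications.  Per replication this module computes the study's four key
performance indicators:

* **AWT** — average waiting time: mean over patients of service start minus
  queue entry (the full-bladder preparation delay is *excluded* by
  definition: a patient preparing is not yet waiting for a physician),
* **WIP** — work-in-process: time-average number of patients present over the
  540-minute working window; patients still in service at the window end
  count up to the window end only,
* **PST** — patient system time: mean time from arrival to service
  completion,
* **util / UtilADC** — per-physician busy time divided by on-shift time, and
  its unweighted mean over scheduled physicians.  A physician working past
  the scheduled shift end (finishing the flush) has the on-shift time
  extended to the last service completion, so utilization never exceeds 1.

Across replications it provides the half-width machinery used for output
analysis: for R replications with sample standard deviation S the half-width
is ``h = t(alpha/2, R-1) * S / sqrt(R)``; the pilot-based sizing rule inverts
it for a target precision ε as ``R >= (t(alpha/2, R0-1) * S0 / ε)²``; and the
validation step is a two-sided one-sample t-test of the replicated mean
against the observed system mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .engine import DoctorSchedule, EventLog

__all__ = [
    "KPISummary",
    "CrossRepStats",
    "ValidationResult",
    "compute_kpis",
    "aggregate",
    "required_replications",
    "validate_mean",
    "one_way_anova",
    "percent_reduction",
    "kpi_table",
    "replicate_kpis",
]


@dataclass(frozen=True)
class KPISummary:
    """KPIs of a single replication."""

    awt: float
    wip: float
    pst: float
    util: tuple[float, ...]
    util_adc: float
    n_patients: int


@dataclass(frozen=True)
class CrossRepStats:
    """Mean, dispersion and confidence half-width of one KPI across replications."""

    n: int
    mean: float
    sd: float
    se: float
    half_width: float
    ci: tuple[float, float]
    alpha: float


@dataclass(frozen=True)
class ValidationResult:
    """Two-sided one-sample t-test of the simulated mean against mu0."""

    t0: float
    mu0: float
    t_crit: float
    df: int
    decision: str  # "accept H0" | "reject H0"
    p_value: float


def compute_kpis(log: EventLog, schedule: DoctorSchedule) -> KPISummary:
    """KPIs of one event log under the schedule that produced it."""
    horizon = log.horizon
    shifts = schedule.shifts()
    util = []
    for d in range(log.n_doctors):
        start, end = shifts[d]
        ivals = log.busy.get(d, [])
        busy_time = sum(e - s for s, e in ivals)
        if ivals:  # flush work extends the effective shift
            end = max(end, max(e for _, e in ivals))
        on_shift = end - start
        util.append(busy_time / on_shift if on_shift > 0 else 0.0)
    util_adc = float(np.mean(util)) if util else 0.0

    if not log.patients:
        warnings.warn("empty event log: all KPIs zero", stacklevel=2)
        return KPISummary(0.0, 0.0, 0.0, tuple(util), util_adc, 0)

    waits = [p.service_start - p.queue_enter for p in log.patients]
    systimes = [p.service_end - p.arrival for p in log.patients]
    # time-average count in system over [0, horizon]
    in_window = sum(
        max(0.0, min(p.service_end, horizon) - min(p.arrival, horizon))
        for p in log.patients
    )
    return KPISummary(
        awt=float(np.mean(waits)),
        wip=in_window / horizon,
        pst=float(np.mean(systimes)),
        util=tuple(util),
        util_adc=util_adc,
        n_patients=len(log.patients),
    )


def aggregate(values, alpha: float = 0.05) -> CrossRepStats:
    """Cross-replication mean, sd (n−1 denominator), SE, half-width and CI."""
    x = np.asarray(list(values), dtype=float)
    n = x.size
    if n < 2:
        raise ValueError(f"need at least 2 replications, got {n}")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    se = sd / math.sqrt(n)
    hw = float(sps.t.ppf(1.0 - alpha / 2.0, n - 1)) * se
    return CrossRepStats(
        n=n, mean=mean, sd=sd, se=se, half_width=hw,
        ci=(mean - hw, mean + hw), alpha=alpha,
    )


def required_replications(s0: float, r0: int, epsilon: float,
                          alpha: float = 0.05, *, ceil: bool = True):
    """Replications needed for a target half-width ε, from an R0-replication pilot.

    Single-step rule with pilot degrees of freedom (not iterated):
    ``R = ceil((t(alpha/2, R0-1) * S0 / ε)²)``.  With ``ceil=False`` the raw
    (un-rounded) value is returned.
    """
    if epsilon <= 0:
        raise ValueError(f"target half-width must be positive, got {epsilon}")
    if s0 <= 0:
        raise ValueError(f"pilot standard deviation must be positive, got {s0}")
    if r0 < 2:
        raise ValueError(f"pilot replication count must be >= 2, got {r0}")
    t = float(sps.t.ppf(1.0 - alpha / 2.0, r0 - 1))
    raw = (t * s0 / epsilon) ** 2
    return math.ceil(raw) if ceil else raw


def validate_mean(mean: float, sd: float, n: int, mu0: float,
                  alpha: float = 0.05) -> ValidationResult:
    """Validate the model: two-sided t-test of the replicated mean against mu0."""
    if n < 2:
        raise ValueError(f"need at least 2 replications, got {n}")
    df = n - 1
    t_crit = float(sps.t.ppf(1.0 - alpha / 2.0, df))
    if sd == 0.0:
        if mean == mu0:
            return ValidationResult(0.0, mu0, t_crit, df, "accept H0", 1.0)
        return ValidationResult(math.copysign(math.inf, mean - mu0), mu0,
                                t_crit, df, "reject H0", 0.0)
    if sd < 0:
        raise ValueError(f"standard deviation must be non-negative, got {sd}")
    t0 = (mean - mu0) / (sd / math.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t0), df))
    decision = "accept H0" if abs(t0) < t_crit else "reject H0"
    return ValidationResult(t0, mu0, t_crit, df, decision, p)


def one_way_anova(groups) -> tuple[float, float]:
    """Classical one-way ANOVA over per-scenario KPI vectors; returns (F, p).

    All-identical data (zero between- and within-group variance) yields
    ``(0.0, 1.0)``.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for g in arrays:
        if g.size < 2:
            raise ValueError("each ANOVA group needs at least two values")
    grand = np.concatenate(arrays)
    ss_between = sum(g.size * (g.mean() - grand.mean()) ** 2 for g in arrays)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    if ss_between == 0.0:
        return 0.0, 1.0
    if ss_within == 0.0:
        return math.inf, 0.0
    f, p = sps.f_oneway(*arrays)
    return float(f), float(p)


def percent_reduction(base: float, alt: float) -> float:
    """Reduction of ``alt`` relative to ``base``, in percent."""
    if base <= 0:
        raise ValueError(f"baseline must be positive, got {base}")
    return 100.0 * (base - alt) / base


def kpi_table(per_scenario: dict, alpha: float = 0.05):
    """Cross-replication KPI table: one row per (scenario, metric).

    ``per_scenario`` maps scenario id to its list of :class:`KPISummary`.
    Returns a DataFrame with columns scenario, metric, avg, half_width —
    the usual report layout for terminating-simulation comparisons.
    """
    import pandas as pd

    rows = []
    for sid, summaries in per_scenario.items():
        for metric in ("awt", "wip", "pst", "util_adc"):
            st = aggregate([getattr(k, metric) for k in summaries], alpha=alpha)
            rows.append({
                "scenario": sid, "metric": metric,
                "avg": st.mean, "half_width": st.half_width,
            })
    return pd.DataFrame(rows, columns=["scenario", "metric", "avg", "half_width"])


def replicate_kpis(config, n_reps: int, seed: int) -> list[KPISummary]:
    """Run ``n_reps`` independent replications of a scenario and return KPIs.

    Replication r uses a child seed spawned from ``seed`` so that scenarios
    compared under the same ``seed`` share their random-number streams
    (common random numbers).
    """
    from .engine import run_replication

    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    return [
        compute_kpis(run_replication(config, int(s)), config.schedule)
        for s in seeds
    ]
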