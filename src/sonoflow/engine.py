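"""Terminating discrete-event engine for one walk-in ultrasonography clinic day.

The department is modelled as a multi-server queueing system with

* nonstationary arrivals — hourly blocks, each with its own interarrival-time
  distribution; the block of the *current* event time supplies the next
  interarrival draw (Arena CREATE-style; the known small bias at block
  boundaries is documented in the methods note),
* heterogeneous examination types drawn from a categorical catalog, each with
  its own processing-time distribution and optional full-bladder preparation,
* a piecewise-constant physician schedule (e.g. four doctors until minute 300,
  three afterwards),
* either *dedicated* routing (each patient irrevocably joins one physician's
  queue) or *pooled* routing (one shared FIFO queue, next free physician).

A day is 540 minutes; arrivals are cut off at the horizon and the system is
flushed: every patient who arrived is eventually served.  A physician whose
shift ends mid-service completes that service, takes no new patient, and any
patients still in that physician's dedicated queue are re-routed under the
active routing rule.  During the flush the number of working physicians never
drops below the final scheduled value.

All stochastic draws for a patient (type, IoT branching, preparation and
processing times) happen at the arrival event, so two runs with identical
seeds but different routing policies see identical demand — common random
numbers for paired scenario comparisons — and a (config, seed) pair always
reproduces a bit-identical event log.
"""

from __future__ import annotations

import heapq
import itertools
import math
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distributions import DistributionSpec, analytic_mean, sample

__all__ = [
    "PatientRecord",
    "ArrivalSchedule",
    "USType",
    "USTypeCatalog",
    "DoctorSchedule",
    "EventLog",
    "SimulationError",
    "capacity_at",
    "next_arrival",
    "draw_patient_type",
    "pick_idle_doctor",
    "pick_dedicated_queue",
    "run_replication",
]

DAY_MINUTES = 540.0  #: working-day horizon, 09:00-18:00

# event ordering: simultaneous events resolve shift changes first, then
# service completions, then arrivals/queue entries; ties broken by sequence
_PRIO_SHIFT = 0
_PRIO_SERVICE_END = 1
_PRIO_ARRIVAL = 2

_ZERO_TICK = 1e-6  # zero interarrival draws advance by this to keep ordering total


class SimulationError(RuntimeError):
    """Raised for mis-specified configurations discovered during a run."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PatientRecord:
    """One entity's timestamps (minutes from day start) and type labels."""

    id: int
    arrival: float
    us_type: str
    iot_class: str = "standard"
    prep_end: float = math.nan
    queue_enter: float = math.nan
    service_start: float = math.nan
    service_end: float = math.nan
    doctor: int | None = None
    service_time: float = math.nan

    @property
    def waiting(self) -> float:
        """Queueing delay: service start minus queue entry (prep excluded)."""
        return self.service_start - self.queue_enter

    @property
    def system_time(self) -> float:
        """Time from arrival to service completion."""
        return self.service_end - self.arrival


@dataclass(frozen=True)
class ArrivalSchedule:
    """Contiguous time blocks, each with its own interarrival distribution."""

    blocks: tuple[tuple[float, float, DistributionSpec], ...]

    def __post_init__(self) -> None:
        blocks = tuple((float(a), float(b), spec) for a, b, spec in self.blocks)
        object.__setattr__(self, "blocks", blocks)
        if not blocks:
            raise ValueError("arrival schedule needs at least one block")
        prev_end = blocks[0][0]
        for start, end, spec in blocks:
            if start != prev_end:
                raise ValueError(
                    f"arrival blocks must be contiguous; gap/overlap at t={start}"
                )
            if end <= start:
                raise ValueError(f"empty arrival block [{start}, {end})")
            if not isinstance(spec, DistributionSpec):
                raise TypeError("block interarrival must be a DistributionSpec")
            prev_end = end

    @property
    def start(self) -> float:
        return self.blocks[0][0]

    @property
    def end(self) -> float:
        return self.blocks[-1][1]

    def block_at(self, t: float) -> DistributionSpec:
        """Interarrival spec of the half-open block [start, end) containing t."""
        for start, end, spec in self.blocks:
            if start <= t < end:
                return spec
        raise ValueError(f"time {t} outside arrival schedule [{self.start}, {self.end})")


@dataclass(frozen=True)
class USType:
    """One examination type of the catalog."""

    name: str
    probability: float
    processing: DistributionSpec
    needs_prep: bool = False
    iot_eligible: bool = False


@dataclass(frozen=True)
class USTypeCatalog:
    """Examination-type mix; printed percentages are renormalized to sum to 1."""

    entries: tuple[USType, ...]

    def __post_init__(self) -> None:
        entries = tuple(self.entries)
        object.__setattr__(self, "entries", entries)
        if not entries:
            raise ValueError("catalog is empty")
        total = sum(e.probability for e in entries)
        if total <= 0 or any(e.probability < 0 for e in entries):
            raise ValueError("catalog probabilities must be non-negative with positive sum")
        probs = np.array([e.probability for e in entries]) / total
        object.__setattr__(self, "_probs", probs)
        object.__setattr__(self, "_cum", np.cumsum(probs))

    @property
    def probabilities(self) -> np.ndarray:
        """Renormalized probabilities in catalog (printed-table) order."""
        return self._probs.copy()

    def __getitem__(self, name: str) -> USType:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)


@dataclass(frozen=True)
class DoctorSchedule:
    """Piecewise-constant physician capacity over the working day."""

    blocks: tuple[tuple[float, float, int], ...]

    def __post_init__(self) -> None:
        blocks = tuple((float(a), float(b), int(c)) for a, b, c in self.blocks)
        object.__setattr__(self, "blocks", blocks)
        prev_end = blocks[0][0]
        for start, end, count in blocks:
            if start != prev_end or end <= start:
                raise ValueError("doctor schedule blocks must be contiguous and non-empty")
            if count < 0:
                raise ValueError("negative physician count")
            prev_end = end

    @property
    def start(self) -> float:
        return self.blocks[0][0]

    @property
    def end(self) -> float:
        return self.blocks[-1][1]

    @property
    def n_doctors(self) -> int:
        return max(c for _, _, c in self.blocks)

    @property
    def final_count(self) -> int:
        """Capacity in the last scheduled block; the flush never goes below it."""
        return self.blocks[-1][2]

    def shifts(self) -> list[tuple[float, float]]:
        """Per-doctor (start, end) on-shift interval.

        Doctor ``i`` is on shift whenever the scheduled capacity exceeds ``i``;
        the interval must be contiguous (physicians leave at a shift end and do
        not return).
        """
        out = []
        for i in range(self.n_doctors):
            spans = [(s, e) for s, e, c in self.blocks if c > i]
            if not spans:
                continue
            start, end = spans[0]
            for s, e in spans[1:]:
                if s != end:
                    raise ValueError(f"doctor {i} has a non-contiguous shift")
                end = e
            out.append((start, end))
        return out


@dataclass
class EventLog:
    """Complete record of one replication."""

    patients: list[PatientRecord]
    busy: dict[int, list[tuple[float, float]]]
    horizon: float
    n_doctors: int
    n_removed: int = 0  #: IoT-eligible patients who never presented

    def patients_dataframe(self) -> pd.DataFrame:
        """One row per patient; columns: id, arrival, us_type, iot_class,
        prep_end, queue_enter, service_start, service_end, doctor."""
        cols = [
            "id", "arrival", "us_type", "iot_class", "prep_end",
            "queue_enter", "service_start", "service_end", "doctor",
        ]
        return pd.DataFrame(
            [{c: getattr(p, c) for c in cols} for p in self.patients], columns=cols
        )

    def busy_dataframe(self) -> pd.DataFrame:
        """One row per service interval; columns: doctor, start, end."""
        rows = [
            {"doctor": d, "start": s, "end": e}
            for d, ivals in sorted(self.busy.items())
            for s, e in ivals
        ]
        return pd.DataFrame(rows, columns=["doctor", "start", "end"])


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def capacity_at(schedule: DoctorSchedule, t: float) -> int:
    """Scheduled physician count at time t (blocks half-open [from, to))."""
    if t < schedule.start or t > schedule.end:
        raise ValueError(f"time {t} outside schedule horizon [{schedule.start}, {schedule.end}]")
    for start, end, count in schedule.blocks:
        if start <= t < end:
            return count
    return schedule.final_count  # t == schedule.end


def next_arrival(
    schedule: ArrivalSchedule, now: float, rng: np.random.Generator,
    horizon: float | None = None,
) -> float | None:
    """Absolute time of the next arrival after ``now``, or None past the cut-off.

    Uses the interarrival distribution of the block containing ``now``; a draw
    of zero is advanced by a 1e-6 tick to keep event ordering total.  Arrivals
    at or beyond the horizon (default: schedule end) are suppressed.
    """
    if horizon is None:
        horizon = schedule.end
    if now >= horizon:
        return None
    spec = schedule.block_at(now)
    t = now + max(sample(spec, rng), _ZERO_TICK)
    return None if t >= horizon else t


def draw_patient_type(catalog: USTypeCatalog, rng: np.random.Generator) -> str:
    """Categorical draw over renormalized probabilities in printed-table order."""
    u = rng.random()
    idx = int(np.searchsorted(catalog._cum, u, side="right"))
    idx = min(idx, len(catalog.entries) - 1)
    return catalog.entries[idx].name


def expected_arrivals(schedule: ArrivalSchedule) -> float:
    """Approximate expected arrival count: sum of block length / mean interarrival."""
    return sum((e - s) / analytic_mean(spec) for s, e, spec in schedule.blocks)


def pick_idle_doctor(idle_indices, after: int | None = None) -> int | None:
    """Select an idle physician, or None if none is idle.

    With ``after`` None the lowest index wins (dedicated routing, matching
    the fixed room ordering of the current system).  Otherwise the first
    idle index cyclically following ``after`` is chosen — the pooled
    policy's round-robin rotation, which spreads idle-time pickups evenly
    and reproduces the near-equal per-physician utilizations of a pooled
    team.
    """
    idle = sorted(idle_indices)
    if not idle:
        return None
    if after is None:
        return idle[0]
    for i in idle:
        if i > after:
            return i
    return idle[0]


def pick_dedicated_queue(queue_lengths, eligible) -> int:
    """Dedicated routing with every physician busy: shortest eligible queue.

    ``queue_lengths[i]`` is the length of physician i's queue; ties break to
    the lowest index.  The assignment is final — the patient stays in that
    queue even if another physician frees up first.
    """
    eligible = sorted(eligible)
    if not eligible:
        raise SimulationError("no eligible physician queue")
    return min(eligible, key=lambda i: (queue_lengths[i], i))


# ---------------------------------------------------------------------------
# the event loop
# ---------------------------------------------------------------------------

class _Doctor:
    __slots__ = ("idx", "shift_start", "shift_end", "flush_worker", "on",
                 "retiring", "serving", "service_began", "queue")

    def __init__(self, idx: int, shift: tuple[float, float], flush_worker: bool):
        self.idx = idx
        self.shift_start, self.shift_end = shift
        self.flush_worker = flush_worker
        self.on = self.shift_start <= 0.0
        self.retiring = False
        self.serving: PatientRecord | None = None
        self.service_began = math.nan
        self.queue: deque[tuple[PatientRecord, float]] = deque()  # dedicated only


def run_replication(config, seed: int) -> EventLog:
    """Simulate one clinic day under ``config`` and return its event log.

    ``config`` is a :class:`~sonoflow.scenarios.ScenarioConfig` (or any object
    with the same fields).  Identical (config, seed) pairs yield identical
    logs.
    """
    from .scenarios import apply_iot, effective_service_time  # local: avoids cycle

    config.check()
    rng = np.random.default_rng(seed)
    horizon = config.horizon
    pooled = config.routing == "pooled"

    shifts = config.schedule.shifts()
    final_count = config.schedule.final_count
    doctors = [
        _Doctor(i, shifts[i], flush_worker=i < final_count) for i in range(len(shifts))
    ]
    shared: deque[PatientRecord] = deque()
    busy: dict[int, list[tuple[float, float]]] = {d.idx: [] for d in doctors}
    patients: list[PatientRecord] = []
    n_removed = 0

    seq = itertools.count()
    heap: list[tuple[float, int, int, str, object]] = []

    def push(t: float, prio: int, kind: str, payload: object = None) -> None:
        heapq.heappush(heap, (t, prio, next(seq), kind, payload))

    for d in doctors:
        if d.shift_start > 0:
            push(d.shift_start, _PRIO_SHIFT, "shift_start", d.idx)
        if not d.flush_worker:
            push(d.shift_end, _PRIO_SHIFT, "shift_end", d.idx)

    def start_service(d: _Doctor, p: PatientRecord, t: float) -> None:
        p.doctor = d.idx
        p.service_start = t
        p.service_end = t + p.service_time
        d.serving = p
        d.service_began = t
        push(p.service_end, _PRIO_SERVICE_END, "service_end", d.idx)

    rotation = -1  # last pooled idle-pick, for the round-robin rotation

    def route(p: PatientRecord, t: float) -> None:
        """Place a patient whose queue_enter is already stamped."""
        nonlocal rotation
        idle = pick_idle_doctor(
            (d.idx for d in doctors if d.on and not d.retiring and d.serving is None),
            after=rotation if pooled else None,
        )
        if idle is not None:
            if pooled:
                rotation = idle
            start_service(doctors[idle], p, t)
            return
        if pooled:
            shared.append(p)
            return
        # dedicated: shortest queue among on-shift, non-retiring doctors
        eligible = [d.idx for d in doctors if d.on and not d.retiring]
        if not eligible:
            eligible = [d.idx for d in doctors if d.shift_start > t]
            if not eligible:
                raise SimulationError(
                    f"patient at t={t}: no physician on shift and none scheduled later"
                )
        lengths = [len(d.queue) for d in doctors]
        doctors[pick_dedicated_queue(lengths, eligible)].queue.append((p, t))

    def take_next(d: _Doctor, t: float) -> None:
        if pooled:
            if shared:
                start_service(d, shared.popleft(), t)
        elif d.queue:
            start_service(d, d.queue.popleft()[0], t)

    def retire(d: _Doctor, t: float) -> None:
        d.on = False
        d.retiring = False
        if d.queue:
            orphans = list(d.queue)
            d.queue.clear()
            for p, _ in orphans:
                route(p, t)

    def handle_arrival(t: float) -> None:
        # draw the next arrival first, from the block of the current time
        nxt = next_arrival(config.arrival, t, rng, horizon)
        if nxt is not None:
            push(nxt, _PRIO_ARRIVAL, "arrival", None)
        # all of this patient's randomness is consumed here, in fixed order
        type_name = draw_patient_type(config.catalog, rng)
        entry = config.catalog[type_name]
        iot_class = "standard"
        if config.iot is not None and entry.iot_eligible:
            iot_class = apply_iot(entry, rng, config.iot)
        prep_time = sample(config.prep, rng) if entry.needs_prep else 0.0
        base = sample(entry.processing, rng)
        nonlocal n_removed
        if iot_class is None:  # thinned away: never presents
            n_removed += 1
            return
        p = PatientRecord(id=len(patients), arrival=t, us_type=type_name,
                          iot_class=iot_class)
        p.service_time = effective_service_time(base, iot_class, config.iot)
        delay = getattr(config, "registration", 0.0) + prep_time
        p.prep_end = t + delay
        patients.append(p)
        if delay <= 0.0:
            p.queue_enter = t
            route(p, t)
        else:
            push(p.prep_end, _PRIO_ARRIVAL, "prep_done", p)

    first = next_arrival(config.arrival, config.arrival.start, rng, horizon)
    if first is not None:
        push(first, _PRIO_ARRIVAL, "arrival", None)

    while heap:
        t, _prio, _seq, kind, payload = heapq.heappop(heap)
        if kind == "arrival":
            handle_arrival(t)
        elif kind == "prep_done":
            p = payload
            p.queue_enter = t
            route(p, t)
        elif kind == "service_end":
            d = doctors[payload]
            busy[d.idx].append((d.service_began, t))
            d.serving = None
            d.service_began = math.nan
            if d.retiring:
                retire(d, t)
            else:
                take_next(d, t)
        elif kind == "shift_end":
            d = doctors[payload]
            if d.serving is not None:
                d.retiring = True  # finishes current service, takes no new patient
            else:
                d.on = False
                retire(d, t)
        elif kind == "shift_start":
            d = doctors[payload]
            d.on = True
            take_next(d, t)

    return EventLog(patients=patients, busy=busy, horizon=horizon,
                    n_doctors=len(doctors), n_removed=n_removed)
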