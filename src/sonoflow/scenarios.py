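"""Scenario configurations S1-S6 and the IoT demand-modification mechanism.

The six operational scenarios compared in the study combine three design
axes:

* routing — ``dedicated`` (current system: fixed doctor-room pairing, each
  patient irrevocably joins one physician's queue) vs ``pooled`` (alternative
  system: one shared FIFO queue, physicians dynamically take the head),
* physician schedule — baseline (four doctors 09:00-14:00, three afterwards)
  vs three doctors throughout,
* IoT support — home wearable breast-ultrasound devices that remove a
  fraction of breast-examination patients from the walk-in stream and split
  the presenting remainder into standard, shorter and longer examinations.

==========  =========  ===================  ====
Scenario    Routing    Schedule             IoT
==========  =========  ===================  ====
S1          dedicated  4 until 300, then 3  off
S2          pooled     4 until 300, then 3  off
S3          dedicated  4 until 300, then 3  on
S4          pooled     4 until 300, then 3  on
S5          dedicated  3 throughout         off
S6          pooled     3 throughout         off
==========  =========  ===================  ====

Default arrival blocks and the examination-type catalog are the fitted
hourly interarrival and processing-time distributions of the studied
department (walk-in demand, 09:00-18:00 working day).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .distributions import DistributionSpec, parse_distribution
from .engine import (
    DAY_MINUTES,
    ArrivalSchedule,
    DoctorSchedule,
    USType,
    USTypeCatalog,
)

__all__ = [
    "IoTParams",
    "ScenarioConfig",
    "SCENARIO_IDS",
    "build_scenario",
    "apply_iot",
    "effective_service_time",
    "default_catalog",
    "working_day_arrivals",
    "full_day_arrivals",
    "baseline_doctor_schedule",
    "allday3_doctor_schedule",
    "save_scenario",
    "load_scenario",
]

SCENARIO_IDS = ("S1", "S2", "S3", "S4", "S5", "S6")

# hourly interarrival-time distributions of the working day, 09:00 -> minute 0
_WORKING_DAY_BLOCKS: tuple[tuple[float, float, str], ...] = (
    (0, 60, "-0.5 + Gamma(9.33, 0.851)"),     # 9-10 A.M.
    (60, 120, "54 * Beta(0.488, 2.34)"),      # 10-11 A.M.
    (120, 180, "-0.5 + 54 * Beta(0.729, 3.86)"),
    (180, 240, "-0.5 + 28 * Beta(0.669, 1.48)"),
    (240, 300, "-0.5 + 56 * Beta(0.451, 1.63)"),
    (300, 360, "54 * Beta(0.488, 2.34)"),     # 2-3 P.M.
    (360, 420, "Expo(11.7)"),
    (420, 480, "-0.5 + 61 * Beta(0.636, 1.95)"),
    (480, 540, "-0.5 + 61 * Beta(0.639, 1.21)"),
)

# remaining blocks of the 24-h day (minutes from midnight), used only by the
# synthetic log generator; the registry has no 7-8 A.M. block, so the
# overnight uniform block is extended to 8 A.M.
_OFF_HOURS_BLOCKS: tuple[tuple[float, float, str], ...] = (
    (0, 60, "Expo(39.6)"),        # tail of the 11 P.M. - 1 A.M. block
    (60, 480, "UNIF(1, 358)"),    # 1 A.M. - 7 A.M., extended to 8 A.M.
    (480, 540, "52 * Beta(0.576, 2.12)"),  # 8-9 A.M.
    # 540-1080: working day, shifted copy of _WORKING_DAY_BLOCKS
    (1080, 1380, "Expo(56.9)"),   # 6-11 P.M.
    (1380, 1440, "Expo(39.6)"),   # 11 P.M. - 1 A.M.
)

# examination-type catalog: (name, processing time, percentage of patients);
# percentages as printed sum to 99.9 and are renormalized by the catalog
_CATALOG_ROWS: tuple[tuple[str, str, float], ...] = (
    ("Abdominal Ultrasound", "9 + Expo(5.69)", 36.1),
    ("Urinary System Ultrasound", "9.5 + 11 * Beta(0.802, 1.36)", 13.0),
    ("Bilateral Breast Ultrasound", "UNIF(15, 30)", 11.2),
    ("Neck Ultrasound", "9.5 + 11 * Beta(0.857, 1.66)", 7.9),
    ("Right hip joint Ultrasound", "4.5 + Expo(2.92)", 7.8),
    ("Left hip joint Ultrasound", "4.5 + Expo(2.92)", 6.3),
    ("Superficial Tissue Ultrasound", "5 + Gamma(1.59, 3.26)", 6.1),
    ("Thyroid Ultrasound", "UNIF(5, 18)", 5.5),
    ("Upper Abdominal Ultrasound", "5 + Gamma(1.59, 3.26)", 3.5),
    ("Nuchal Translucency Measurement", "10 + Erlang(3.75, 2)", 2.5),
)

_PREP_TYPES = frozenset({"Abdominal Ultrasound", "Urinary System Ultrasound"})
_IOT_TYPES = frozenset({"Bilateral Breast Ultrasound"})


def default_catalog() -> USTypeCatalog:
    """The ten-type examination catalog with processing-time distributions.

    Full-bladder preparation applies to abdominal and urinary-system
    examinations; breast examinations are the IoT-eligible type.
    """
    return USTypeCatalog(tuple(
        USType(
            name=name,
            probability=pct / 100.0,
            processing=parse_distribution(expr),
            needs_prep=name in _PREP_TYPES,
            iot_eligible=name in _IOT_TYPES,
        )
        for name, expr, pct in _CATALOG_ROWS
    ))


def working_day_arrivals() -> ArrivalSchedule:
    """Hourly arrival blocks of the 540-minute working day (minute 0 = 09:00)."""
    return ArrivalSchedule(tuple(
        (a, b, parse_distribution(expr)) for a, b, expr in _WORKING_DAY_BLOCKS
    ))


def full_day_arrivals() -> ArrivalSchedule:
    """24-hour arrival blocks (minutes from midnight), for synthetic logs."""
    blocks = {a: (a, b, expr) for a, b, expr in _OFF_HOURS_BLOCKS}
    for a, b, expr in _WORKING_DAY_BLOCKS:
        blocks[a + 540.0] = (a + 540.0, b + 540.0, expr)
    ordered = [blocks[k] for k in sorted(blocks)]
    return ArrivalSchedule(tuple(
        (a, b, parse_distribution(expr)) for a, b, expr in ordered
    ))


def baseline_doctor_schedule() -> DoctorSchedule:
    """Four physicians 09:00-14:00, three for the rest of the working day."""
    return DoctorSchedule(((0, 300, 4), (300, DAY_MINUTES, 3)))


def allday3_doctor_schedule() -> DoctorSchedule:
    """Three physicians available throughout the working day (S5/S6)."""
    return DoctorSchedule(((0, DAY_MINUTES, 3),))


@dataclass(frozen=True)
class IoTParams:
    """Demand modification from home wearable breast-ultrasound devices.

    ``removal_prob`` of breast-examination patients never present at the
    hospital.  Of those who do present, ``nonuser_prob`` did not use the
    device and keep standard processing times; device users split evenly
    (``short_given_user``) into shorter examinations (lesion already located)
    and longer, more detailed ones.  The duration multipliers are design
    parameters — the study states the direction of the effect but not its
    magnitude — and every report should state the values used.
    """

    removal_prob: float = 0.30
    nonuser_prob: float = 0.70
    short_given_user: float = 0.50
    short_mult: float = 0.7
    long_mult: float = 1.3

    def __post_init__(self) -> None:
        for name in ("removal_prob", "nonuser_prob", "short_given_user"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if not self.short_mult <= 1.0 <= self.long_mult:
            raise ValueError("need short_mult <= 1 <= long_mult")


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything :func:`~sonoflow.engine.run_replication` needs for one day."""

    id: str
    routing: str  # "dedicated" | "pooled"
    schedule: DoctorSchedule
    arrival: ArrivalSchedule
    catalog: USTypeCatalog
    iot: IoTParams | None = None
    prep: DistributionSpec = field(
        default_factory=lambda: DistributionSpec("constant", (0.0,))
    )
    registration: float = 0.0  #: constant registration-desk delay, minutes
    horizon: float = DAY_MINUTES

    def check(self) -> None:
        if self.registration < 0:
            raise ValueError("registration delay cannot be negative")
        if self.routing not in ("dedicated", "pooled"):
            raise ValueError(f"routing must be 'dedicated' or 'pooled', got {self.routing!r}")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.schedule.n_doctors < 1:
            raise ValueError("schedule provides no physicians")
        # constructing the dataclasses already validated schedules/catalog

    def with_iot(self, iot: IoTParams | None) -> "ScenarioConfig":
        return replace(self, iot=iot)


def build_scenario(scenario_id: str, prep: DistributionSpec | str | None = None,
                   iot: IoTParams | None = None) -> ScenarioConfig:
    """Return the configuration of one of the six study scenarios.

    Parameters
    ----------
    scenario_id:
        One of ``S1`` … ``S6``.
    prep:
        Optional full-bladder preparation delay (distribution or expression
        string); defaults to ``CONST(0)``.
    iot:
        Override the IoT parameters for S3/S4 (ignored for the others, which
        have IoT off by definition).
    """
    sid = scenario_id.upper()
    if sid not in SCENARIO_IDS:
        raise ValueError(f"unknown scenario {scenario_id!r}; valid ids: {', '.join(SCENARIO_IDS)}")
    routing = "dedicated" if sid in ("S1", "S3", "S5") else "pooled"
    schedule = allday3_doctor_schedule() if sid in ("S5", "S6") else baseline_doctor_schedule()
    iot_params = (iot or IoTParams()) if sid in ("S3", "S4") else None
    if isinstance(prep, str):
        prep = parse_distribution(prep)
    return ScenarioConfig(
        id=sid,
        routing=routing,
        schedule=schedule,
        arrival=working_day_arrivals(),
        catalog=default_catalog(),
        iot=iot_params,
        prep=prep or DistributionSpec("constant", (0.0,)),
    )


def apply_iot(entry: USType, rng: np.random.Generator, iot: IoTParams) -> str | None:
    """IoT branching for one arriving patient of type ``entry``.

    Returns ``None`` if the patient never presents (thinned away), otherwise
    the examination class: ``standard``, ``iot_short`` or ``iot_long``.
    Non-eligible types always present with standard class (and consume no
    randomness, keeping non-breast demand identical with IoT on or off).
    """
    if not entry.iot_eligible:
        return "standard"
    if rng.random() < iot.removal_prob:
        return None
    if rng.random() < iot.nonuser_prob:
        return "standard"
    return "iot_short" if rng.random() < iot.short_given_user else "iot_long"


def effective_service_time(base_draw: float, iot_class: str,
                           iot: IoTParams | None = None) -> float:
    """Apply the IoT duration multiplier to a sampled processing time."""
    if iot_class == "standard":
        return base_draw
    if iot is None:
        raise ValueError(f"class {iot_class!r} requires IoT parameters")
    if iot_class == "iot_short":
        return iot.short_mult * base_draw
    if iot_class == "iot_long":
        return iot.long_mult * base_draw
    raise ValueError(f"unknown IoT class {iot_class!r}")


# ---------------------------------------------------------------------------
# YAML round-trip: distribution expressions appear verbatim as strings
# ---------------------------------------------------------------------------

def _config_to_dict(cfg: ScenarioConfig) -> dict:
    d = {
        "id": cfg.id,
        "routing": cfg.routing,
        "horizon": cfg.horizon,
        "registration": cfg.registration,
        "prep": str(cfg.prep),
        "schedule": [[s, e, c] for s, e, c in cfg.schedule.blocks],
        "arrival": [[s, e, str(spec)] for s, e, spec in cfg.arrival.blocks],
        "catalog": [
            {
                "name": t.name,
                "probability": t.probability,
                "processing": str(t.processing),
                "needs_prep": t.needs_prep,
                "iot_eligible": t.iot_eligible,
            }
            for t in cfg.catalog.entries
        ],
        "iot": None,
    }
    if cfg.iot is not None:
        d["iot"] = {
            "removal_prob": cfg.iot.removal_prob,
            "nonuser_prob": cfg.iot.nonuser_prob,
            "short_given_user": cfg.iot.short_given_user,
            "short_mult": cfg.iot.short_mult,
            "long_mult": cfg.iot.long_mult,
        }
    return d


def save_scenario(cfg: ScenarioConfig, path) -> None:
    """Write a scenario to YAML so users can derive custom scenarios by editing."""
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(cfg), fh, sort_keys=False)


def load_scenario(path) -> ScenarioConfig:
    """Read a scenario written by :func:`save_scenario` (or hand-edited)."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return ScenarioConfig(
        id=d["id"],
        routing=d["routing"],
        schedule=DoctorSchedule(tuple((s, e, c) for s, e, c in d["schedule"])),
        arrival=ArrivalSchedule(tuple(
            (s, e, parse_distribution(expr)) for s, e, expr in d["arrival"]
        )),
        catalog=USTypeCatalog(tuple(
            USType(
                name=t["name"],
                probability=t["probability"],
                processing=parse_distribution(t["processing"]),
                needs_prep=t["needs_prep"],
                iot_eligible=t["iot_eligible"],
            )
            for t in d["catalog"]
        )),
        iot=IoTParams(**d["iot"]) if d.get("iot") else None,
        prep=parse_distribution(d["prep"]),
        registration=d.get("registration", 0.0),
        horizon=d.get("horizon", DAY_MINUTES),
    )
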