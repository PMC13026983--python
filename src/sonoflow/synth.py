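"""Synthetic timestamped arrival logs and descriptive summaries.

The department's historical registry is confidential, so every pipeline
stage is exercised on synthetic logs that carry the same statistical
structure: hourly arrival intensity from the fitted interarrival blocks
(24-hour coverage, minutes from midnight) and an examination type per
patient from the catalog mix.  Logs are plain tables — one row per patient
with columns ``day``, ``minutes`` (from 00:00) and ``us_type`` — written and
read as CSV.

Descriptive summaries reproduce the registry-style tables: per-group count
statistics (mean, SE of the mean, sd, min, quartiles, max) with
linear-interpolation quartiles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .distributions import sample
from .engine import ArrivalSchedule, USTypeCatalog, draw_patient_type
from .scenarios import default_catalog, full_day_arrivals

__all__ = ["generate_log", "summarize", "write_log", "read_log"]

LOG_COLUMNS = ("day", "minutes", "us_type")


def generate_log(
    days: int,
    seed: int,
    schedule: ArrivalSchedule | None = None,
    catalog: USTypeCatalog | None = None,
    rate_multipliers=None,
) -> pd.DataFrame:
    """Generate a ``days``-day synthetic arrival log.

    Arrivals are produced block-by-block: each block's renewal stream starts
    at the block start and draws gaps from that block's interarrival
    distribution until the block ends.  (Unlike the day engine's
    current-block rule, a draw never crosses a block boundary — essential
    here because the overnight block's mean gap of ~3 h would otherwise
    swallow the morning blocks.)  Each arrival is assigned an examination
    type from the catalog.

    Parameters
    ----------
    days:
        Number of days to simulate (each day restarts at midnight).
    seed:
        Seed for the single random stream; identical inputs reproduce the
        log exactly.
    schedule:
        24-hour arrival schedule; defaults to the fitted hourly blocks.
    catalog:
        Examination-type catalog; defaults to the ten-type study mix.
    rate_multipliers:
        Optional per-day multiplier on arrival intensity (e.g. to emulate
        the weekday/weekend level difference); entry d scales day d's
        interarrival draws by 1/multiplier.  Default: all ones.
    """
    if days < 1:
        raise ValueError(f"days must be >= 1, got {days}")
    schedule = schedule or full_day_arrivals()
    catalog = catalog or default_catalog()
    if rate_multipliers is None:
        mult = np.ones(days)
    else:
        mult = np.asarray(rate_multipliers, dtype=float)
        if mult.shape != (days,) or np.any(mult <= 0):
            raise ValueError("rate_multipliers needs one positive value per day")
    rng = np.random.default_rng(seed)
    rows = []
    for day in range(days):
        # block-by-block: each block's renewal stream restarts at its start,
        # so a long overnight gap can never swallow the morning blocks
        for start, end, spec in schedule.blocks:
            t = start
            while True:
                t = t + max(sample(spec, rng), 1e-6) / mult[day]
                if t >= end:
                    break
                rows.append((day, t, draw_patient_type(catalog, rng)))
    return pd.DataFrame(rows, columns=list(LOG_COLUMNS))


def summarize(log: pd.DataFrame, grouping: str = "day") -> pd.DataFrame:
    """Descriptive statistics of arrival counts.

    ``grouping='day'`` summarizes the per-day patient counts in a single row;
    ``grouping='hour'`` summarizes per-hour-of-day counts across days, one
    row per hour.  Quartiles use linear interpolation; SE is sd/sqrt(n).
    """
    if log.empty:
        raise ValueError("cannot summarize an empty log")
    if grouping == "day":
        counts = log.groupby("day").size()
        return pd.DataFrame([_describe_counts("all days", counts)])
    if grouping == "hour":
        hours = (log["minutes"] // 60).astype(int)
        n_days = log["day"].nunique()
        days_index = sorted(log["day"].unique())
        rows = []
        for hour, sub in log.groupby(hours):
            per_day = sub.groupby("day").size().reindex(days_index, fill_value=0)
            rows.append(_describe_counts(hour, per_day))
        return pd.DataFrame(rows)
    raise ValueError(f"grouping must be 'day' or 'hour', got {grouping!r}")


def _describe_counts(group, counts: pd.Series) -> dict:
    x = counts.to_numpy(dtype=float)
    n = x.size
    sd = float(x.std(ddof=1)) if n > 1 else 0.0
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    return {
        "group": group,
        "n": n,
        "mean": float(x.mean()),
        "se_mean": sd / np.sqrt(n),
        "sd": sd,
        "min": float(x.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(x.max()),
    }


def write_log(log: pd.DataFrame, path) -> None:
    """Write an arrival log as CSV with the fixed column set."""
    log.loc[:, list(LOG_COLUMNS)].to_csv(path, index=False)


def read_log(path) -> pd.DataFrame:
    """Read an arrival log CSV written by :func:`write_log`."""
    df = pd.read_csv(path)
    missing = set(LOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"arrival log missing columns: {sorted(missing)}")
    return df
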