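"""Data-validity rules for continuous rotating-analyzer sampling.

Three rules govern which observations enter daily emission rates:

* **Event exclusion** — opening the large roll-up door or the bunk flaps
  disrupts the enclosure's gas equilibrium; readings from the affected
  enclosure during the event, 5 min before and 15 min after are excluded.
  Small-door entry/exit is deemed negligible and excludes nothing.
* **Period validity** — a 15-min sampling period is valid only if at least
  4 min of readings (16 readings at the 15-s cadence) survive exclusion.
* **Day validity and substitution** — a gas-day needs at least four valid
  periods; an invalid day may be reconstructed as the arithmetic mean of the
  daily per-animal emissions 2 d before and 2 d after (all four neighbours
  must exist and be valid; there is no deeper fallback).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "PRE_EVENT_S",
    "POST_EVENT_S",
    "PERIOD_S",
    "READING_INTERVAL_S",
    "MIN_VALID_READINGS",
    "MIN_VALID_PERIODS",
    "UnrecoverableDayError",
    "mark_exclusions",
    "summarize_periods",
    "substitute_daily",
]

PRE_EVENT_S = 5 * 60
POST_EVENT_S = 15 * 60
PERIOD_S = 15 * 60
READING_INTERVAL_S = 15
#: 4 min of 15-s readings
MIN_VALID_READINGS = 16
MIN_VALID_PERIODS = 4
DAY_S = 86_400

EXCLUDING_EVENT_KINDS = frozenset({"large_door", "bunk_flap"})
NEUTRAL_EVENT_KINDS = frozenset({"small_door"})


class UnrecoverableDayError(ValueError):
    """An invalid gas-day whose neighbour-mean substitution is impossible."""


def mark_exclusions(readings: pd.DataFrame, events: pd.DataFrame) -> pd.DataFrame:
    """Flag readings falling in door/bunk-flap exclusion windows.

    Parameters
    ----------
    readings
        Long table with columns ``cycle``, ``time_s``, ``source`` and any
        value columns; an ``excluded`` boolean column is (re)computed.
    events
        Table with columns ``cycle``, ``cpe_id``, ``kind``, ``open_s``,
        ``close_s``.

    Returns
    -------
    DataFrame
        Copy of ``readings`` with ``excluded`` set.  Windows from overlapping
        events are unioned (set semantics), so the operation is idempotent.
    """
    out = readings.copy()
    excluded = np.zeros(len(out), dtype=bool)
    if len(events):
        unknown = set(events["kind"].unique()) - EXCLUDING_EVENT_KINDS - NEUTRAL_EVENT_KINDS
        if unknown:
            raise ValueError(f"unknown event kind(s): {sorted(unknown)}")
        if (events["close_s"] < events["open_s"]).any():
            raise ValueError("event close time before open time")
        active = events[events["kind"].isin(EXCLUDING_EVENT_KINDS)]
        time_s = out["time_s"].to_numpy()
        # merged window edges per (cycle, enclosure), then a single
        # searchsorted pass per group: odd insertion index = inside a window
        for (cycle, cpe_id), ev in active.groupby(["cycle", "cpe_id"]):
            sel = (out["cycle"] == cycle) & (out["source"].astype(str) == cpe_id)
            idx = np.flatnonzero(sel.to_numpy())
            if idx.size == 0:
                continue
            starts = (ev["open_s"] - PRE_EVENT_S).to_numpy(dtype=float)
            ends = (ev["close_s"] + POST_EVENT_S).to_numpy(dtype=float)
            order = np.argsort(starts)
            starts, ends = starts[order], ends[order]
            merged = []
            for s, e in zip(starts, ends):
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            m = np.array(merged)
            t = time_s[idx]
            i = np.searchsorted(m[:, 0], t, side="right") - 1
            inside = (i >= 0) & (t <= m[np.maximum(i, 0), 1])
            excluded[idx] |= inside
    out["excluded"] = excluded
    return out


def summarize_periods(readings: pd.DataFrame) -> pd.DataFrame:
    """Collapse 15-s readings into per-period summaries with validity flags.

    A period is the 15-min rotation slot ``time_s // 900``; the period is
    assigned to the day containing its start time.  Excluded readings do not
    contribute to the period mean; a period is valid iff at least
    :data:`MIN_VALID_READINGS` readings survive.
    """
    df = readings.copy()
    if "excluded" not in df.columns:
        df["excluded"] = False
    df["period"] = df["time_s"] // PERIOD_S
    keep = ~df["excluded"]
    df["_v"] = df["value"].astype(float).where(keep)
    df["_t"] = df["temp_C"].astype(float).where(keep)
    grouped = df.groupby(["cycle", "gas", "source", "period"], observed=True, sort=True)
    out = grouped.agg(
        n_readings=("value", "size"),
        n_valid=("_v", "count"),
        mean_value=("_v", "mean"),
        mean_temp_C=("_t", "mean"),
    ).reset_index()
    out["start_s"] = out["period"] * PERIOD_S
    out["day"] = out["start_s"] // DAY_S
    out["is_valid"] = out["n_valid"] >= MIN_VALID_READINGS
    return out


def substitute_daily(daily: pd.DataFrame, value_col: str = "g_per_animal") -> pd.DataFrame:
    """Apply the neighbour-mean rule to invalid gas-days.

    ``daily`` must hold one row per (cycle, cpe_id, gas, day) with a boolean
    ``day_valid`` column.  For every invalid day ``d`` the substituted value
    is the mean of days ``d-2, d-1, d+1, d+2``, all of which must exist and
    be valid, else :class:`UnrecoverableDayError` is raised.
    """
    out = daily.copy()
    out["substituted"] = False
    bad = out.index[~out["day_valid"]]
    if len(bad) == 0:
        return out
    keyed = out.set_index(["cycle", "cpe_id", "gas", "day"])
    for idx in bad:
        row = out.loc[idx]
        neighbours = []
        for off in (-2, -1, 1, 2):
            key = (row["cycle"], row["cpe_id"], row["gas"], row["day"] + off)
            try:
                nb = keyed.loc[key]
            except KeyError:
                raise UnrecoverableDayError(
                    f"day {row['day']} of {row['cpe_id']} ({row['gas']}, cycle "
                    f"{row['cycle']}) invalid and neighbour day {row['day'] + off} missing"
                ) from None
            if not bool(nb["day_valid"]):
                raise UnrecoverableDayError(
                    f"day {row['day']} of {row['cpe_id']} ({row['gas']}, cycle "
                    f"{row['cycle']}) invalid and neighbour day {row['day'] + off} also invalid"
                )
            neighbours.append(float(nb[value_col]))
        out.loc[idx, value_col] = float(np.mean(neighbours))
        out.loc[idx, "substituted"] = True
    return out


def validity_report(daily: pd.DataFrame) -> pd.DataFrame:
    """Per gas-day validity summary (n_valid periods, substitution flag)."""
    cols = ["cycle", "cpe_id", "gas", "day", "n_valid", "day_valid"]
    if "substituted" in daily.columns:
        cols.append("substituted")
    return daily[cols].copy()
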