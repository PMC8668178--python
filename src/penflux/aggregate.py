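"""Daily, cumulative and weight-standardized emissions.

The chain mirrors the measurement protocol: per-period fluxes from valid
rotation periods are averaged into a daily g/min rate per enclosure and gas
(days anchored at 0800, i.e. ``time_s = 0``), multiplied by 1,440 min and
divided by that day's headcount to give g/animal/day, summed over the interim
body-weight intervals (days 0–7, 0–14, 0–28, 0–56) and the full 91-d period,
and finally divided by the pen-mean unshrunk BW at the interval end (or the
pen-mean HCW for the 91-d interval).

Measurements end at 0500 on the morning of day 91, before a complete daily
window, so the 0–91 cumulative covers days 0..90 inclusive.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import flux as fluxmod
from . import validity as vmod

__all__ = [
    "INTERVALS",
    "period_fluxes",
    "daily_emissions",
    "cumulative",
    "cumulative_table",
    "standardize",
    "standardized_cumulative",
]

#: Interval end-days; interval (0, d) sums daily emissions over days 0..d-1.
INTERVALS = (7, 14, 28, 56, 91)
MIN_PER_DAY = 1_440.0


def period_fluxes(periods: pd.DataFrame, fans: pd.DataFrame) -> pd.DataFrame:
    """Net concentration, airflow and flux for every valid enclosure period.

    Parameters
    ----------
    periods
        Output of :func:`penflux.validity.summarize_periods` over both the
        ambient source and the enclosures.
    fans
        Fan calibrations: ``cycle, cpe_id, fan_id, t0_s, flow_start, t1_s,
        flow_end`` (m³/min).

    Each enclosure period is paired with the most recent valid ambient period
    of the same cycle and gas (the rotation samples ambient once per sweep);
    periods before the first ambient sweep use the first one.  Invalid
    enclosure periods are retained with NaN flux so day-level validity can be
    assessed, but carry no flux information.
    """
    amb = periods[(periods["source"] == "ambient") & periods["is_valid"]]
    cpe = periods[periods["source"] != "ambient"].copy()
    amb = amb[["cycle", "gas", "period", "mean_value"]].rename(
        columns={"mean_value": "ambient_value", "period": "ambient_period"}
    )

    merged = []
    for (cycle, gas), grp in cpe.groupby(["cycle", "gas"], observed=True):
        a = amb[(amb["cycle"] == cycle) & (amb["gas"] == gas)].sort_values("ambient_period")
        g = grp.sort_values("period")
        m = pd.merge_asof(
            g,
            a[["ambient_period", "ambient_value"]],
            left_on="period",
            right_on="ambient_period",
            direction="backward",
        )
        # periods preceding the first ambient sweep fall back to it
        m["ambient_value"] = m["ambient_value"].bfill()
        merged.append(m)
    out = pd.concat(merged, ignore_index=True)

    out["net_value"] = fluxmod.net_concentration(out["mean_value"], out["ambient_value"])

    # airflow: sum of per-fan linear interpolation at the period midpoint
    mid = out["start_s"] + vmod.PERIOD_S / 2.0
    airflow = np.full(len(out), np.nan)
    for (cycle, cpe_id), fg in fans.groupby(["cycle", "cpe_id"]):
        sel = (out["cycle"] == cycle) & (out["source"].astype(str) == cpe_id)
        if not sel.any():
            continue
        t = mid[sel].to_numpy(dtype=float)
        total = np.zeros_like(t)
        for fan in fg.itertuples(index=False):
            cal = fluxmod.FanCalibration(
                str(fan.fan_id), cpe_id, fan.t0_s, fan.flow_start, fan.t1_s, fan.flow_end
            )
            total += np.asarray(cal.flow_at(t))
        airflow[sel.to_numpy()] = total
    out["airflow_m3_min"] = airflow

    flux = np.full(len(out), np.nan)
    for gas, gg in out.groupby("gas", observed=True):
        valid = gg["is_valid"] & gg["airflow_m3_min"].notna() & gg["net_value"].notna()
        idx = gg.index[valid]
        flux[out.index.get_indexer(idx)] = fluxmod.period_flux(
            gg.loc[idx, "net_value"].to_numpy(),
            str(gas),
            gg.loc[idx, "airflow_m3_min"].to_numpy(),
            gg.loc[idx, "mean_temp_C"].to_numpy(),
        )
    out["flux_g_min"] = flux
    out = out.rename(columns={"source": "cpe_id"})
    out["cpe_id"] = out["cpe_id"].astype(str)
    return out


def daily_emissions(
    fluxes: pd.DataFrame, inventory: pd.DataFrame, substitute: bool = True
) -> pd.DataFrame:
    """Daily per-animal emissions per enclosure and gas.

    The daily g/min rate is the mean flux over the day's valid periods
    (at most 11 are available from the continuous nine-source rotation);
    multiplied by 1,440 min and divided by the day's headcount.  Days with
    fewer than four valid periods are invalid and, when ``substitute`` is
    true, filled by the neighbour-mean rule.
    """
    grouped = fluxes.groupby(["cycle", "cpe_id", "gas", "day"], observed=True)
    daily = grouped.agg(
        n_periods=("flux_g_min", "size"),
        n_valid=("is_valid", "sum"),
        mean_flux_g_min=("flux_g_min", "mean"),  # NaN-aware: invalid periods are NaN
    ).reset_index()
    daily["n_valid"] = daily["n_valid"].astype(int)
    daily["day_valid"] = daily["n_valid"] >= vmod.MIN_VALID_PERIODS
    daily.loc[~daily["day_valid"], "mean_flux_g_min"] = np.nan

    inv = inventory.rename(columns={"headcount": "_head"})[["cycle", "cpe_id", "day", "_head"]]
    daily = daily.merge(inv, on=["cycle", "cpe_id", "day"], how="left")
    if daily["_head"].isna().any():
        missing = daily.loc[daily["_head"].isna(), ["cycle", "cpe_id", "day"]]
        raise ValueError(f"missing inventory for:\n{missing.head()}")
    if (daily["_head"] <= 0).any():
        raise ValueError("headcount must be positive")
    daily = daily.rename(columns={"_head": "headcount"})
    daily["g_per_animal"] = daily["mean_flux_g_min"] * MIN_PER_DAY / daily["headcount"]

    if substitute:
        daily = vmod.substitute_daily(daily, value_col="g_per_animal")
    else:
        daily["substituted"] = False
    return daily


def cumulative(daily_values: Sequence[float], interval_end: int) -> float:
    """Sum per-animal daily emissions over days ``0 .. interval_end - 1``."""
    vals = np.asarray(daily_values, dtype=float)[: int(interval_end)]
    if len(vals) == 0:
        return 0.0
    if np.isnan(vals).any():
        raise ValueError("missing daily values inside the interval")
    return float(vals.sum())


def cumulative_table(
    daily: pd.DataFrame, intervals: Optional[Sequence[int]] = None
) -> pd.DataFrame:
    """Cumulative g/animal per enclosure, gas and interval.

    By default the canonical interim intervals are used, truncated to the
    days actually present, with the full run length always included (so
    shortened synthetic runs still expose a final cumulative).
    """
    rows = []
    for (cycle, cpe_id, gas), grp in daily.groupby(["cycle", "cpe_id", "gas"], observed=True):
        grp = grp.sort_values("day")
        days = grp["day"].to_numpy()
        vals = grp["g_per_animal"].to_numpy()
        n_days = int(days.max()) + 1
        ends = (
            sorted({i for i in INTERVALS if i <= n_days} | {n_days})
            if intervals is None
            else intervals
        )
        for end in ends:
            if end > n_days:
                continue  # shorter runs simply lack the longer intervals
            sel = days < end
            if sel.sum() < end or np.isnan(vals[sel]).any():
                raise ValueError(
                    f"incomplete daily series for {cpe_id} {gas} interval 0-{end}"
                )
            rows.append(
                {
                    "cycle": cycle,
                    "cpe_id": cpe_id,
                    "gas": gas,
                    "interval_end": end,
                    "total_g_per_animal": float(vals[sel].sum()),
                }
            )
    return pd.DataFrame(rows)


def standardize(cum_g: float, weight_kg: float) -> float:
    """Cumulative emission per kilogram of body or carcass weight (g/kg)."""
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    return cum_g / weight_kg


def standardized_cumulative(
    cum: pd.DataFrame,
    bw_means: pd.DataFrame,
    hcw_means: Mapping | pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Attach g/kg BW (interval-end pen-mean BW) and g/kg HCW (91-d only).

    ``bw_means`` holds pen-mean unshrunk BW per measurement day with columns
    ``cycle, cpe_id, day, bw_kg``; ``hcw_means`` pen-mean HCW with columns
    ``cycle, cpe_id, hcw_kg``.
    """
    out = cum.copy()
    bw = bw_means.rename(columns={"day": "interval_end", "bw_kg": "_bw"})
    out = out.merge(bw, on=["cycle", "cpe_id", "interval_end"], how="left")
    out["per_kg_bw"] = [
        standardize(g, w) if pd.notna(w) else np.nan
        for g, w in zip(out["total_g_per_animal"], out["_bw"])
    ]
    out = out.rename(columns={"_bw": "bw_kg"})
    out["per_kg_hcw"] = np.nan
    if hcw_means is not None:
        if isinstance(hcw_means, pd.DataFrame):
            h = hcw_means[["cycle", "cpe_id", "hcw_kg"]]
        else:
            h = pd.DataFrame(
                [
                    {"cycle": c, "cpe_id": p, "hcw_kg": v}
                    for (c, p), v in dict(hcw_means).items()
                ]
            )
        out = out.merge(h, on=["cycle", "cpe_id"], how="left")
        final = out["interval_end"] == max(INTERVALS)
        out.loc[final, "per_kg_hcw"] = [
            standardize(g, w) if pd.notna(w) else np.nan
            for g, w in zip(
                out.loc[final, "total_g_per_animal"], out.loc[final, "hcw_kg"]
            )
        ]
    return out
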