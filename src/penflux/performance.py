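"""Growth-performance and carcass-derived quantities.

Pen-level feeding metrics (DMI, ADG, G:F, dressing percentage), the USDA
yield-grade equation and its discrete 1–5 classes, marbling-based quality
grading for A-maturity carcasses, the temperature–humidity index (THI) used
to summarise heat load, and Warner–Bratzler shear-force averaging.

All pen metrics are computed from pen means of unshrunk body weights — the
enclosure, not the animal, is the experimental unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "compute_dmi",
    "average_daily_gain",
    "gain_to_feed",
    "dressing_percent",
    "yield_grade",
    "yield_grade_class",
    "thi",
    "quality_class",
    "wbsf_mean",
    "PenPerformance",
    "pen_performance",
]

QUALITY_CLASSES = ("Prime", "upper 2/3 Choice", "low Choice", "Select", "Standard")


def compute_dmi(
    total_delivered_asfed_kg: float,
    orts_asfed_kg: float,
    cattle_days: float,
    dm_fraction: float,
) -> float:
    """Dry-matter intake, kg·animal⁻¹·d⁻¹.

    Feed delivered less refusals, per cattle-day, scaled by the diet
    dry-matter fraction.
    """
    if cattle_days <= 0:
        raise ValueError("cattle_days must be positive")
    if not 0 < dm_fraction <= 1:
        raise ValueError("dm_fraction must be in (0, 1]")
    if orts_asfed_kg > total_delivered_asfed_kg:
        raise ValueError("refused feed exceeds delivered feed")
    return (total_delivered_asfed_kg - orts_asfed_kg) / cattle_days * dm_fraction


def average_daily_gain(initial_bw_kg: float, final_bw_kg: float, days: int = 91) -> float:
    """ADG (kg/d) from pen-mean unshrunk initial and final BW."""
    if days <= 0:
        raise ValueError("days must be positive")
    return (final_bw_kg - initial_bw_kg) / days


def gain_to_feed(adg_kg_d: float, dmi_kg_d: float) -> float:
    """G:F, the quotient of ADG and DMI (kg gain per kg dry matter)."""
    if dmi_kg_d <= 0:
        raise ValueError("DMI must be positive")
    return adg_kg_d / dmi_kg_d


def dressing_percent(hcw_kg: float, final_bw_kg: float) -> float:
    """Hot carcass weight as a percentage of unshrunk final BW."""
    if final_bw_kg <= 0:
        raise ValueError("final BW must be positive")
    return 100.0 * hcw_kg / final_bw_kg


def yield_grade(adj_fat_cm, kph_pct, hcw_kg, lm_cm2):
    """Continuous USDA yield grade (metric coefficients), unrounded.

    YG = 2.50 + 0.98·fat(cm) + 0.2·KPH(%) + 0.0084·HCW(kg) − 0.05·LM(cm²)
    """
    return (
        2.50
        + 0.98 * np.asarray(adj_fat_cm, dtype=float)
        + 0.2 * np.asarray(kph_pct, dtype=float)
        + 0.0084 * np.asarray(hcw_kg, dtype=float)
        - 0.05 * np.asarray(lm_cm2, dtype=float)
    )


def yield_grade_class(yg_continuous) -> int:
    """Discrete YG 1–5: floor of the continuous grade, clamped to [1, 5]."""
    return int(min(5, max(1, np.floor(yg_continuous))))


def thi(ta_C: float, rh_pct: float) -> float:
    """Temperature–humidity index from ambient temperature and RH.

    THI = 0.8·TA + (RH/100)·(TA − 14.4) + 46.4
    """
    if not 0 <= rh_pct <= 100:
        raise ValueError("relative humidity must be within [0, 100] %")
    return 0.8 * ta_C + (rh_pct * 0.01) * (ta_C - 14.4) + 46.4


def quality_class(marbling: float, overall_maturity: float = 100.0) -> str:
    """Grid quality category for young (A/B-maturity) carcasses.

    Marbling is on the 100-points-per-degree scale (500 = Small⁰⁰).  Standard
    USDA marbling-degree boundaries: ≥700 Prime; 600–699 upper 2/3 Choice;
    500–599 low Choice; 400–499 Select; <400 Standard.  Hardbone (C+)
    maturity grading is out of scope.
    """
    if marbling < 0:
        raise ValueError("marbling score must be non-negative")
    if overall_maturity >= 300:
        raise ValueError("C+ maturity grading not supported")
    if marbling >= 700:
        return "Prime"
    if marbling >= 600:
        return "upper 2/3 Choice"
    if marbling >= 500:
        return "low Choice"
    if marbling >= 400:
        return "Select"
    return "Standard"


def wbsf_mean(core_forces_kg: Sequence[float]) -> float:
    """Single shear-force value per steak: mean of exactly six cores (kg)."""
    cores = np.asarray(core_forces_kg, dtype=float)
    if cores.shape != (6,):
        raise ValueError(f"expected exactly 6 cores, got {cores.size}")
    return float(cores.mean())


@dataclass
class PenPerformance:
    """Growth and carcass summary for one enclosure."""

    cycle: int
    cpe_id: str
    initial_bw_kg: float
    final_bw_kg: float
    dmi_kg_d: float
    adg_kg_d: float
    gain_feed: float
    hcw_kg: float
    dressing_pct: float


def pen_performance(
    bw: pd.DataFrame,
    feed: pd.DataFrame,
    pens: pd.DataFrame,
    carcass: pd.DataFrame,
    inventory: pd.DataFrame,
    dm_fraction: float,
    days: int = 91,
) -> pd.DataFrame:
    """Per-enclosure performance table from the raw input tables.

    ``bw``: individual weights (cycle, cpe_id, animal_id, day, bw_kg);
    ``feed``: daily as-fed deliveries; ``pens``: per-pen metadata including
    total refused feed (orts_asfed_kg); ``carcass``: individual carcass
    records; ``inventory``: daily headcounts (for cattle-days).
    """
    rows = []
    final_day = int(bw["day"].max())
    for (cycle, cpe_id), grp in bw.groupby(["cycle", "cpe_id"]):
        initial = grp.loc[grp["day"] == 0, "bw_kg"].mean()
        final = grp.loc[grp["day"] == final_day, "bw_kg"].mean()
        delivered = feed.loc[
            (feed["cycle"] == cycle) & (feed["cpe_id"] == cpe_id), "delivered_asfed_kg"
        ].sum()
        orts = float(
            pens.loc[
                (pens["cycle"] == cycle) & (pens["cpe_id"] == cpe_id), "orts_asfed_kg"
            ].iloc[0]
        )
        cattle_days = float(
            inventory.loc[
                (inventory["cycle"] == cycle) & (inventory["cpe_id"] == cpe_id),
                "headcount",
            ].sum()
        )
        dmi = compute_dmi(delivered, orts, cattle_days, dm_fraction)
        adg = average_daily_gain(initial, final, days=days)
        hcw = carcass.loc[
            (carcass["cycle"] == cycle) & (carcass["cpe_id"] == cpe_id), "hcw_kg"
        ].mean()
        rows.append(
            {
                "cycle": cycle,
                "cpe_id": cpe_id,
                "initial_bw_kg": initial,
                "final_bw_kg": final,
                "dmi_kg_d": dmi,
                "adg_kg_d": adg,
                "gain_feed": gain_to_feed(adg, dmi),
                "hcw_kg": hcw,
                "dressing_pct": dressing_percent(hcw, final),
            }
        )
    return pd.DataFrame(rows)
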