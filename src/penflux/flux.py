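"""Gas flux computation for mechanically ventilated pen enclosures.

Converts net gas concentrations (enclosure minus ambient) into mass emission
rates (g/min) using the ideal-gas molar-volume conversion, and reconstructs
enclosure airflow from two-point fan efficiency decay calibrations.

Concentrations are volume-ratio measurements reported in µg/L (NH3, H2S) or
mg/L (CH4, CO2, N2O).  For a net concentration ``c``, airflow ``Q`` (m³/min),
sample temperature ``T`` (°C) and molecular weight ``MW`` (g/mol)::

    flux (g/min) = c * Q * 1000 / (Vs * (T + 273.15) / 273.15) * MW / denom

where ``Vs`` = 22.4 L/mol and ``denom`` is 1e6 for mg/L gases and 1e9 for
µg/L gases.  Net concentrations may be negative (an enclosure can act as a
sink relative to ambient, as observed for N2O) and the sign is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np

__all__ = [
    "VS_L_PER_MOL",
    "KELVIN_OFFSET",
    "LITRES_PER_M3",
    "GasSpecies",
    "GASES",
    "get_species",
    "FanCalibration",
    "airflow_at",
    "net_concentration",
    "period_flux",
]

#: Molar volume (L/mol) at the analyzers' constant temperature and pressure.
VS_L_PER_MOL = 22.4
KELVIN_OFFSET = 273.15
LITRES_PER_M3 = 1000.0


@dataclass(frozen=True)
class GasSpecies:
    """A measured gas: name, molecular weight and concentration unit."""

    name: str
    molecular_weight: float  # g/mol
    concentration_unit: str  # "ug/L" or "mg/L"
    unit_denominator: float  # 1e9 for ug/L, 1e6 for mg/L

    def __post_init__(self) -> None:
        expected = {"ug/L": 1e9, "mg/L": 1e6}
        if self.concentration_unit not in expected:
            raise ValueError(f"unknown concentration unit {self.concentration_unit!r}")
        if self.unit_denominator != expected[self.concentration_unit]:
            raise ValueError(
                f"unit denominator {self.unit_denominator} inconsistent with "
                f"{self.concentration_unit}"
            )


GASES = {
    g.name: g
    for g in (
        GasSpecies("NH3", 17.03, "ug/L", 1e9),
        GasSpecies("H2S", 34.08, "ug/L", 1e9),
        GasSpecies("CH4", 16.04, "mg/L", 1e6),
        GasSpecies("CO2", 44.01, "mg/L", 1e6),
        GasSpecies("N2O", 44.01, "mg/L", 1e6),
    )
}


def get_species(species: Union[str, GasSpecies]) -> GasSpecies:
    if isinstance(species, GasSpecies):
        return species
    try:
        return GASES[species]
    except KeyError:
        raise KeyError(f"unknown gas species {species!r}; known: {sorted(GASES)}") from None


@dataclass(frozen=True)
class FanCalibration:
    """Two-point airflow calibration for one ventilation fan.

    Flow is measured at the start (``t0``) and end (``t1``) of a cycle; fan
    efficiency decays between the two, modelled as linear in time (two
    calibration points admit exactly a line).
    """

    fan_id: str
    cpe_id: str
    t0: float
    flow_start: float  # m³/min at t0
    t1: float
    flow_end: float  # m³/min at t1

    def __post_init__(self) -> None:
        if self.t1 <= self.t0:
            raise ValueError("calibration end time must be after start time")
        if self.flow_start <= 0 or self.flow_end <= 0:
            raise ValueError("fan flow rates must be positive")

    def flow_at(self, t):
        """Linearly interpolated flow (m³/min) at time ``t`` within [t0, t1]."""
        t = np.asarray(t, dtype=float)
        if np.any(t < self.t0) or np.any(t > self.t1):
            raise ValueError(
                f"time outside calibration window [{self.t0}, {self.t1}] for fan "
                f"{self.fan_id}; no extrapolation"
            )
        frac = (t - self.t0) / (self.t1 - self.t0)
        out = self.flow_start + frac * (self.flow_end - self.flow_start)
        return out if out.shape else float(out)


def airflow_at(calibrations: Iterable[FanCalibration], t):
    """Total enclosure outflow (m³/min) at time ``t``.

    The sum of the per-fan linearly interpolated flows; the calibrations must
    all belong to the same enclosure and cover ``t``.
    """
    cals = list(calibrations)
    if not cals:
        raise ValueError("no fan calibrations supplied")
    cpes = {c.cpe_id for c in cals}
    if len(cpes) > 1:
        raise ValueError(f"calibrations span multiple enclosures: {sorted(cpes)}")
    total = sum(c.flow_at(t) for c in cals)
    return total


def net_concentration(cpe_value, ambient_value):
    """Enclosure concentration minus concurrent ambient concentration.

    Both values must be in the same unit for the same species.  The result may
    be negative and is never clamped: enclosures can read below ambient.
    """
    return np.subtract(cpe_value, ambient_value)


def period_flux(mean_net_conc, species, airflow_m3_min, temp_C):
    """Mass emission rate (g/min) for one sampling period.

    Parameters
    ----------
    mean_net_conc
        Mean net concentration over the period, in the species' unit
        (µg/L or mg/L).  Scalar or array.
    species
        Gas name or :class:`GasSpecies`.
    airflow_m3_min
        Enclosure outflow during the period (m³/min); must be positive.
    temp_C
        Sample temperature (°C); must exceed absolute zero.

    Returns
    -------
    float or ndarray
        Emission rate in g/min; sign follows the net concentration.
    """
    sp = get_species(species)
    conc = np.asarray(mean_net_conc, dtype=float)
    q = np.asarray(airflow_m3_min, dtype=float)
    t = np.asarray(temp_C, dtype=float)
    if np.any(q <= 0):
        raise ValueError("airflow must be positive")
    if np.any(t <= -KELVIN_OFFSET):
        raise ValueError("temperature below absolute zero")
    molar_volume = VS_L_PER_MOL * (t + KELVIN_OFFSET) / KELVIN_OFFSET
    flux = conc * q * LITRES_PER_M3 / molar_volume * sp.molecular_weight
    flux = flux / sp.unit_denominator
    return flux if flux.shape else float(flux)


def concentration_for_flux(flux_g_min, species, airflow_m3_min, temp_C):
    """Invert :func:`period_flux`: the net concentration producing a flux.

    Used by the synthetic generator and by sealed-box recovery checks: a
    perfectly mixed enclosure emitting ``flux_g_min`` at the given airflow
    shows exactly this net concentration at the outlet.
    """
    sp = get_species(species)
    q = np.asarray(airflow_m3_min, dtype=float)
    t = np.asarray(temp_C, dtype=float)
    molar_volume = VS_L_PER_MOL * (t + KELVIN_OFFSET) / KELVIN_OFFSET
    conc = (
        np.asarray(flux_g_min, dtype=float)
        * sp.unit_denominator
        * molar_volume
        / (q * LITRES_PER_M3 * sp.molecular_weight)
    )
    return conc if conc.shape else float(conc)
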