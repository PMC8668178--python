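"""Convert analyzer concentrations into a gas emission flux.

Builds one 15-min sampling period by hand: an enclosure NH3 concentration,
the concurrent ambient reading, a two-fan airflow interpolated from the
cycle's start/end calibrations, and the enclosure temperature.
"""

from penflux import FanCalibration, airflow_at, net_concentration, period_flux

# two fans calibrated at the start (t=0 s) and end (t=7,862,400 s = 91 d)
fans = [
    FanCalibration("F1", "CPE1", 0, 121.0, 7_862_400, 112.0),
    FanCalibration("F2", "CPE1", 0, 118.5, 7_862_400, 109.0),
]
t = 3_000_000  # mid-cycle (s)
airflow = airflow_at(fans, t)

cpe_nh3 = 4_980.0  # ug/L inside the enclosure
ambient_nh3 = 102.0  # ug/L in incoming air
net = net_concentration(cpe_nh3, ambient_nh3)

flux = period_flux(net, "NH3", airflow, temp_C=21.5)

print(f"total airflow at t={t}: {airflow:.1f} m3/min")
print(f"net NH3 concentration:  {net:.1f} ug/L")
print(f"emission flux:          {flux:.3f} g/min")
print(f"daily emission:         {flux * 1440:.0f} g/day for the whole pen")
# The flux (~0.85 g/min, ~1.2 kg/day for a 14-head pen) is the mass of NH3
# leaving the enclosure; dividing by headcount gives the per-animal rate.
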