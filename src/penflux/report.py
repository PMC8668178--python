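"""End-to-end pipeline orchestration and headline calculators.

Two kinds of entry points live here:

* :func:`run_pipeline` — drive the whole analysis from a trial bundle (or a
  config that synthesizes one): validity filtering, flux computation, daily
  and cumulative aggregation, weight standardization, RCBD ANOVA per
  response, dose–response model selection, and minimum/maximum effective
  dose determination.

* the worked-example calculators — percent reductions relative to control
  and the nitrogen-conservation chain (NH3 is 82.2% N; protein is 16% N and
  makes up 16.5% of retail beef), evaluated against the packaged reference
  LSMeans table so the trial's headline percentages can be reproduced
  without any raw data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import aggregate as agg
from . import design
from . import doseresponse as dr
from . import performance as perf
from . import synth
from . import validity as vmod

__all__ = [
    "percent_reduction",
    "NConservationResult",
    "n_conservation",
    "reference_lsmeans",
    "worked_examples",
    "process_trial",
    "analyze_trial",
    "run_pipeline",
]

#: N fraction of ammonia (by mass), of protein, and protein fraction of carcass
NH3_N_FRACTION = 0.822
PROTEIN_N_FRACTION = 0.16
CARCASS_PROTEIN_FRACTION = 0.165


def percent_reduction(control_value: float, treated_value: float) -> float:
    """Percent reduction relative to control, rounded to one decimal."""
    if control_value <= 0:
        raise ValueError("control value must be positive")
    return round(100.0 * (control_value - treated_value) / control_value, 1)


@dataclass
class NConservationResult:
    """Nitrogen bookkeeping for a cumulative NH3 emission reduction.

    The chain: conserved N = 0.822 × NH3 reduction; protein equivalent =
    N / 0.16; carcass equivalent = protein / 0.165.  Efficiency compares the
    observed HCW gain with the carcass equivalent of the reduction, the
    latter evaluated at reporting precision (kg carcass per 1,000 g NH3,
    one decimal).
    """

    nh3_reduction_g: float
    n_conserved_g: float
    protein_equiv_g: float
    carcass_equiv_kg: float
    efficiency_pct: Optional[float]


#: kg of carcass equivalent per 1,000 g NH3 reduced, at reporting precision
CARCASS_KG_PER_KG_NH3 = round(
    NH3_N_FRACTION / PROTEIN_N_FRACTION / CARCASS_PROTEIN_FRACTION, 1
)


def n_conservation(
    nh3_reduction_g: float, hcw_gain_kg: Optional[float] = None
) -> NConservationResult:
    """Translate an NH3 emission reduction into conserved body nitrogen."""
    if nh3_reduction_g < 0:
        raise ValueError("reduction must be non-negative")
    n_g = NH3_N_FRACTION * nh3_reduction_g
    protein_g = n_g / PROTEIN_N_FRACTION
    carcass_kg = protein_g / CARCASS_PROTEIN_FRACTION / 1000.0
    eff = None
    if hcw_gain_kg is not None and nh3_reduction_g > 0:
        eff = round(
            100.0 * hcw_gain_kg / (nh3_reduction_g / 1000.0 * CARCASS_KG_PER_KG_NH3), 1
        )
    return NConservationResult(nh3_reduction_g, n_g, protein_g, carcass_kg, eff)


def reference_lsmeans() -> pd.DataFrame:
    """The packaged reference LSMeans table, indexed by variable."""
    with resources.files("penflux.data").joinpath("reference_lsmeans.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("variable")


_DOSE_COLS = ("dose_1_38", "dose_5_5", "dose_22")
DOSE_LABELS = ("1.38", "5.5", "22.0")


def worked_examples(ref: Optional[pd.DataFrame] = None) -> Dict[str, float]:
    """Headline trial quantities recomputed from the reference table.

    Returns a flat dict: percent NH3 reductions (cumulative, per kg BW, per
    kg HCW, interim intervals), absolute gram reductions, HCW increases, G:F
    and ADG percent increases, and the nitrogen-conservation chain.
    """
    if ref is None:
        ref = reference_lsmeans()

    out: Dict[str, float] = {}

    def reductions(var, key):
        row = ref.loc[var]
        for col, lab in zip(_DOSE_COLS, DOSE_LABELS):
            out[f"{key}_{lab}"] = percent_reduction(row["dose_0"], row[col])

    reductions("nh3_g_per_animal_d0_91", "nh3_cum_reduction_pct")
    reductions("nh3_g_per_kg_bw_d0_91", "nh3_per_kg_bw_reduction_pct")
    reductions("nh3_g_per_kg_hcw_d0_91", "nh3_per_kg_hcw_reduction_pct")

    r07 = ref.loc["nh3_g_per_animal_d0_7"]
    out["nh3_d0_7_reduction_pct_22.0"] = percent_reduction(r07["dose_0"], r07["dose_22"])
    r014 = ref.loc["nh3_g_per_animal_d0_14"]
    out["nh3_d0_14_reduction_pct_5.5"] = percent_reduction(r014["dose_0"], r014["dose_5_5"])
    out["nh3_d0_14_reduction_pct_22.0"] = percent_reduction(r014["dose_0"], r014["dose_22"])

    cum = ref.loc["nh3_g_per_animal_d0_91"]
    hcw = ref.loc["hcw_kg"]
    gram_reductions = {}
    hcw_gains = {}
    for col, lab in zip(_DOSE_COLS, DOSE_LABELS):
        gram_reductions[lab] = cum["dose_0"] - cum[col]
        hcw_gains[lab] = hcw[col] - hcw["dose_0"]
        out[f"nh3_gram_reduction_{lab}"] = float(gram_reductions[lab])
        out[f"hcw_increase_kg_{lab}"] = float(hcw_gains[lab])

    for var, key in (("gf_kg_kg", "gf_increase_pct"), ("adg_kg_d", "adg_increase_pct")):
        row = ref.loc[var]
        for col, lab in zip(_DOSE_COLS, DOSE_LABELS):
            out[f"{key}_{lab}"] = round(
                100.0 * (row[col] - row["dose_0"]) / row["dose_0"], 1
            )

    chain = n_conservation(1000.0)
    out["protein_equiv_g_per_kg_nh3"] = round(chain.protein_equiv_g)
    out["carcass_equiv_kg_per_kg_nh3"] = round(chain.carcass_equiv_kg, 1)
    for lab in DOSE_LABELS:
        res = n_conservation(gram_reductions[lab], hcw_gains[lab])
        out[f"n_conservation_efficiency_pct_{lab}"] = res.efficiency_pct

    return out


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def process_trial(trial: synth.SyntheticTrial, substitute: bool = True) -> dict:
    """Readings → valid periods → fluxes → daily/cumulative/standardized.

    Returns a dict of DataFrames: ``periods``, ``fluxes``, ``daily``,
    ``cumulative`` (with per-kg columns), ``validity``.
    """
    readings = vmod.mark_exclusions(trial.readings, trial.events)
    periods = vmod.summarize_periods(readings)
    fluxes = agg.period_fluxes(periods, trial.fans)
    daily = agg.daily_emissions(fluxes, trial.inventory, substitute=substitute)
    if daily["g_per_animal"].isna().any():
        # without substitution an invalid day blocks every cumulative total
        cum = None
    else:
        cum = agg.cumulative_table(daily)
        bw_means = (
            trial.bw.groupby(["cycle", "cpe_id", "day"])["bw_kg"].mean().reset_index()
        )
        hcw_means = (
            trial.carcass.groupby(["cycle", "cpe_id"])["hcw_kg"].mean().reset_index()
        )
        cum = agg.standardized_cumulative(cum, bw_means, hcw_means)
    return {
        "periods": periods,
        "fluxes": fluxes,
        "daily": daily,
        "cumulative": cum,
        "validity": vmod.validity_report(daily),
    }


def analyze_trial(processed: dict, trial: synth.SyntheticTrial) -> dict:
    """ANOVA per gas/response plus dose–response on the NH3 claim variables.

    Returns ``anova`` (dict keyed by (gas, response)), ``performance`` (pen
    table with its own ANOVAs), ``dose_response`` (fits and effective doses
    for NH3 per kg BW and per kg HCW), and ``summary`` (tidy LSMeans table).
    """
    cum = processed["cumulative"]
    assign = trial.assignments
    final_interval = int(cum["interval_end"].max())

    def _try_fit(df):
        # single-cycle (or otherwise deficient) runs have no block stratum
        try:
            return design.rcbd_fit(df, "value")
        except ValueError:
            return None

    anova: dict = {}
    summary_rows = []
    for gas in cum["gas"].astype(str).unique():
        sub = cum[(cum["gas"].astype(str) == gas) & (cum["interval_end"] == final_interval)]
        sub = sub.merge(assign, on=["cycle", "cpe_id"])
        for response, col in (
            ("total_g", "total_g_per_animal"),
            ("per_kg_bw", "per_kg_bw"),
            ("per_kg_hcw", "per_kg_hcw"),
        ):
            if sub[col].isna().any():
                continue
            res = _try_fit(sub.rename(columns={col: "value"}))
            if res is None:
                continue
            anova[(gas, response)] = res
            for dose, m in res.lsmeans_dose.items():
                summary_rows.append(
                    {
                        "gas": gas,
                        "response": response,
                        "dose": dose,
                        "lsmean": m,
                        "sem": res.sem_dose,
                        "p_dose": res.dose_p,
                        "p_interaction": res.interaction_p,
                    }
                )

    perf_table = perf.pen_performance(
        trial.bw,
        trial.feed,
        trial.pens,
        trial.carcass,
        trial.inventory,
        trial.config.effects.dm_fraction,
        days=trial.config.days,
    ).merge(assign, on=["cycle", "cpe_id"])
    perf_anova = {}
    for col in ("adg_kg_d", "dmi_kg_d", "gain_feed", "hcw_kg", "dressing_pct"):
        res = _try_fit(perf_table.rename(columns={col: "value"}))
        if res is not None:
            perf_anova[col] = res

    # discrete yield-grade and quality-grade class frequencies per pen
    carcass = trial.carcass.copy()
    carcass["yg_class"] = [
        perf.yield_grade_class(perf.yield_grade(f, k, h, l))
        for f, k, h, l in zip(
            carcass["fat_cm"], carcass["kph_pct"], carcass["hcw_kg"], carcass["lm_cm2"]
        )
    ]
    carcass["quality"] = [
        perf.quality_class(m, o)
        for m, o in zip(carcass["marbling"], carcass["overall_maturity"])
    ]
    categorical = {}
    pens = carcass.merge(assign, on=["cycle", "cpe_id"])
    graded = pens.groupby(["cycle", "cpe_id", "dose", "sex"]).size().rename("n")
    for label, col in (("yg", "yg_class"), ("quality", "quality")):
        for level in sorted(pens[col].unique()):
            k = (
                pens[pens[col] == level]
                .groupby(["cycle", "cpe_id", "dose", "sex"])
                .size()
                .rename("k")
            )
            counts = (
                pd.concat([graded, k], axis=1).fillna({"k": 0}).reset_index()
            )
            counts["k"] = counts["k"].astype(int)
            try:
                categorical[f"{label}_{level}"] = design.binomial_category_fit(counts)
            except ValueError:
                continue

    dose_response = {}
    doses = sorted(trial.config.doses)
    for response in ("per_kg_bw", "per_kg_hcw"):
        key = ("NH3", response)
        if key not in anova:
            continue
        res = anova[key]
        fit = dr.fit_candidates(
            res.lsmeans_dose.reindex(doses).to_numpy(),
            res.sem_dose,
            doses=doses,
            df_resid=res.df_resid,
        )
        med, med_reason = dr.min_effective_dose(res.dose_p, res.contrasts)
        xed, xed_reason = dr.max_effective_dose(fit, dose_f_p=res.dose_p)
        dose_response[response] = {
            "fit": fit,
            "min_effective_dose": med,
            "min_effective_reason": med_reason,
            "max_effective_dose": xed,
            "max_effective_reason": xed_reason,
        }

    return {
        "anova": anova,
        "performance": perf_table,
        "performance_anova": perf_anova,
        "categorical": categorical,
        "dose_response": dose_response,
        "summary": pd.DataFrame(summary_rows),
    }


def run_pipeline(
    config: Optional[synth.TrialConfig] = None,
    trial: Optional[synth.SyntheticTrial] = None,
    out_dir=None,
) -> dict:
    """Synthesize (or accept) a trial, process and analyze it.

    Deterministic given the config seed.  When ``out_dir`` is given, the
    machine-readable result tables are written there as CSV.
    """
    if trial is None:
        trial = synth.simulate_trial(config or synth.TrialConfig())
    processed = process_trial(trial)
    analysis = analyze_trial(processed, trial)
    results = {"trial": trial, **processed, **analysis}
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        processed["daily"].to_csv(out / "emissions_daily.csv", index=False)
        processed["cumulative"].to_csv(out / "emissions_cumulative.csv", index=False)
        processed["validity"].to_csv(out / "validity_report.csv", index=False)
        analysis["summary"].to_csv(out / "anova_summary.csv", index=False)
        analysis["performance"].to_csv(out / "performance.csv", index=False)
        drrows = []
        for response, d in analysis["dose_response"].items():
            for c in d["fit"].candidates:
                drrows.append(
                    {
                        "response": response,
                        "model_id": c.model_id,
                        "description": c.description,
                        "slope": c.slope,
                        "p": c.p,
                        "selected": c.model_id == d["fit"].selected_model,
                        "min_effective_dose": d["min_effective_dose"],
                        "max_effective_dose": d["max_effective_dose"],
                    }
                )
        pd.DataFrame(drrows).to_csv(out / "dose_response.csv", index=False)
    return results
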