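"""Generator structure, determinism, rotation, effect recovery, failure injection."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from penflux import report, synth, validity

from conftest import clean_config


class TestDesignStructure:
    def test_default_design_counts(self):
        cfg = synth.TrialConfig(days=1, gases=("NH3",), seed=0)
        trial = synth.simulate_trial(cfg)
        a = trial.assignments
        assert a["cycle"].nunique() == 3
        assert len(a) == 24
        combos = a.groupby(["dose", "sex"]).size()
        assert (combos == 3).all()  # each dose x sex appears once per cycle
        per_cycle = a.groupby(["cycle", "dose", "sex"]).size()
        assert (per_cycle == 1).all()

    def test_control_dose_required(self):
        with pytest.raises(ValueError, match="control"):
            synth.TrialConfig(doses=(1.38, 5.5, 22.0, 44.0))

    def test_rotation_samples_exactly_one_source_at_a_time(self, noisy_trial):
        r = noisy_trial.readings
        dup = r.duplicated(subset=["cycle", "gas", "time_s"])
        assert not dup.any()
        # and the rotation order is ambient, CPE1..CPE8, repeating
        periods = (
            r[r["gas"] == "NH3"].assign(period=lambda d: d["time_s"] // 900)
            .groupby("period", observed=True)["source"].first()
        )
        rot = noisy_trial.config.rotation_sources
        for p, src in periods.items():
            assert src == rot[p % len(rot)]

    def test_max_11_periods_per_enclosure_day(self, noisy_trial):
        proc = report.process_trial(noisy_trial)
        assert proc["daily"]["n_periods"].max() <= 11

    def test_bit_reproducible_for_fixed_seed(self):
        cfg = synth.TrialConfig(days=2, gases=("NH3",), n_cycles=1, seed=123)
        a = synth.simulate_trial(cfg)
        b = synth.simulate_trial(cfg)
        pd.testing.assert_frame_equal(a.readings, b.readings)
        pd.testing.assert_frame_equal(a.carcass, b.carcass)
        pd.testing.assert_frame_equal(a.bw, b.bw)

    def test_headcount_non_increasing_with_floor(self):
        cfg = clean_config(days=20)
        cfg = dataclasses.replace(
            cfg, effects=dataclasses.replace(cfg.effects, removal_hazard=0.05)
        )
        trial = synth.simulate_trial(cfg)
        for _, grp in trial.inventory.groupby(["cycle", "cpe_id"]):
            counts = grp.sort_values("day")["headcount"].to_numpy()
            assert (np.diff(counts) <= 0).all()
            assert counts.min() >= cfg.effects.headcount_floor


class TestEffectInjection:
    def test_null_effect_all_enclosures_identical(self, clean_trial, clean_processed):
        """Zero noise and no dose effect: every enclosure's daily NH3 per
        animal equals the generating rate exactly."""
        daily = clean_processed["daily"]
        rate = clean_trial.truth["expected_daily_g_per_animal"][("NH3", 0.0)]
        assert np.allclose(daily["g_per_animal"], rate, rtol=1e-9)

    def test_analytic_mean_matches_monte_carlo(self):
        """The generator's analytic expected daily NH3 must agree with the
        Monte-Carlo mean over replicates within 3 SE."""
        gp = {"NH3": synth.GasParams(base_rate=60.0, day_slope=0.5,
                                     reading_noise_sd=40.0, ambient_mean=100.0,
                                     ambient_ar1_sd=2.0, pen_sd=0.10)}
        means = []
        expected = None
        for seed in range(20):
            eff = synth.default_effect_model(gas_params=gp, cycle_sd=0.05,
                                             sex_emission_effect={})
            cfg = synth.TrialConfig(days=4, gases=("NH3",), n_cycles=1,
                                    seed=seed, effects=eff)
            trial = synth.simulate_trial(cfg)
            proc = report.process_trial(trial)
            con = proc["daily"].merge(trial.assignments, on=["cycle", "cpe_id"])
            means.append(con.loc[con["dose"] == 0.0, "g_per_animal"].mean())
            expected = trial.truth["expected_daily_g_per_animal"][("NH3", 0.0)]
        mc = np.array(means)
        se = mc.std(ddof=1) / np.sqrt(len(mc))
        assert abs(mc.mean() - expected) < 3 * se + 1e-12

    def test_dose_effect_recovered_across_seeds(self):
        """An injected 0.87 top-dose multiplier is recovered by the realized
        cumulative ratio vs control within Monte-Carlo error."""
        gp = {"NH3": synth.GasParams(base_rate=60.0, diurnal_amplitude=0.25,
                                     reading_noise_sd=30.0, ambient_mean=100.0,
                                     ambient_ar1_sd=2.0, pen_sd=0.05)}
        ratios = []
        for seed in range(20):
            eff = synth.default_effect_model(
                gas_params=gp,
                nh3_dose_effect={0.0: 1.0, 1.38: 0.95, 5.5: 0.90, 22.0: 0.87},
                cycle_sd=0.02,
            )
            cfg = synth.TrialConfig(days=5, gases=("NH3",), seed=seed, effects=eff)
            trial = synth.simulate_trial(cfg)
            proc = report.process_trial(trial)
            cum = proc["cumulative"].merge(trial.assignments, on=["cycle", "cpe_id"])
            final = cum[cum["interval_end"] == cum["interval_end"].max()]
            g = final.groupby("dose")["total_g_per_animal"].mean()
            ratios.append(g[22.0] / g[0.0])
        ratios = np.array(ratios)
        se = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - 0.87) < 3 * se + 0.005

    def test_diurnal_pattern_biases_noncontinuous_sampling(self):
        """Continuous rotation sampling is unbiased under a diurnal emission
        cycle, while sampling only a fixed daytime window is biased."""
        gp = {"NH3": synth.GasParams(base_rate=60.0, diurnal_amplitude=0.5)}
        eff = synth.default_effect_model(
            gas_params=gp, nh3_dose_effect={d: 1.0 for d in (0.0, 1.38, 5.5, 22.0)},
            cycle_sd=0.0, sex_emission_effect={}, removal_hazard=0.0,
            diurnal_peak_hour=6.0,  # 1400 local: t=0 is 0800
        )
        cfg = synth.TrialConfig(days=4, gases=("NH3",), n_cycles=1, seed=5,
                                effects=eff, event_rate_bunk_flap=0.0,
                                event_rate_large_door=0.0, event_rate_small_door=0.0)
        trial = synth.simulate_trial(cfg)
        proc = report.process_trial(trial)
        continuous = proc["daily"]["g_per_animal"].mean()

        # keep only the half-day window centred on the emission peak
        r = trial.readings
        hod = (r["time_s"] % 86400) / 3600.0
        daytime = trial.readings[(hod >= 0) & (hod < 12)]
        trial_day = dataclasses.replace(trial, readings=daytime.reset_index(drop=True))
        proc_day = report.process_trial(trial_day)
        biased = proc_day["daily"]["g_per_animal"].mean()

        rate = trial.truth["expected_daily_g_per_animal"][("NH3", 0.0)]
        assert abs(continuous - rate) / rate < 0.01
        assert biased > rate * 1.2  # peak-window sampling overestimates


@pytest.fixture(scope="module")
def failed_trial():
    cfg = clean_config(days=10)
    trial = synth.simulate_trial(cfg)
    readings = synth.inject_analyzer_failure(trial.readings, "NH3", day=7, cycle=1)
    return dataclasses.replace(trial, readings=readings)


class TestAnalyzerFailure:

    def test_day_flagged_invalid_everywhere(self, failed_trial):
        proc = report.process_trial(failed_trial, substitute=False)
        day7 = proc["daily"][proc["daily"]["day"] == 7]
        assert len(day7) == 8
        assert (~day7["day_valid"]).all()
        assert (day7["n_valid"] < validity.MIN_VALID_PERIODS).all()

    def test_substitution_uses_four_neighbour_days(self, failed_trial):
        proc = report.process_trial(failed_trial, substitute=True)
        daily = proc["daily"]
        for _, grp in daily.groupby(["cycle", "cpe_id"], observed=True):
            grp = grp.set_index("day")
            assert grp.loc[7, "substituted"]
            expected = grp.loc[[5, 6, 8, 9], "g_per_animal"].mean()
            assert grp.loc[7, "g_per_animal"] == pytest.approx(expected)

    def test_no_injection_no_substitution(self, clean_processed):
        assert clean_processed["daily"]["substituted"].sum() == 0

    def test_failure_at_boundary_day_unrecoverable(self):
        cfg = clean_config(days=6)
        trial = synth.simulate_trial(cfg)
        readings = synth.inject_analyzer_failure(trial.readings, "NH3", day=0)
        bad = dataclasses.replace(trial, readings=readings)
        with pytest.raises(validity.UnrecoverableDayError):
            report.process_trial(bad)

    def test_day_out_of_range_rejected(self, clean_trial):
        with pytest.raises(ValueError, match="outside trial range"):
            synth.inject_analyzer_failure(clean_trial.readings, "NH3", day=400)
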