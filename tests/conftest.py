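import dataclasses

import pytest

from penflux import report, synth


def clean_config(**overrides):
    """A noise-free single-gas configuration: no events, no removals,
    constant emission rate, no dose or sex effects.  Every deviation from
    the injected rate downstream is then an implementation error."""
    gp = {"NH3": synth.GasParams(base_rate=60.0)}
    eff = synth.default_effect_model(
        gas_params=gp,
        nh3_dose_effect={0.0: 1.0, 1.38: 1.0, 5.5: 1.0, 22.0: 1.0},
        cycle_sd=0.0,
        sex_emission_effect={},
        removal_hazard=0.0,
    )
    base = dict(
        days=6,
        gases=("NH3",),
        n_cycles=1,
        seed=7,
        effects=eff,
        event_rate_bunk_flap=0.0,
        event_rate_large_door=0.0,
        event_rate_small_door=0.0,
    )
    base.update(overrides)
    return synth.TrialConfig(**base)


@pytest.fixture(scope="session")
def clean_trial():
    return synth.simulate_trial(clean_config())


@pytest.fixture(scope="session")
def clean_processed(clean_trial):
    return report.process_trial(clean_trial)


@pytest.fixture(scope="session")
def noisy_trial():
    """A short trial with all noise sources and events active."""
    cfg = synth.TrialConfig(days=6, gases=("NH3",), n_cycles=1, seed=42)
    return synth.simulate_trial(cfg)


def with_effects(config: synth.TrialConfig, **eff_overrides) -> synth.TrialConfig:
    eff = dataclasses.replace(config.effects, **eff_overrides)
    return dataclasses.replace(config, effects=eff)
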