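import dataclasses

import pytest

import polypgrowth as pg


@pytest.fixture(scope="session")
def al_cohort():
    """Default ad-libitum two-cycle cohort (96 individuals, 4 phases)."""
    return pg.simulate_cohort(pg.nematostella_al(seed=42))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Single-phase cohort with every noise source switched off."""
    cfg = pg.SimCohortConfig(
        n_individuals=4, phase_schedule=[(0, 20, 0.3)],
        noise_sd=0.0, rate_heterogeneity_sd=0.0, start_size_logsd=0.0,
        start_size_logmean=0.2, shape_noise_sd=0.0,
        sampling_days=list(range(0, 21, 2)), seed=0,
    )
    return pg.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def day1_events():
    """Truth-labelled event cloud at the fed (day-1) cell-cycle composition."""
    cfg = pg.events_day1(n_cells=50_000, seed=7)
    events = pg.simulate_events(cfg)
    control = pg.simulate_events(dataclasses.replace(cfg, edu_fraction=0.0, seed=8))
    return cfg, events, control
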