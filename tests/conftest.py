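import pytest

from idpanel import SimulationConfig, fixture_tables, simulate_cohorts, simulate_panel


@pytest.fixture(scope="session")
def default_panel():
    return simulate_panel(SimulationConfig())


@pytest.fixture(scope="session")
def fixtures():
    """Deterministic regression fixtures with the published count structure."""
    return fixture_tables()


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort for structural and round-trip tests."""
    cfg = SimulationConfig(n_case=40, n_comparison=40, seed=11)
    variants, samples, truth = simulate_cohorts(cfg)
    return cfg, variants, samples, truth
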