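import pytest

from rumenferm import SimulationConfig, paper_fixture, simulate_experiment, study_design
from rumenferm.design import BasalComponent, SupplementSpec, TreatmentSpec


@pytest.fixture(scope="session")
def design():
    return study_design()

@pytest.fixture(scope="session")
def design_by_id(design):
    return {t.id: t for t in design}


@pytest.fixture(scope="session")
def fixture_means():
    """Published treatment-mean observation table (30 rows)."""
    return paper_fixture()


@pytest.fixture(scope="session")
def default_simulation():
    cfg = SimulationConfig(seed=20190918)
    records, truth = simulate_experiment(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def minimal_design():
    """Control plus one whey-like supplement at a single high dose."""
    basal = (
        BasalComponent("grass silage", 400.0, 0.16),
        BasalComponent("compound feed", 400.0, 0.19),
    )
    supp = SupplementSpec("TEST", cp_frac=0.892)
    return (
        TreatmentSpec(id="Control", basal=basal),
        TreatmentSpec(
            id="TEST High",
            basal=basal,
            supplement=supp,
            dose_mg_dm=176.0,
            bcaa_mmol={"Val": 0.088, "Ile": 0.085, "Leu": 0.139},
        ),
    )
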