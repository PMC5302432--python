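import pytest

from nutmet import AnalysisConfig, SimulationConfig, generate_met, worked_example_fixture
from nutmet.pipeline import full_report


@pytest.fixture()
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def worked():
    """Deterministic 19 × 3 × 2 worked-example dataset."""
    return worked_example_fixture()


@pytest.fixture(scope="session")
def worked_report():
    """Full pipeline output on the worked example (computed once)."""
    return full_report(worked_example_fixture(), AnalysisConfig())


@pytest.fixture(scope="session")
def rank1_sim():
    """Balanced synthetic trial with a single interaction component.

    hulled_fraction = 0 keeps the analysed yield on the generated scale so
    estimates can be compared against stored truth directly.
    """
    cfg = SimulationConfig(
        n_genotypes=30,
        n_environments=5,
        n_replicates=2,
        interaction_lambdas=[400.0],
        sigma_g=400.0,
        sigma_eps=200.0,
        hulled_fraction=0.0,
        seed=7,
    )
    return generate_met(cfg)
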