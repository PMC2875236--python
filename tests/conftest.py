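import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def vtg_truth():
    """The canned two-species/two-paralogue family, simulated once."""
    from concerta import scenario_vtg, simulate_family

    return simulate_family(scenario_vtg(7))


@pytest.fixture(scope="session")
def vtg_codon_aln(vtg_truth):
    from concerta import align_codons

    return align_codons([r.cds() for r in vtg_truth.records],
                        [r.id for r in vtg_truth.records])


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
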