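import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import asgroups as ag

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_table():
    """3 OTUs x 2 samples with taxonomy, for round-trip and subset tests."""
    return ag.OTUTable(
        ["OTU_1", "OTU_2", "OTU_3"],
        ["s1", "s2"],
        np.array([[1, 3], [5, 0], [0, 2]]),
        taxonomy={
            "OTU_1": ["Bacteria", "Proteobacteria", "Betaproteobacteria"],
            "OTU_2": ["Bacteria", "Actinobacteria"],
        },
    )


@pytest.fixture(scope="session")
def planted():
    """Neutral 13-sample background with planted ecological-group rows.

    Session-scoped: the table and its ground-truth labels feed both the
    partitioning unit tests and the recovery acceptance test.
    """
    scen = ag.SyntheticScenario(n_otus=150, n_samples=13, reads_per_sample=7000, seed=42)
    base = ag.simulate_metacommunity(scen)
    table, truth = ag.plant_group_structure(base, seed=43)
    return table, truth


@pytest.fixture(scope="session")
def planted_gs_records(planted):
    """Generalist/specialist classification of the planted table (1,000 nulls)."""
    table, _ = planted
    return ag.generalist_specialist(table, n_null=1000, seed=7)
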