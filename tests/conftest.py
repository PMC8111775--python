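import pytest

from plastidtraj.simulate import SimConfig, generate_experiment


@pytest.fixture(scope="session")
def experiment():
    """One default synthetic experiment shared across read-only tests."""
    return generate_experiment(SimConfig(seed=1))


@pytest.fixture(scope="session")
def rpm(experiment):
    from plastidtraj.expression import rpm_normalize

    matrix = rpm_normalize(experiment.counts)
    return matrix.drop(index="BACKGROUND")
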