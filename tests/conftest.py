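import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cabletree as ct

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    """Uniform cable constants used in the species-comparison simulations."""
    return ct.CableParameters(cm=1.0, rm=15000.0, ra=150.0)


@pytest.fixture(scope="session")
def coarse_policy():
    return ct.CompartmentPolicy(max_length_um=20.0)


@pytest.fixture(scope="session")
def human_cell():
    m, truth = ct.generate_morphology(ct.HUMAN, 5)
    return m, truth


@pytest.fixture(scope="session")
def rat_cell():
    m, truth = ct.generate_morphology(ct.RAT, 5)
    return m, truth


@pytest.fixture(scope="session")
def swc_fixture(tmp_path_factory):
    """Minimal hand-built SWC: one soma record + two dendrite records 50 µm
    apart along x (section length 100 µm including the soma attachment)."""
    path = tmp_path_factory.mktemp("swc") / "three_records.swc"
    path.write_text(
        "# minimal fixture\n"
        "1 1 0 0 0 5.0 -1\n"
        "2 3 50 0 0 1.0 1\n"
        "3 3 100 0 0 1.0 2\n"
    )
    return path
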