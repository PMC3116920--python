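import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ancres import Alignment, SimulationSpec, read_tree, simulate_alignment
from ancres.substitution_models import build_model

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def jtt1():
    """JTT model, single rate category."""
    return build_model(alpha=1.0, K=1)


@pytest.fixture(scope="session")
def jtt4():
    """JTT model, four gamma categories (shape 0.7)."""
    return build_model(alpha=0.7, K=4)


@pytest.fixture()
def quartet_tree():
    return read_tree("((A:0.1,B:0.2)u:0.15,(C:0.3,D:0.05)v:0.08)r;")


@pytest.fixture()
def quartet_alignment():
    return Alignment.from_sequences(
        ["A", "B", "C", "D"], ["ACDEF", "ACDEY", "ACSEF", "ACDKF"]
    )


@pytest.fixture(scope="session")
def study_scale_sim():
    """One simulated dataset at the study's scale: 12 taxa, 240 sites."""
    spec = SimulationSpec(seed=42, ntaxa=12, nsites=240, alpha=1.0, K=4)
    aln, ancestors, tree = simulate_alignment(spec)
    return spec, aln, ancestors, tree
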