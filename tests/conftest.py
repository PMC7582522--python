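import numpy as np
import pytest

from astrotopo import (
    EphysGroundTruth,
    NetworkPointSet,
    SyntheticNetworkSpec,
    generate_network_points,
    generate_voltage_step_traces,
)


@pytest.fixture
def wt_spec():
    """Study-scale anisotropic network spec (2:1 axes, dorsoventral)."""
    return SyntheticNetworkSpec(seed=42)


@pytest.fixture
def wt_points(wt_spec):
    return generate_network_points(wt_spec)


@pytest.fixture
def pa_traces():
    return generate_voltage_step_traces(EphysGroundTruth(r_series=5.0, r_membrane=10.0))


@pytest.fixture
def npa_traces():
    return generate_voltage_step_traces(EphysGroundTruth.npa(g_max_outward=50.0))


def random_point_set(rng, n=None):
    """A random network for property tests."""
    n = n or rng.integers(3, 40)
    cells = rng.normal(0.0, 50.0, size=(n, 2))
    patched = rng.normal(0.0, 10.0, size=2)
    return NetworkPointSet(patched=patched, cells=patched + cells)
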