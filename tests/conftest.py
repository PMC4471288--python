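import numpy as np
import pytest

import ssridose as sd
from ssridose import datasets


@pytest.fixture(scope="session")
def fluoxetine_params():
    """The published fluoxetine Michaelis-Menten constants."""
    return datasets.fluoxetine_params()


@pytest.fixture(scope="session")
def registry():
    """Calibrated registry of all six bundled drugs (cached: the two
    saturable drugs need an optimisation each)."""
    return datasets.build_drug_registry()


@pytest.fixture(scope="session")
def reference(registry):
    """Fluoxetine 40 mg q24h loading curve over 30 days."""
    spec = registry["fluoxetine"]
    return sd.build_reference(spec.params, dose=40.0, days=30)


@pytest.fixture(scope="session")
def published_fluoxetine_cave():
    """The published fluoxetine daily-mean column of the 30-day dosing
    table (ng/ml), used as an external oracle for the loading fractions."""
    return np.array([
        30.8, 55.8, 74.8, 89.5, 101.0, 110.1, 117.5, 123.4, 128.1, 132.0,
        135.1, 137.7, 139.8, 141.5, 142.9, 144.0, 145.0, 145.7, 146.4, 146.9,
        147.3, 147.7, 148.0, 148.2, 148.4, 148.5, 148.7, 148.8, 148.9, 149.0,
    ])


@pytest.fixture(scope="session")
def sample_linear():
    """A generic linear drug (sertraline-like) for property checks."""
    return sd.LinearPKParams(
        volume=1400.0, absorption_rate=0.4672, elimination_rate=np.log(2) / 26.0
    )
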