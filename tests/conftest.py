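import sys
from pathlib import Path

import matplotlib
import pytest

matplotlib.use("Agg")
sys.path.insert(0, str(Path(__file__).parent))  # for helpers.py

from causalpath.casestudies import build_example


@pytest.fixture(scope="session")
def mediated_spec():
    return build_example("mediated_pair")


@pytest.fixture(scope="session")
def confounded_spec():
    return build_example("confounded_pair")


@pytest.fixture(scope="session")
def mediated_theta(mediated_spec):
    return mediated_spec.true_theta()


@pytest.fixture(scope="session")
def mediated_trained(mediated_spec, mediated_theta):
    """One moderately-sized trained mediated-system model shared across tests."""
    data = mediated_spec.correct.sample_observational(mediated_theta, 800, seed=41)
    return mediated_spec.correct.fit(data, chains=2, warmup=300, draws=250, seed=42)
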