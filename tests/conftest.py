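import numpy as np
import pytest

from tacivive.adam import default_regions
from tacivive.dlm import FormulationModel
from tacivive.media import build_default_protocol
from tacivive.pbpk import CompoundDisposition
from tacivive.sensitivity import apply_scalars

#: proximal scalars used as the "true" configuration of a fast test-like
#: product in recovery exercises; distal regions resolved separately.
PROXIMAL_SCALARS = {"Stomach": 2.0, "Duodenum": 2.0,
                    "Jejunum I": 1.5, "Jejunum II": 1.5}


@pytest.fixture(scope="session")
def protocol():
    return build_default_protocol()


@pytest.fixture(scope="session")
def form():
    return FormulationModel.monodisperse(dose=5.0, label="test")


@pytest.fixture(scope="session")
def disposition():
    return CompoundDisposition()


@pytest.fixture(scope="session")
def regions_resolved():
    """All nine regions with resolved scalars (ileum 0.05, colon 0.5)."""
    base = default_regions(scalars_by_region=PROXIMAL_SCALARS)
    return apply_scalars(base, 0.05, 0.5)


@pytest.fixture(scope="session")
def obs_grid():
    """10-min observation grid over the 6-h experiment."""
    return np.arange(0.0, 361.0, 10.0)
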