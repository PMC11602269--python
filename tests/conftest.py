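import pytest

from phantomgel import load_published_models
from phantomgel.mixing_model import CoefficientSet, MixingModel
from phantomgel.synthetic_data import DesignSpec


@pytest.fixture(scope="session")
def published_models():
    return load_published_models()


@pytest.fixture(scope="session")
def synthetic_truth():
    """A well-scaled ground-truth model for parameter-recovery studies."""
    a = CoefficientSet((0.4, 1.0, 0.2, 0.6, 0.05, 0.3, 0.0, 0.0, 0.0), "T1")
    b = CoefficientSet((0.5, 3.0, 0.5, 1.5, 0.1, 0.8, 0.0, 0.0, 0.0), "T2")
    return MixingModel("NiCl2", 0.064, a, b, "synthetic truth")


@pytest.fixture(scope="session")
def recovery_design():
    """The well-powered design used in noisy recovery studies.

    49 compositions (water, six agarose-only, six salt-only, 36 mixed) with
    12 replicates each at 1% multiplicative noise; replication is sized so
    coefficient standard errors sit well inside the recovery tolerance.
    """
    return DesignSpec(
        agarose_levels=(0.5, 1.0, 1.5, 2.0, 3.0, 4.0),
        salt_levels=(0.5, 1.0, 2.0, 4.0, 7.0, 10.0),
        noise_sigma=0.01, replicates=12, seed=7,
    )
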