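import pytest

from mrtplan import (
    ArraySpec,
    CohortSurvival,
    PhantomSpec,
    generate_phantom,
)
from mrtplan.reference_params import LQ_9LGS
import pandas as pd


@pytest.fixture(scope="session")
def lq_conventional():
    return LQ_9LGS["conventional"]


@pytest.fixture(scope="session")
def lq_2t():
    return LQ_9LGS["2T"]


@pytest.fixture(scope="session")
def lq_3t():
    return LQ_9LGS["3T"]


@pytest.fixture(scope="session")
def array_spec():
    return ArraySpec()


@pytest.fixture()
def small_phantom():
    """Noiseless 0.485 mm-radius spherical tumor on a 97 um grid."""
    spec = PhantomSpec(
        shape=(40, 40, 40),
        center_mm=(1.8915, 1.8915, 1.8915),
        semi_axes_mm=(0.485, 0.485, 0.485),
        seed=42,
    )
    image, mask = generate_phantom(spec)
    return spec, image, mask


@pytest.fixture(scope="session")
def treated_cohort():
    """The reconstructed treated-arm survival times, cure censored at horizon."""
    table = pd.DataFrame(
        {
            "id": [f"r{i}" for i in range(5)],
            "group": ["treated"] * 5,
            "days": [13.0, 32.0, 44.0, 60.0, 528.0],
            "event": [1, 1, 1, 1, 0],
        }
    )
    return CohortSurvival(table=table)
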