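import numpy as np
import pytest

from htplan.fdtd import ComplexFieldVolume
from htplan.phantom import generate_breast_phantom
from htplan.tissues import build_tissue_table


@pytest.fixture(scope="session")
def tissue_table():
    return build_tissue_table()


@pytest.fixture(scope="session")
def hd_phantom():
    """Default heterogeneously dense phantom with a 12 mm tumor."""
    return generate_breast_phantom(seed=1)


def make_synthetic_fields(n_antennas=8, shape=(10, 10, 10), seed=0,
                          spacing=3.0, origin=(0.0, 0.0, 0.0)):
    """Random complex unit fields on a shared grid (normalized flag set)."""
    rng = np.random.default_rng(seed)
    fields = []
    for n in range(n_antennas):
        E = rng.standard_normal((3, *shape)) + 1j * rng.standard_normal((3, *shape))
        fields.append(
            ComplexFieldVolume(
                E=E, spacing=spacing, origin=np.asarray(origin, float),
                antenna_index=n, accepted_power_norm=1.0,
            )
        )
    return fields


@pytest.fixture()
def synthetic_fields():
    return make_synthetic_fields()
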