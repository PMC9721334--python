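import numpy as np
import pytest

from fibrilsaxs import (CylinderSpec, equatorial_from_isotropic,
                        isotropic_cylinder_intensity)


@pytest.fixture(scope="session")
def q_saxs():
    """Standard SAXS window for cylinder benchmarks."""
    return np.linspace(0.004, 0.3, 600)


@pytest.fixture(scope="session")
def cyl35():
    return CylinderSpec(35.0, 1000.0)


@pytest.fixture(scope="session")
def iso35(q_saxs, cyl35):
    """Isotropic intensity of the 35 Å x 1000 Å benchmark cylinder."""
    return isotropic_cylinder_intensity(q_saxs, cyl35)


@pytest.fixture(scope="session")
def eq35(iso35):
    """Equatorial intensity recovered from the isotropic benchmark curve."""
    return equatorial_from_isotropic(iso35)
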