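import numpy as np
import pytest
from hypothesis import settings

from perifem import BloodModel, LesionAnnotation

from helpers import make_gaussian_narrowing, make_tube

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def blood():
    """Default blood: hematocrit 0.42, density 1.06 g/cm^3."""
    return BloodModel(hematocrit=0.42)


@pytest.fixture
def tube():
    return make_tube()


@pytest.fixture
def narrowed_profile():
    return make_gaussian_narrowing()


@pytest.fixture
def single_lesion():
    return LesionAnnotation(start=40.0, end=60.0, reference_radius=2.5, minimal_radius=1.0)
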