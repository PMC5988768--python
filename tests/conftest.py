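import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from psoct.optics import AcquisitionParams
from psoct.pipeline import PipelineSettings
from psoct.tissue import GradePreset, IndentationGeometry, default_presets, make_tissue


@pytest.fixture(scope="session")
def geometry():
    return IndentationGeometry()


@pytest.fixture(scope="session")
def presets():
    return default_presets()


@pytest.fixture(scope="session")
def noiseless_params():
    return AcquisitionParams(noise_sigma=0.0, noise_floor=0.0)


@pytest.fixture(scope="session")
def default_params():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def settings_default():
    return PipelineSettings()


def slab_tissue(truth_brc: float, geometry=None, **kwargs):
    """Laterally uniform slab with an exact, noise-free ground-truth BRC."""
    preset = GradePreset("G0", "XZ_nonindented", truth_brc, 0.0, 10)
    return make_tissue(preset, geometry or IndentationGeometry(), 0, 0, **kwargs)


@pytest.fixture(scope="session")
def make_slab():
    return slab_tissue
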