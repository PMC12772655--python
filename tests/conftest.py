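import numpy as np
import pytest

import ctphantom as cp
from ctphantom.materials import LesionSpec, PhantomSpec


@pytest.fixture(scope="session")
def default_config() -> cp.StudyConfig:
    return cp.StudyConfig()


@pytest.fixture(scope="session")
def full_study(default_config) -> cp.StudyReport:
    """The complete default synthetic study, run once per session: 180
    lesion instances, ROI metrics, radiomics, clustering and statistics."""
    return cp.run_study(default_config, with_radiomics=True, with_stats=True)


def make_toy_phantom(lesion_type: str = "solid", mean_intensity: float = -200.0):
    """A reduced single-lesion phantom on a small grid for fast unit tests."""
    lesion = LesionSpec(
        f"toy_{lesion_type}", lesion_type, "small", 16.0, mean_intensity,
        "quarter", 1,
    )
    return PhantomSpec(
        1, 80.0, 20.0, (lesion,), ring_outer_diameter=100.0, bore_diameter=80.0
    )


@pytest.fixture(scope="session")
def toy_phantom():
    return make_toy_phantom()


@pytest.fixture(scope="session")
def toy_scan(toy_phantom):
    """Toy truth + mask (PCCT) on a 220x220x20 grid."""
    return cp.rasterize_phantom(
        toy_phantom, cp.DEFAULT_MATERIALS, "PCCT", fov_mm=110.0, seed=5
    )


@pytest.fixture(scope="session")
def ph2_truth_eidct():
    """Canonical phantom 2 (ground-glass pair) truth for the EIDCT table."""
    spec = cp.canonical_phantoms()[1]
    vol, mask = cp.rasterize_phantom(spec, cp.DEFAULT_MATERIALS, "EIDCT", seed=11)
    return spec, vol, mask


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
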