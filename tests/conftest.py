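import numpy as np
import pytest

from octliver import phantom as ph
from octliver.preprocess import PreprocParams


@pytest.fixture(scope="session")
def default_params() -> PreprocParams:
    return PreprocParams()


@pytest.fixture(scope="session")
def tiny_phantom_params() -> ph.PhantomParams:
    """Small, fast phantom geometry for unit tests."""
    return ph.PhantomParams(
        n_bscans=3, height_px=120, width_px=80, surface_level_px=18.0,
        surface_tilt=0.02, surface_roughness_px=1.5,
        attenuation_per_px=0.10, artifact_col_rate=2.0, seed=7,
    )


@pytest.fixture(scope="session")
def healthy_scan():
    """One full-geometry healthy phantom C-scan with few B-scans."""
    return ph.generate_cscan(ph.healthy_params(n_bscans=2, seed=21), "healthy")


@pytest.fixture(scope="session")
def tumor_scan():
    # elevated artifact rate so every B-scan reliably carries planted columns
    return ph.generate_cscan(
        ph.tumor_params(n_bscans=2, artifact_col_rate=3.0, seed=22), "tumor"
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
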