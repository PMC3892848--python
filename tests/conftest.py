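from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from goniohcrf import AcquisitionModel, SceneModel, simulate_session
from goniohcrf.pipeline import SessionData
from goniohcrf.synthetic import default_wavelength_grid

#: The case-study site/instant: 69°40'28"N, 148°43'15"W, 2012-07-09 13:48 UTC-8.
SITE_LAT = 69.0 + 40 / 60 + 28 / 3600
SITE_LON = -(148.0 + 43 / 60 + 15 / 3600)
SESSION_START = datetime(2012, 7, 9, 13, 48, tzinfo=timezone(timedelta(hours=-8)))


@pytest.fixture(scope="session")
def wavelengths():
    return default_wavelength_grid()


@pytest.fixture(scope="session")
def clean_session():
    """Noiseless, jitter-free session with smooth 0.2%/min drift."""
    scene = SceneModel()
    acq = AcquisitionModel(drift_rate_per_min=0.002, noise_sd=0.0,
                           pointing_jitter_sd=0.0, pp_misalignment_sd=0.0, seed=7)
    manifest, spectra, irr, truth = simulate_session(
        scene, acq, latitude=SITE_LAT, longitude=SITE_LON)
    return SessionData(manifest, spectra, irr, truth.panel_calibration), truth


@pytest.fixture(scope="session")
def noisy_session():
    """Session with the generator's default noise/jitter/misalignment."""
    scene = SceneModel()
    acq = AcquisitionModel(seed=11)
    manifest, spectra, irr, truth = simulate_session(
        scene, acq, latitude=SITE_LAT, longitude=SITE_LON)
    return SessionData(manifest, spectra, irr, truth.panel_calibration), truth


def relative_rms(estimate: np.ndarray, truth: np.ndarray) -> float:
    return float(np.sqrt(np.mean(((estimate - truth) / truth) ** 2)))
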