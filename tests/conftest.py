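import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from wbdwi import DWISeries, ImageVolume, LesionSpec, default_torso_spec, render_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_series(s_low, s_high, spacing=(2.0, 2.0, 5.0), patient="p1", timepoint=0):
    """Two-b-value series from raw arrays (b = 50 and 800)."""
    return DWISeries(
        patient_id=patient,
        timepoint=timepoint,
        volumes={
            50: ImageVolume(np.asarray(s_low, dtype=np.float64), spacing),
            800: ImageVolume(np.asarray(s_high, dtype=np.float64), spacing),
        },
    )


@pytest.fixture(scope="session")
def small_torso():
    """A fast torso phantom with one organ-free lesion and moderate noise."""
    spec = default_torso_spec(
        shape=(32, 32, 48),
        spacing=(4.0, 4.0, 8.0),
        lesions=(LesionSpec(center=(40.0, 50.0, 120.0), radii=(16.0, 16.0, 16.0)),),
        noise_sigma=5.0,
        seed=7,
    )
    series, truth = render_phantom(spec)
    return spec, series, truth
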