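"""Shared fixtures: calibrated presets and small synthetic recordings.

Session-scoped so that the expensive pieces (preset calibration, example
recordings) are built once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from cardioresp import HEALTHY, SPORT, generate_recording
from cardioresp.synthetic import calibrate_preset


@pytest.fixture(scope="session")
def healthy_cal():
    return calibrate_preset(HEALTHY, seed=12345)


@pytest.fixture(scope="session")
def sport_cal():
    return calibrate_preset(SPORT, seed=12345)


@pytest.fixture(scope="session")
def healthy_recording(healthy_cal):
    return generate_recording(
        HEALTHY, seed=7, scales=(healthy_cal.a, healthy_cal.g)
    )


@pytest.fixture(scope="session")
def uncoupled_recordings():
    preset = HEALTHY.with_(coupling_strength=0.0)
    cal = calibrate_preset(preset, seed=12345)
    return [
        generate_recording(
            preset, seed=300 + i, scales=(cal.a, cal.g), between_subject=False
        )
        for i in range(5)
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
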