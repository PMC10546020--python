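"""Shared fixtures: one synthetic study per session plus small helpers."""

from __future__ import annotations

import datetime as dt

import pytest

from cottonphys.config import PipelineConfig
from cottonphys.pipeline import analyze_study
from cottonphys.simulate import SimConfig, generate_study
from cottonphys.thermal_time import WeatherDay


@pytest.fixture(scope="session")
def bundle1():
    """Default synthetic study, seed 1 (25 plots x 5 dates)."""
    return generate_study(SimConfig(seed=1))


@pytest.fixture(scope="session")
def result1(bundle1):
    """Full pipeline result on the seed-1 study."""
    return analyze_study(bundle1, PipelineConfig())


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Synthetic study with observation noise switched off."""
    return generate_study(SimConfig(seed=2).noiseless())


@pytest.fixture()
def flat_weather():
    """Ten days of constant weather: tmax 30, tmin 20, solar 20."""
    start = dt.date(2022, 5, 1)
    return [
        WeatherDay(date=start + dt.timedelta(days=i), tmax=30.0, tmin=20.0, solar=20.0)
        for i in range(10)
    ]
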