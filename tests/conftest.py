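import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mclsim.forcing import WeatherDay, WeatherSeries, ZoneClimateSpec, generate_weather
from mclsim.soil import SoilLayer, SoilProfile


def make_day(tmin=22.0, tmax=34.0, precip=0.0, srad=20.0, rh=50.0, wind=2.0,
             date="2001-07-01"):
    ts = pd.Timestamp(date)
    return WeatherDay(ts, tmin, tmax, 0.5 * (tmin + tmax), precip, srad, rh, wind)


@pytest.fixture
def sahel_weather():
    return generate_weather(ZoneClimateSpec(zone="sahelian", seed=7), 3)


@pytest.fixture
def two_layer_profile():
    # 100 mm fc / 40 mm wp top, 150/60 bottom, both half full above wp
    layers = [SoilLayer(0.3, 100.0, 40.0, 160.0, 70.0),
              SoilLayer(0.5, 150.0, 60.0, 240.0, 105.0)]
    return SoilProfile(layers, mineral_n=10.0, infiltration_capacity=50.0)
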