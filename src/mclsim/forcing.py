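"""Daily weather forcing: synthetic zone-specific generation, climate deltas, CSV I/O.

Weather series are stored as a pandas DataFrame with one row per calendar day
and columns ``tmin, tmax, tmean, precip, srad, rh, wind`` indexed by date.
The synthetic generator emulates the two West African agro-ecological zones:
a Sahelian regime (short unimodal wet season, ~150-600 mm yr-1, 25-31 degC)
and a Sudanian regime (longer wet season, ~600-1200 mm yr-1, 22-29 degC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

WEATHER_COLUMNS = ["tmin", "tmax", "tmean", "precip", "srad", "rh", "wind"]
CSV_COLUMNS = ["date", "tmin", "tmax", "precip", "srad", "rh", "wind"]

ZONES = ("sahelian", "sudanian")


class WeatherFormatError(ValueError):
    """Missing column or malformed weather file."""


class WeatherSequenceError(ValueError):
    """Dates not strictly increasing / gapped."""


class WeatherValidationError(ValueError):
    """A physical invariant (tmin <= tmax, precip >= 0, ...) is violated."""


@dataclass(frozen=True)
class ZoneClimateSpec:
    """Statistical description of one zone's daily climate.

    Parameters
    ----------
    zone : {"sahelian", "sudanian"}
    annual_rain_mm : target long-run mean annual rainfall (mm).
    wet_season_start_doy, wet_season_length_days : wet-season window (1-based DOY).
    tmax_mean, tmin_mean : annual-mean daily extremes (degC).
    cv_rain : interannual coefficient of variation of annual totals (%).
    seed : RNG seed; identical spec + seed gives identical series.
    """

    zone: str = "sahelian"
    annual_rain_mm: float = 400.0
    wet_season_start_doy: int = 160
    wet_season_length_days: int = 110
    tmax_mean: float = 36.0
    tmin_mean: float = 22.0
    cv_rain: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.zone not in ZONES:
            raise ValueError(f"unknown zone {self.zone!r}; expected one of {ZONES}")
        if self.annual_rain_mm <= 0:
            raise ValueError("annual_rain_mm must be > 0")
        if not 0 < self.wet_season_length_days < 366:
            raise ValueError("wet_season_length_days must lie in (0, 366)")
        if self.cv_rain < 0:
            raise ValueError("cv_rain must be >= 0")


#: Illustrative zone defaults; annual means sit inside the zones' climatic ranges.
ZONE_SPECS = {
    "sahelian": ZoneClimateSpec(
        zone="sahelian", annual_rain_mm=400.0, wet_season_start_doy=160,
        wet_season_length_days=110, tmax_mean=36.0, tmin_mean=22.0, cv_rain=30.0,
    ),
    "sudanian": ZoneClimateSpec(
        zone="sudanian", annual_rain_mm=900.0, wet_season_start_doy=130,
        wet_season_length_days=170, tmax_mean=33.0, tmin_mean=21.0, cv_rain=20.0,
    ),
}


@dataclass(frozen=True)
class ClimateDelta:
    """Additive temperature shift and multiplicative precipitation factor."""

    delta_tmax: float = 0.0
    delta_tmin: float = 0.0
    precip_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.precip_factor < 0:
            raise ValueError("precip_factor must be >= 0")


@dataclass(frozen=True)
class WeatherDay:
    """One day of forcing, the unit the process modules consume."""

    date: pd.Timestamp
    tmin: float
    tmax: float
    tmean: float
    precip: float
    srad: float
    rh: float
    wind: float

    @property
    def doy(self) -> int:
        return int(self.date.dayofyear)


@dataclass
class WeatherSeries:
    """Daily forcing for one site: a validated DataFrame plus site metadata."""

    site_id: str
    latitude: float
    data: pd.DataFrame  # index: DatetimeIndex, columns: WEATHER_COLUMNS

    def __post_init__(self) -> None:
        validate_weather_frame(self.data)

    def __len__(self) -> int:
        return len(self.data)

    def year_totals(self, column: str = "precip") -> pd.Series:
        return self.data[column].groupby(self.data.index.year).sum()

    def copy(self) -> "WeatherSeries":
        return WeatherSeries(self.site_id, self.latitude, self.data.copy())

    def day(self, i: int) -> WeatherDay:
        row = self.data.iloc[i]
        return WeatherDay(self.data.index[i], *(float(row[c]) for c in WEATHER_COLUMNS))

    def iter_days(self):
        idx = self.data.index
        cols = [self.data[c].to_numpy() for c in WEATHER_COLUMNS]
        for i in range(len(idx)):
            yield WeatherDay(idx[i], *(float(col[i]) for col in cols))


def validate_weather_frame(df: pd.DataFrame) -> None:
    """Raise if the frame violates the daily-weather invariants."""
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise WeatherFormatError(f"missing weather column(s): {', '.join(missing)}")
    if not isinstance(df.index, pd.DatetimeIndex):
        raise WeatherSequenceError("weather index must be datetime")
    if len(df) == 0:
        raise WeatherValidationError("empty weather series")
    diffs = df.index.to_series().diff().dropna()
    if len(diffs) and not (diffs == pd.Timedelta(days=1)).all():
        raise WeatherSequenceError("dates must be strictly increasing daily with no gaps")
    checks = [
        (df["tmin"] > df["tmean"] + 1e-9, "tmin > tmean"),
        (df["tmean"] > df["tmax"] + 1e-9, "tmean > tmax"),
        (df["precip"] < 0, "negative precip"),
        (df["srad"] < 0, "negative srad"),
        (df["rh"] < 0, "rh < 0"),
        (df["rh"] > 100, "rh > 100"),
        (df["wind"] < 0, "negative wind"),
    ]
    for bad, what in checks:
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise WeatherValidationError(f"{what} at row {row} ({df.index[row].date()})")


def _wet_season_mask(doy: np.ndarray, start: int, length: int) -> np.ndarray:
    # window may wrap the year end
    end = start + length - 1
    if end <= 366:
        return (doy >= start) & (doy <= end)
    return (doy >= start) | (doy <= end - 366)


def generate_weather(spec: ZoneClimateSpec, n_years: int, *,
                     start_year: int = 2001, site_id: str | None = None,
                     latitude: float = 13.0) -> WeatherSeries:
    """Generate ``n_years`` of synthetic daily weather for one zone.

    Rainfall: a two-state (wet/dry) Markov occurrence chain inside the wet-season
    window with exponential wet-day amounts, rescaled per year so annual totals
    follow a lognormal law with mean ``annual_rain_mm`` and CV ``cv_rain``.
    Temperatures: seasonal sine around the zone means plus Gaussian noise.
    Solar radiation: clear-sky seasonal curve damped 25 % on wet days.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(spec.seed)
    dates = pd.date_range(f"{start_year}-01-01", f"{start_year + n_years - 1}-12-31",
                          freq="D")
    doy = dates.dayofyear.to_numpy()
    n = len(dates)
    years = dates.year.to_numpy()

    # --- rainfall occurrence: persistent Markov chain within the window
    wet_window = _wet_season_mask(doy, spec.wet_season_start_doy,
                                  spec.wet_season_length_days)
    p_ww, p_wd = 0.65, 0.30  # P(wet | wet yesterday), P(wet | dry yesterday)
    u = rng.random(n)
    occurrence = np.zeros(n, dtype=bool)
    prev = False
    for i in range(n):
        if wet_window[i]:
            occurrence[i] = u[i] < (p_ww if prev else p_wd)
        prev = occurrence[i]

    # exponential wet-day amounts, then exact per-year rescaling to the target
    amounts = np.where(occurrence, rng.exponential(1.0, n), 0.0)

    if spec.cv_rain > 0:
        cv = spec.cv_rain / 100.0
        sigma2 = np.log1p(cv * cv)
        year_ids = np.unique(years)
        factors = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), len(year_ids))
        year_factor = dict(zip(year_ids.tolist(), factors.tolist()))
    else:
        year_factor = {int(y): 1.0 for y in np.unique(years)}

    precip = np.zeros(n)
    for y in np.unique(years):
        sel = years == y
        raw = amounts[sel].sum()
        target = spec.annual_rain_mm * year_factor[int(y)]
        if raw > 0:
            precip[sel] = amounts[sel] * (target / raw)
        elif wet_window[sel].any():
            # degenerate all-dry draw: put the whole target on the mid-window day
            idx = np.flatnonzero(sel & wet_window)
            precip[idx[len(idx) // 2]] = target
    wet = precip > 0

    # --- temperatures: hottest just before monsoon onset (~45 d before mid-window)
    phase = (spec.wet_season_start_doy - 45) % 365
    seasonal = np.cos(2 * np.pi * (doy - phase) / 365.0)
    tmax = spec.tmax_mean + 3.5 * seasonal + rng.normal(0.0, 1.0, n)
    tmax = np.where(wet, tmax - 1.5, tmax)  # cloud cooling on rain days
    tmin = spec.tmin_mean + 3.0 * seasonal + rng.normal(0.0, 1.0, n)
    tmin = np.minimum(tmin, tmax - 2.0)
    tmean = 0.5 * (tmin + tmax)

    # --- radiation, humidity, wind
    srad = 20.0 + 3.5 * np.cos(2 * np.pi * (doy - 120) / 365.0) \
        + rng.normal(0.0, 1.0, n)
    srad = np.clip(srad, 5.0, None)
    srad = np.where(wet, 0.75 * srad, srad)
    rh = np.where(wet_window, 70.0, 30.0) + rng.normal(0.0, 6.0, n)
    rh = np.clip(rh, 2.0, 98.0)
    wind = np.clip(rng.normal(2.2, 0.8, n), 0.1, None)

    df = pd.DataFrame(
        {"tmin": tmin, "tmax": tmax, "tmean": tmean, "precip": precip,
         "srad": srad, "rh": rh, "wind": wind},
        index=dates,
    )
    return WeatherSeries(site_id or f"{spec.zone}-synthetic", latitude, df)


def apply_climate_delta(series: WeatherSeries, delta: ClimateDelta) -> WeatherSeries:
    """Shift temperatures additively and scale precipitation multiplicatively.

    ``tmean`` is recomputed as ``(tmin + tmax) / 2``; radiation, humidity and
    wind are left unchanged.
    """
    df = series.data.copy()
    df["tmax"] = df["tmax"] + delta.delta_tmax
    df["tmin"] = df["tmin"] + delta.delta_tmin
    df["tmean"] = 0.5 * (df["tmin"] + df["tmax"])
    df["precip"] = df["precip"] * delta.precip_factor
    return WeatherSeries(series.site_id, series.latitude, df)


def compose_deltas(d1: ClimateDelta, d2: ClimateDelta) -> ClimateDelta:
    """The single delta equivalent to applying ``d1`` then ``d2``."""
    return ClimateDelta(d1.delta_tmax + d2.delta_tmax,
                        d1.delta_tmin + d2.delta_tmin,
                        d1.precip_factor * d2.precip_factor)


def read_weather_csv(path, *, site_id: str | None = None,
                     latitude: float = 13.0) -> WeatherSeries:
    """Read the weather CSV dialect: header ``date,tmin,tmax,precip,srad,rh,wind``.

    ``tmean`` is filled as (tmin+tmax)/2 when the file does not carry it.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise WeatherFormatError(
            f"{path}: missing required column(s): {', '.join(missing)}")
    df["date"] = pd.to_datetime(df["date"])
    df = df.set_index("date")
    df.index.name = None
    if "tmean" not in df.columns:
        df["tmean"] = 0.5 * (df["tmin"] + df["tmax"])
    df = df[WEATHER_COLUMNS].astype(float)
    return WeatherSeries(site_id or str(path), latitude, df)


def write_weather_csv(series: WeatherSeries, path) -> None:
    out = series.data.reset_index(names="date")
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out[CSV_COLUMNS].to_csv(path, index=False, float_format="%.6f")
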