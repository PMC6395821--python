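"""Synthetic station weather and temperature-logger series.

The station series emulates an hourly valley weather station: air
temperature as seasonal trend + daily sinusoid + noise, wind speed and
cosine wind direction (+1 = wind from the north, -1 = from the south), and
daytime solar radiation.  Logger series are derived from the station by an
elevational lapse, per-sector offsets and independent noise — exactly the
linear structure the thermal interpolation model is built to recover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class WeatherConfig:
    start: str = "2011-05-01"
    n_days: int = 180
    mean_temp: float = 10.0  # deg C at the station over the season
    seasonal_amplitude: float = 6.0  # deg C, peak of the seasonal half-sine
    daily_amplitude: float = 5.0  # deg C, half peak-to-trough of the diurnal cycle
    peak_hour: int = 14  # local hour of the daily temperature maximum
    noise_sd: float = 0.8  # deg C
    wind_mean: float = 2.0  # m/s
    wind_sd: float = 1.2
    solar_max: float = 900.0  # W/m2 clear-sky noon
    seed: int = 0

    def validate(self) -> None:
        if self.n_days < 1:
            raise ValueError("duration must be at least one day")


def generate_weather(config: WeatherConfig) -> pd.DataFrame:
    """Hourly station series: temp_station, wind_speed, cos_wind_dir, solar.

    Temperature is ``mean + seasonal half-sine + daily_amplitude *
    cos(2*pi*(hour - peak_hour)/24) + noise``, so the noiseless daily
    maximum is ``mean + seasonal + daily_amplitude`` at ``peak_hour``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    idx = pd.date_range(config.start, periods=config.n_days * 24, freq="h")
    hours = idx.hour.to_numpy()
    dayfrac = np.arange(len(idx)) / (config.n_days * 24.0)
    seasonal = config.seasonal_amplitude * np.sin(np.pi * dayfrac)
    diurnal = config.daily_amplitude * np.cos(2 * np.pi * (hours - config.peak_hour) / 24.0)
    temp = config.mean_temp + seasonal + diurnal + rng.normal(0, config.noise_sd, len(idx))

    wind = np.abs(rng.normal(config.wind_mean, config.wind_sd, len(idx)))
    # wind direction drifts slowly through the season
    phase = np.cumsum(rng.normal(0, 0.08, len(idx)))
    cos_wind_dir = np.clip(np.cos(phase), -1.0, 1.0)
    solar = config.solar_max * np.clip(
        np.cos(2 * np.pi * (hours - 13) / 24.0), 0.0, None
    ) * (0.7 + 0.3 * rng.random(len(idx)))

    return pd.DataFrame(
        {
            "timestamp": idx,
            "temp_station": temp,
            "wind_speed": wind,
            "cos_wind_dir": cos_wind_dir,
            "solar": solar,
        }
    )


@dataclass
class LoggerNetwork:
    """Logger placement metadata plus the hourly series.

    ``meta`` columns: logger_id, row, col, x, y, elevation, sector.
    ``series`` columns: logger_id, timestamp, temp.
    """

    meta: pd.DataFrame
    series: pd.DataFrame
    station_elevation: float


def place_loggers(stack, n_loggers: int, seed: int = 0) -> pd.DataFrame:
    """Stratified logger placement spanning elevation and sectors."""
    if n_loggers < 2:
        raise ValueError("need at least 2 loggers")
    rng = np.random.default_rng(seed)
    dem = stack["dem"]
    sector = stack["sector"].astype(int)
    valid = stack.valid
    rows, cols = np.nonzero(valid)
    elev = dem[rows, cols]
    # stratify by elevation quantile bins, rotating through sectors
    qs = np.quantile(elev, np.linspace(0, 1, n_loggers + 1))
    recs = []
    n_sectors = int(sector.max()) + 1
    for i in range(n_loggers):
        lo, hi = qs[i], qs[i + 1]
        in_bin = (elev >= lo) & (elev <= hi)
        want_sector = i % n_sectors
        pick = in_bin & (sector[rows, cols] == want_sector)
        if not pick.any():
            pick = in_bin
        j = rng.choice(np.nonzero(pick)[0])
        r, c = rows[j], cols[j]
        x, y = stack.georef.xy(r, c)
        recs.append(
            {
                "logger_id": i,
                "row": int(r),
                "col": int(c),
                "x": float(x),
                "y": float(y),
                "elevation": float(dem[r, c]),
                "sector": int(sector[r, c]),
            }
        )
    return pd.DataFrame(recs)


def generate_logger_data(
    stack,
    weather: pd.DataFrame,
    lapse_rate: float = -0.0065,
    sector_offsets=None,
    noise_sd: float = 0.5,
    n_loggers: int = 17,
    station_elevation: float = 1951.0,
    seed: int = 0,
    logger_meta: pd.DataFrame | None = None,
) -> LoggerNetwork:
    """Hourly logger temperatures from the station series.

    ``temp = temp_station + lapse_rate * (elev - station_elevation) +
    sector_offset + noise``.  The default network size (17) matches a
    two-year deployment of 15-17 loggers stratified by elevation and
    hydro-geographic sector.
    """
    meta = logger_meta if logger_meta is not None else place_loggers(stack, n_loggers, seed)
    g = stack.georef
    if not np.all(g.contains(meta["x"], meta["y"])):
        raise ValueError("logger positions must fall inside the landscape")
    n_sectors = int(stack["sector"].max()) + 1
    if sector_offsets is None:
        sector_offsets = np.zeros(n_sectors)
    sector_offsets = np.asarray(sector_offsets, float)

    rng = np.random.default_rng(seed + 1)
    frames = []
    for _, lg in meta.iterrows():
        base = (
            weather["temp_station"].to_numpy()
            + lapse_rate * (lg["elevation"] - station_elevation)
            + sector_offsets[int(lg["sector"])]
        )
        temp = base + rng.normal(0, noise_sd, len(weather)) if noise_sd > 0 else base
        frames.append(
            pd.DataFrame(
                {
                    "logger_id": int(lg["logger_id"]),
                    "timestamp": weather["timestamp"].to_numpy(),
                    "temp": temp,
                }
            )
        )
    return LoggerNetwork(
        meta=meta, series=pd.concat(frames, ignore_index=True), station_elevation=station_elevation
    )
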