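"""Thermal-field interpolation: from loggers + station to per-pixel temperature.

The model is linear in the station temperature, the logger-station
elevation offset, and the hydro-geographic sector:

    T_logger(t) = a + b * T_station(t) + lapse * (elev - elev_station)
                  + offset[sector] + eps

fitted by least squares, with the first sector as the reference (offset 0).
Prediction applies the same linear form to every landscape pixel; maximum
daily temperature is the per-pixel maximum over the 24 hourly predictions
of the date, which keeps the two prediction modes exactly consistent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import Raster
from .weather import LoggerNetwork


@dataclass
class ThermalResults:
    """Fitted interpolation coefficients and metadata."""

    intercept: float
    station_coef: float
    lapse: float  # deg C per metre
    sector_offsets: np.ndarray  # one per sector, reference fixed at 0
    resid_sd: float
    station_elevation: float
    nobs: int
    time_span: tuple
    cov_params: np.ndarray | None = None
    param_names: list = field(default_factory=list)

    def conf_int(self, alpha: float = 0.05):
        """Wald confidence intervals, rows ordered as ``param_names``."""
        from scipy import stats

        if self.cov_params is None:
            raise ValueError("covariance unavailable")
        est = np.concatenate(
            [[self.intercept, self.station_coef, self.lapse], self.sector_offsets[1:]]
        )
        se = np.sqrt(np.diag(self.cov_params))
        zc = stats.norm.ppf(1 - alpha / 2)
        return np.column_stack([est - zc * se, est + zc * se])

    def predict_at(self, station_temp, elevation, sector):
        """Temperature at given elevation/sector for a station reading."""
        sector = np.asarray(sector, int)
        return (
            self.intercept
            + self.station_coef * np.asarray(station_temp, float)
            + self.lapse * (np.asarray(elevation, float) - self.station_elevation)
            + self.sector_offsets[sector]
        )

    def to_json(self, path=None) -> str:
        obj = {
            "intercept": self.intercept,
            "station_coef": self.station_coef,
            "lapse": self.lapse,
            "sector_offsets": list(map(float, self.sector_offsets)),
            "resid_sd": self.resid_sd,
            "station_elevation": self.station_elevation,
            "nobs": self.nobs,
            "time_span": [str(t) for t in self.time_span],
        }
        text = json.dumps(obj, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "ThermalResults":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            intercept=obj["intercept"],
            station_coef=obj["station_coef"],
            lapse=obj["lapse"],
            sector_offsets=np.asarray(obj["sector_offsets"], float),
            resid_sd=obj["resid_sd"],
            station_elevation=obj["station_elevation"],
            nobs=obj["nobs"],
            time_span=tuple(obj["time_span"]),
        )


class ThermalModel:
    """Interpolation model over a logger network and a station series."""

    def __init__(self, loggers: LoggerNetwork, weather: pd.DataFrame):
        if loggers.meta["elevation"].nunique() < 2:
            raise ValueError(
                "rank-deficient design: all loggers share one elevation, "
                "the elevation (lapse) term is not estimable"
            )
        merged = loggers.series.merge(loggers.meta, on="logger_id")
        merged = merged.merge(
            weather[["timestamp", "temp_station"]], on="timestamp", how="inner"
        )
        if merged.empty:
            raise ValueError("logger and station series do not overlap in time")
        self.data = merged
        self.station_elevation = loggers.station_elevation
        self.n_sectors = int(merged["sector"].max()) + 1

    def fit(self) -> ThermalResults:
        import statsmodels.api as sm

        d = self.data
        cols = {
            "temp_station": d["temp_station"].to_numpy(),
            "elev_offset": (d["elevation"] - self.station_elevation).to_numpy(),
        }
        names = ["intercept", "temp_station", "elev_offset"]
        for s in range(1, self.n_sectors):
            cols[f"sector_{s}"] = (d["sector"] == s).to_numpy(float)
            names.append(f"sector_{s}")
        X = sm.add_constant(pd.DataFrame(cols), has_constant="add")
        res = sm.OLS(d["temp"].to_numpy(), X.to_numpy()).fit()
        params = res.params
        offsets = np.zeros(self.n_sectors)
        for s in range(1, self.n_sectors):
            offsets[s] = params[2 + s]
        resid_sd = float(np.sqrt(res.scale))
        return ThermalResults(
            intercept=float(params[0]),
            station_coef=float(params[1]),
            lapse=float(params[2]),
            sector_offsets=offsets,
            resid_sd=resid_sd,
            station_elevation=self.station_elevation,
            nobs=int(res.nobs),
            time_span=(d["timestamp"].min(), d["timestamp"].max()),
            cov_params=np.asarray(res.cov_params()),
            param_names=names,
        )


def fit_thermal_model(loggers: LoggerNetwork, weather: pd.DataFrame) -> ThermalResults:
    """Convenience wrapper: build and fit in one call."""
    return ThermalModel(loggers, weather).fit()


def _station_slice(weather: pd.DataFrame, date) -> pd.DataFrame:
    day = pd.Timestamp(date).normalize()
    ts = pd.to_datetime(weather["timestamp"])
    sel = weather[(ts >= day) & (ts < day + pd.Timedelta(days=1))]
    if sel.empty:
        raise ValueError(f"date {day.date()} outside the station record")
    return sel


def predict_temperature(
    model: ThermalResults, stack, weather: pd.DataFrame, when, mode: str = "hourly"
) -> Raster:
    """Per-pixel temperature raster at an hour, or the daily maximum.

    ``mode='hourly'`` needs ``when`` to be a timestamp present in the
    station series; ``mode='max_daily'`` needs a date covered by it and
    evaluates all its hours, taking the per-pixel maximum.
    """
    dem = stack["dem"]
    sector = stack["sector"].astype(int)
    if mode == "hourly":
        ts = pd.Timestamp(when)
        row = weather[pd.to_datetime(weather["timestamp"]) == ts]
        if row.empty:
            raise ValueError(f"hour {ts} outside the station record")
        grid = model.predict_at(float(row["temp_station"].iloc[0]), dem, sector)
    elif mode == "max_daily":
        sel = _station_slice(weather, when)
        # explicit hour-by-hour evaluation keeps max-daily exactly
        # consistent with the hourly predictions
        grid = np.full(dem.shape, -np.inf)
        for t in sel["temp_station"].to_numpy():
            grid = np.maximum(grid, model.predict_at(t, dem, sector))
    else:
        raise ValueError("mode must be 'hourly' or 'max_daily'")
    out = np.where(stack.valid, grid, stack.nodata)
    return Raster(out, stack.georef, stack.nodata)


def station_max_daily(weather: pd.DataFrame, date) -> float:
    """Maximum station temperature over the 24 hours of ``date``."""
    return float(_station_slice(weather, date)["temp_station"].max())
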