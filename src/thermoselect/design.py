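"""Two-scale used/available design.

Builds the stratified case/control table a resource-selection fit consumes:
an availability domain (population-level 100% MCP, or per-observation
mobility circles), uniform random available points paired 1:k with each
used location under a shared stratum ID, covariate attachment from the
raster stack and thermal model, table-wide standardization, and the
availability-ratio sensitivity analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, mapping

logger = logging.getLogger(__name__)

#: numeric covariates standardized by default when present
DEFAULT_COVARIATES = [
    "elevation",
    "slope",
    "cos_aspect",
    "ruggedness",
    "ndvi",
    "log_dist_trail",
    "dist_safe",
    "t_max_daily",
    "t_hourly",
    "wind_speed",
    "cos_wind_dir",
    "solar",
    "group_size",
    "julian_day",
]


@dataclass
class ScalingParams:
    """Per-covariate (mean, SD) frozen at fit time for projection reuse."""

    params: dict = field(default_factory=dict)  # name -> (mean, sd)

    def transform(self, name: str, x):
        mean, sd = self.params[name]
        return (np.asarray(x, float) - mean) / sd

    def inverse(self, name: str, z):
        mean, sd = self.params[name]
        return np.asarray(z, float) * sd + mean

    def __contains__(self, name):
        return name in self.params

    def to_dict(self):
        return {k: [float(m), float(s)] for k, (m, s) in self.params.items()}

    @classmethod
    def from_dict(cls, d):
        return cls({k: (float(v[0]), float(v[1])) for k, v in d.items()})


@dataclass
class AvailabilityDomain:
    """Large scale: one MCP polygon.  Small scale: a circle per used point."""

    scale: str  # "large" | "small"
    polygon: object = None  # shapely Polygon (large scale)
    radius_by_month: dict = None  # month -> metres (small scale)

    def to_geojson(self, path=None) -> str:
        if self.scale != "large":
            raise ValueError("GeoJSON export implemented for the MCP domain")
        obj = {
            "type": "Feature",
            "properties": {"scale": self.scale},
            "geometry": mapping(self.polygon),
        }
        text = json.dumps(obj, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def mcp(points: np.ndarray):
    """100% minimum convex polygon (convex hull) of used locations."""
    pts = np.asarray(points, float)
    if len(pts) < 3:
        raise ValueError("MCP needs at least 3 points")
    hull = MultiPoint(pts).convex_hull
    if hull.geom_type != "Polygon" or hull.area == 0:
        raise ValueError("degenerate MCP: points are collinear")
    return hull


def availability_domain(obs: pd.DataFrame, scale: str, radius_by_month: dict | None = None):
    """Availability domain for one spatial scale.

    Large scale is the population-level home range (100% MCP over all used
    points); small scale is a per-observation circle whose radius follows
    monthly mobility.
    """
    if scale == "large":
        return AvailabilityDomain("large", polygon=mcp(obs[["x", "y"]].to_numpy()))
    if scale == "small":
        if not radius_by_month:
            raise ValueError("small scale requires radius_by_month")
        if any(r <= 0 for r in radius_by_month.values()):
            raise ValueError("buffer radii must be positive")
        return AvailabilityDomain("small", radius_by_month=dict(radius_by_month))
    raise ValueError(f"unknown scale {scale!r}")


_INHERITED = ["individual_id", "group_id", "group_size", "timestamp", "julian_day"]


def _point_valid(stack, x, y):
    if stack is None:
        return np.ones(np.shape(x), dtype=bool)
    ok = stack.georef.contains(x, y)
    v = stack.raster(next(iter(stack.layers))).like(stack.valid.astype(float)).sample(x, y)
    return ok & (v > 0.5)


def _sample_polygon(polygon, n, rng, stack=None, max_iter=1000):
    minx, miny, maxx, maxy = polygon.bounds
    out = np.empty((0, 2))
    for _ in range(max_iter):
        m = max(4 * (n - len(out)), 64)
        x = rng.uniform(minx, maxx, m)
        y = rng.uniform(miny, maxy, m)
        keep = shapely.contains_xy(polygon, x, y) & _point_valid(stack, x, y)
        out = np.vstack([out, np.column_stack([x[keep], y[keep]])])
        if len(out) >= n:
            return out[:n]
    raise RuntimeError("rejection sampling failed: domain appears to be all nodata")


def _sample_circle(cx, cy, radius, n, rng, stack=None, max_iter=1000):
    out = np.empty((0, 2))
    for _ in range(max_iter):
        m = max(4 * (n - len(out)), 16)
        r = radius * np.sqrt(rng.random(m))
        th = rng.uniform(0, 2 * np.pi, m)
        x, y = cx + r * np.cos(th), cy + r * np.sin(th)
        keep = _point_valid(stack, x, y)
        out = np.vstack([out, np.column_stack([x[keep], y[keep]])])
        if len(out) >= n:
            return out[:n]
    raise RuntimeError("rejection sampling failed: buffer appears to be all nodata")


def sample_available(
    obs: pd.DataFrame,
    domain: AvailabilityDomain,
    n_per_used: int,
    stack=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Pair each used location with ``n_per_used`` uniform available points.

    Returns the stratified case/control table: one row per point with
    ``stratum_id``, ``case`` (1 used / 0 available), coordinates, and the
    used observation's individual attributes copied onto its availables.
    Deterministic given ``seed``.
    """
    if n_per_used < 1:
        raise ValueError("n_per_used must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    obs = obs.reset_index(drop=True)
    if domain.scale == "large":
        pool = _sample_polygon(domain.polygon, len(obs) * n_per_used, rng, stack)
    for i, ob in obs.iterrows():
        attrs = {k: ob[k] for k in _INHERITED if k in obs.columns}
        rows.append({"stratum_id": i, "case": 1, "x": ob["x"], "y": ob["y"], **attrs})
        if domain.scale == "large":
            pts = pool[i * n_per_used : (i + 1) * n_per_used]
        else:
            month = pd.Timestamp(ob["timestamp"]).month
            radius = domain.radius_by_month[month]
            pts = _sample_circle(ob["x"], ob["y"], radius, n_per_used, rng, stack)
        for x, y in pts:
            rows.append({"stratum_id": i, "case": 0, "x": x, "y": y, **attrs})
    return pd.DataFrame(rows)


def attach_covariates(
    table: pd.DataFrame,
    stack,
    thermal=None,
    weather: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Attach pixel, thermal and station covariates to every row.

    Pixel covariates come from the containing raster cell; hourly
    temperature applies the thermal model at the row's (inherited)
    timestamp, max-daily temperature at its date; wind covariates are the
    station values at the timestamp, hence shared within a stratum.  Rows
    on nodata pixels are dropped with a logged count.
    """
    table = table.copy()
    x, y = table["x"].to_numpy(), table["y"].to_numpy()
    layer_cols = {
        "elevation": "dem",
        "slope": "slope",
        "cos_aspect": "cos_aspect",
        "ruggedness": "ruggedness",
        "ndvi": "ndvi",
        "log_dist_trail": "log_dist_trail",
        "dist_safe": "dist_safe",
        "landcover": "landcover",
        "sector": "sector",
    }
    bad = np.zeros(len(table), dtype=bool)
    for col, layer in layer_cols.items():
        if layer in stack:
            v = stack.raster(layer).sample(x, y)
            bad |= np.isclose(v, stack.nodata)
            table[col] = v
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("dropping %d rows on nodata pixels", n_bad)
        table = table[~bad].reset_index(drop=True)
    if thermal is not None and weather is not None:
        ts = pd.to_datetime(table["timestamp"]).dt.floor("h")
        w = weather.set_index(pd.to_datetime(weather["timestamp"]))
        st_hour = w["temp_station"].reindex(ts).to_numpy()
        if np.isnan(st_hour).any():
            raise ValueError("some observation hours fall outside the station record")
        table["t_hourly"] = thermal.predict_at(
            st_hour, table["elevation"], table["sector"].astype(int)
        )
        # per-date station profile -> per-row daily maximum of the prediction
        dates = pd.to_datetime(table["timestamp"]).dt.normalize()
        wdates = w.index.normalize()
        base = {}
        for d in dates.unique():
            temps = w["temp_station"].to_numpy()[wdates == d]
            if len(temps) == 0:
                raise ValueError(f"date {d.date()} outside the station record")
            base[d] = temps
        tmax = np.empty(len(table))
        for d, temps in base.items():
            sel = (dates == d).to_numpy()
            elev = table.loc[sel, "elevation"].to_numpy()
            sec = table.loc[sel, "sector"].astype(int).to_numpy()
            preds = np.stack([thermal.predict_at(t, elev, sec) for t in temps])
            tmax[sel] = preds.max(axis=0)
        table["t_max_daily"] = tmax
        for col in ("wind_speed", "cos_wind_dir", "solar"):
            if col in w.columns:
                table[col] = w[col].reindex(ts).to_numpy()
    return table


def standardize(table: pd.DataFrame, covariates=None):
    """Add z-scored columns ``z_<name>`` using table-wide mean/SD.

    Returns the augmented table and the :class:`ScalingParams` needed to
    standardize new (e.g. projected) covariate values identically.
    """
    if covariates is None:
        covariates = [c for c in DEFAULT_COVARIATES if c in table.columns]
    table = table.copy()
    params = {}
    for name in covariates:
        x = table[name].to_numpy(float)
        mean, sd = float(np.mean(x)), float(np.std(x, ddof=0))
        if sd <= 0 or not np.isfinite(sd):
            raise ValueError(f"covariate {name!r} has zero variance, cannot standardize")
        params[name] = (mean, sd)
        table[f"z_{name}"] = (x - mean) / sd
    return table, ScalingParams(params)


@dataclass
class SensitivityResult:
    ratios: list
    coefficients: pd.DataFrame  # one row per ratio
    max_rel_change: list  # length len(ratios) - 1
    stable_ratio: int | None
    failures: list = field(default_factory=list)
    tolerance: float = 0.05


def relative_coefficient_change(prev, new, floor: float = 0.1):
    """Max per-coefficient relative change between successive ratio fits.

    Coefficients whose magnitude stays below ``floor`` (a negligible
    standardized effect) count as unchanged; otherwise the change is
    ``|new - prev| / |prev|``.
    """
    prev = np.asarray(prev, float)
    new = np.asarray(new, float)
    out = np.zeros(len(prev))
    small = (np.abs(prev) < floor) & (np.abs(new) < floor)
    est = np.abs(prev) >= floor
    out[est] = np.abs(new[est] - prev[est]) / np.abs(prev[est])
    blown = ~small & ~est  # grew from ~0 past the floor
    out[blown] = np.inf
    return float(out.max()) if len(out) else 0.0


def availability_sensitivity(
    obs: pd.DataFrame,
    domain: AvailabilityDomain,
    stack,
    spec,
    ratios,
    reps: int = 1,
    seed: int = 0,
    thermal=None,
    weather: pd.DataFrame | None = None,
    tolerance: float = 0.05,
    floor: float = 0.1,
) -> SensitivityResult:
    """Refit the RSF at increasing available:used ratios.

    Reports the smallest ratio from which every subsequent successive
    change in the coefficient vector stays below ``tolerance``.
    Non-convergent refits are recorded, not fatal.
    """
    from .rsf import RSFModel

    if list(ratios) != sorted(ratios):
        raise ValueError("ratios must be increasing")
    coef_rows, failures = [], []
    for ri, ratio in enumerate(ratios):
        reps_coefs = []
        for rep in range(reps):
            try:
                t = sample_available(obs, domain, ratio, stack, seed=seed + 1000 * ri + rep)
                t = attach_covariates(t, stack, thermal, weather)
                t, scaling = standardize(t, covariates=spec.variables)
                fit = RSFModel(t, spec, scaling).fit()
                reps_coefs.append(fit.params.drop("intercept"))
            except Exception as exc:  # noqa: BLE001 - recorded per spec
                failures.append((ratio, rep, str(exc)))
        if not reps_coefs:
            raise RuntimeError(f"all refits failed at ratio {ratio}")
        coef_rows.append(pd.concat(reps_coefs, axis=1).mean(axis=1).rename(ratio))
    coefs = pd.DataFrame(coef_rows)
    changes = [
        relative_coefficient_change(coefs.iloc[i].to_numpy(), coefs.iloc[i + 1].to_numpy(), floor)
        for i in range(len(ratios) - 1)
    ]
    stable = None
    for i in range(len(ratios) - 1):
        if all(c < tolerance for c in changes[i:]):
            stable = ratios[i]
            break
    return SensitivityResult(list(ratios), coefs, changes, stable, failures, tolerance)
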