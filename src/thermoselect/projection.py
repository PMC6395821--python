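"""Climate-delta projection of RSF maps and habitat-change summaries.

Each climate-ensemble member contributes one temperature shift ΔT
(scenario-year August mean maximum-daily temperature minus the observed
baseline); ΔT is added uniformly to the interpolated pixel-level max-daily
field, re-standardized with the *fitting* scaling parameters, and the RSF
is re-evaluated with every other covariate frozen at baseline.  Projecting
each member and then averaging (rather than projecting the mean ΔT)
propagates ensemble spread through the exponential model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import Raster
from .thermal import predict_temperature

SCENARIOS = ("RCP4.5", "RCP8.5")


@dataclass
class ClimateDelta:
    scenario: str
    year: int
    deltas: pd.Series  # per-model ΔT, deg C
    baseline: float

    @property
    def mean(self) -> float:
        return float(self.deltas.mean())

    @property
    def sd(self) -> float:
        return float(self.deltas.std(ddof=1)) if len(self.deltas) > 1 else 0.0


def climate_deltas(ensemble: pd.DataFrame, baseline_temp: float) -> dict:
    """Per-(scenario, year) temperature shifts from an ensemble table.

    ``ensemble`` columns: model, scenario, year, tasmax_aug_C.  The shift
    of each member is its scenario-year August mean max-daily temperature
    minus ``baseline_temp`` (same reference-point definition).
    """
    out = {}
    for (scen, year), grp in ensemble.groupby(["scenario", "year"]):
        if grp.empty:
            raise ValueError(f"no ensemble members for {scen} {year}")
        deltas = pd.Series(
            grp["tasmax_aug_C"].to_numpy(float) - baseline_temp,
            index=grp["model"].to_numpy(),
        )
        out[(scen, int(year))] = ClimateDelta(scen, int(year), deltas, baseline_temp)
    if not out:
        raise ValueError("empty climate ensemble")
    return out


@dataclass
class ScenarioConditions:
    """Context frozen into every projected map.

    Defaults mirror a peak-summer scenario: the hottest survey day
    (Julian day 233, 21 August), the median summer group size (2) and
    median August wind.
    """

    julian_day: float = 233.0
    group_size: float = 2.0
    wind_speed: float = 1.8
    cos_wind_dir: float = 0.0
    baseline_date: str = "2011-08-21"

    def as_context(self) -> dict:
        return {
            "julian_day": self.julian_day,
            "group_size": self.group_size,
            "wind_speed": self.wind_speed,
            "cos_wind_dir": self.cos_wind_dir,
        }


def project_rsf(
    fit,
    stack,
    thermal,
    weather: pd.DataFrame,
    delta: float,
    conditions: ScenarioConditions,
    baseline_tmax: Raster | None = None,
) -> Raster:
    """RSF raster under a uniform temperature shift ``delta`` (deg C).

    The baseline-date max-daily field is computed per pixel, shifted by
    ``delta``, standardized with the fit's original ScalingParams, and
    scored with all other covariates at their stack/condition values.
    """
    if fit.spec.temperature != "max_daily":
        raise ValueError("projection requires the max-daily temperature model")
    if baseline_tmax is None:
        baseline_tmax = predict_temperature(
            thermal, stack, weather, conditions.baseline_date, mode="max_daily"
        )
    shifted = baseline_tmax.like(
        np.where(baseline_tmax.valid, baseline_tmax.data + delta, baseline_tmax.nodata)
    )
    return fit.score_raster(stack, conditions.as_context(), temp_raster=shifted)


def ensemble_summary(runs: list) -> tuple:
    """Per-pixel arithmetic mean and sample SD over member projections."""
    if not runs:
        raise ValueError("need at least one projection")
    ref = runs[0]
    for r in runs[1:]:
        if r.data.shape != ref.data.shape or r.georef != ref.georef:
            raise ValueError("projection grids are not aligned")
    stackarr = np.stack([r.masked() for r in runs])
    mean = np.nanmean(stackarr, axis=0)
    if len(runs) > 1:
        sd = np.nanstd(stackarr, axis=0, ddof=1)
    else:
        sd = np.full(ref.data.shape, np.nan)  # sample SD undefined for n=1
    mean_r = ref.like(np.where(np.isfinite(mean), mean, ref.nodata))
    sd_r = ref.like(np.where(np.isfinite(sd), sd, ref.nodata))
    return mean_r, sd_r


def range_retention(future: Raster, baseline: Raster, rule="score_above_1"):
    """Fraction of the selectable range retained under a projection.

    Rules: ``"score_above_1"`` (selection above the mean-covariate
    baseline; retention = selected area future / selected area baseline),
    ``("quantile", q)`` (threshold at the baseline's q-quantile score,
    applied to both rasters), ``"difference_positive"`` (fraction of the
    valid range where the future score exceeds the baseline; in [0, 1]).
    Also returns the future-minus-baseline difference map.
    """
    if future.data.shape != baseline.data.shape:
        raise ValueError("rasters are not aligned")
    valid = future.valid & baseline.valid
    f, b = future.data, baseline.data
    diff = np.where(valid, f - b, baseline.nodata)
    diff_r = baseline.like(diff)
    if rule == "difference_positive":
        frac = float((f[valid] > b[valid]).sum() / valid.sum())
        return frac, diff_r
    if rule == "score_above_1":
        sel_b = valid & (b > 1.0)
        sel_f = valid & (f > 1.0)
    elif isinstance(rule, tuple) and rule[0] == "quantile":
        thresh = np.quantile(b[valid], rule[1])
        sel_b = valid & (b > thresh)
        sel_f = valid & (f > thresh)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    if sel_b.sum() == 0:
        raise ValueError("baseline selected area is empty; retention undefined")
    return float(sel_f.sum() / sel_b.sum()), diff_r


@dataclass
class ElevationProfile:
    table: pd.DataFrame  # elevation bin centre, mean score, smoothed score
    weighted_mean_elevation: float

    def to_csv(self, path):
        self.table.to_csv(path, index=False)


def elevation_profile(score_raster: Raster, dem: Raster, n_knots: int = 25) -> ElevationProfile:
    """Min-max-standardized score vs elevation, smoothed, plus the
    selection-weighted mean elevation Σ(w·elev)/Σw (raw-score weights)."""
    valid = score_raster.valid & dem.valid
    w = score_raster.data[valid]
    elev = dem.data[valid]
    wmean = float(np.sum(w * elev) / np.sum(w))
    lo, hi = w.min(), w.max()
    if hi > lo:
        s = (w - lo) / (hi - lo)
    else:
        s = np.zeros_like(w)
    if elev.max() == elev.min():
        warnings.warn("flat DEM: elevation profile degenerate", stacklevel=2)
        table = pd.DataFrame(
            {"elevation": [float(elev.mean())], "mean_score": [float(s.mean())],
             "smoothed": [float(s.mean())]}
        )
        return ElevationProfile(table, wmean)
    edges = np.linspace(elev.min(), elev.max(), n_knots + 1)
    idx = np.clip(np.digitize(elev, edges) - 1, 0, n_knots - 1)
    centres, means = [], []
    for i in range(n_knots):
        m = idx == i
        if m.any():
            centres.append(0.5 * (edges[i] + edges[i + 1]))
            means.append(float(s[m].mean()))
    centres, means = np.asarray(centres), np.asarray(means)
    if len(centres) >= 4:
        from scipy.interpolate import UnivariateSpline

        spl = UnivariateSpline(centres, means, k=3, s=len(centres) * np.var(means) * 0.05)
        smoothed = spl(centres)
    else:
        smoothed = means
    table = pd.DataFrame({"elevation": centres, "mean_score": means, "smoothed": smoothed})
    return ElevationProfile(table, wmean)


def save_difference_map(diff: Raster, path, dem: Raster | None = None) -> None:
    """Signed colour-mapped image of a future-minus-baseline score map.

    Red = weaker selection than baseline, blue = stronger, white = no
    change; an optional DEM is drawn as grey hillshade-like background.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    if dem is not None:
        ax.imshow(dem.masked(), cmap="Greys", alpha=0.6)
    d = diff.masked()
    vmax = np.nanmax(np.abs(d)) or 1.0
    im = ax.imshow(d, cmap="RdBu", vmin=-vmax, vmax=vmax)
    fig.colorbar(im, ax=ax, label="score difference (future - baseline)")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class ProjectionSet:
    """All member projections for one (scenario, year) plus summaries."""

    scenario: str
    year: int
    baseline: Raster
    member_rasters: list
    mean: Raster = None
    sd: Raster = None
    retention: float = None
    difference: Raster = None
    profile: ElevationProfile = None


def project_scenario(
    fit,
    stack,
    thermal,
    weather,
    delta: ClimateDelta,
    conditions: ScenarioConditions,
    rule="score_above_1",
) -> ProjectionSet:
    """Project every ensemble member, then summarize (mean/SD maps,
    retention against baseline, elevation profile of the mean map)."""
    baseline_tmax = predict_temperature(
        thermal, stack, weather, conditions.baseline_date, mode="max_daily"
    )
    baseline = project_rsf(
        fit, stack, thermal, weather, 0.0, conditions, baseline_tmax=baseline_tmax
    )
    members = [
        project_rsf(fit, stack, thermal, weather, float(dt), conditions, baseline_tmax)
        for dt in delta.deltas
    ]
    mean_r, sd_r = ensemble_summary(members)
    retention, diff = range_retention(mean_r, baseline, rule)
    profile = elevation_profile(mean_r, stack.raster("dem"))
    return ProjectionSet(
        delta.scenario, delta.year, baseline, members, mean_r, sd_r, retention, diff, profile
    )
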