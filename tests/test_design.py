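"""Used/available design: MCP, sampling, pairing, standardization, sensitivity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import thermoselect as ts
from thermoselect.design import relative_coefficient_change
from thermoselect.rsf import ModelSpec, RSFModel


def _obs(points, month=6):
    return pd.DataFrame(
        {
            "individual_id": range(len(points)),
            "group_id": range(len(points)),
            "group_size": 1,
            "timestamp": pd.Timestamp(f"2011-{month:02d}-15 06:00"),
            "julian_day": 196.0,
            "x": [p[0] for p in points],
            "y": [p[1] for p in points],
        }
    )


def test_mcp_triangle_matches_shoelace():
    hull = ts.mcp([(0, 0), (4, 0), (0, 3)])
    assert hull.area == pytest.approx(6.0)  # shoelace: |4*3|/2


def test_mcp_unit_square():
    hull = ts.mcp([(0, 0), (1, 0), (1, 1), (0, 1)])
    assert hull.area == pytest.approx(1.0)


def test_collinear_points_rejected():
    with pytest.raises(ValueError, match="collinear"):
        ts.mcp([(0, 0), (1, 1), (2, 2)])
    with pytest.raises(ValueError):
        ts.mcp([(0, 0), (1, 1)])


def test_mcp_contains_all_used_points(fitted_chain):
    import shapely

    obs, dom = fitted_chain["obs"], fitted_chain["domain"]
    buffered = dom.polygon.buffer(1e-9)
    assert shapely.contains_xy(buffered, obs["x"], obs["y"]).all()


def test_stratum_pairing_and_containment():
    import shapely

    obs = _obs([(10, 10), (80, 15), (40, 90), (15, 60)])
    dom = ts.availability_domain(obs, "large")
    table = ts.sample_available(obs, dom, 7, seed=1)
    counts = table.groupby("stratum_id")["case"].agg(["sum", "count"])
    assert (counts["sum"] == 1).all()
    assert (counts["count"] == 8).all()
    av = table[table["case"] == 0]
    assert shapely.contains_xy(dom.polygon, av["x"], av["y"]).all()
    # availables inherit the used row's attributes
    for _, grp in table.groupby("stratum_id"):
        assert grp["individual_id"].nunique() == 1
        assert grp["timestamp"].nunique() == 1


def test_small_scale_uses_monthly_radii():
    obs = pd.concat([_obs([(500, 500)], month=6), _obs([(500, 500)], month=8)])
    dom = ts.availability_domain(obs, "small", radius_by_month={6: 50.0, 8: 400.0})
    table = ts.sample_available(obs, dom, 200, seed=2)
    av = table[table["case"] == 0]
    d = np.hypot(av["x"] - 500, av["y"] - 500)
    june = av[pd.to_datetime(av["timestamp"]).dt.month == 6]
    aug = av[pd.to_datetime(av["timestamp"]).dt.month == 8]
    assert np.hypot(june["x"] - 500, june["y"] - 500).max() <= 50.0
    assert np.hypot(aug["x"] - 500, aug["y"] - 500).max() <= 400.0
    assert np.hypot(aug["x"] - 500, aug["y"] - 500).max() > 50.0
    assert d.min() >= 0


def test_sampling_is_deterministic():
    obs = _obs([(10, 10), (80, 15), (40, 90)])
    dom = ts.availability_domain(obs, "large")
    a = ts.sample_available(obs, dom, 5, seed=3)
    b = ts.sample_available(obs, dom, 5, seed=3)
    pd.testing.assert_frame_equal(a, b)


def test_available_points_uniform_in_rectangle():
    """Uniformity: 4x4-bin chi-square at alpha = 0.01 passes in >= 95/100 draws."""
    obs = _obs([(0.5, 0.5), (99.5, 0.5), (99.5, 99.5), (0.5, 99.5)])
    dom = ts.availability_domain(obs, "large")
    ok = 0
    for rep in range(100):
        table = ts.sample_available(obs, dom, 200, seed=rep)
        av = table[table["case"] == 0]
        # restrict to the full-coverage inner square to keep bins equal-area
        h = np.histogram2d(
            av["x"], av["y"], bins=4, range=[[0.5, 99.5], [0.5, 99.5]]
        )[0].ravel()
        p = stats.chisquare(h).pvalue
        ok += p > 0.01
    assert ok >= 95


def test_standardization_properties(fitted_chain):
    table = fitted_chain["table"]
    zcols = [c for c in table.columns if c.startswith("z_")]
    assert len(zcols) >= 8
    for c in zcols:
        assert abs(table[c].mean()) < 1e-10
        assert abs(table[c].std(ddof=0) - 1) < 1e-10
    # round-trip through the stored scaling parameters
    scaling = fitted_chain["scaling"]
    x = table["ndvi"].to_numpy()
    z = scaling.transform("ndvi", x)
    assert np.allclose(scaling.inverse("ndvi", z), x, atol=1e-12)
    assert scaling.transform("ndvi", scaling.params["ndvi"][0]) == pytest.approx(0.0)
    m, sd = scaling.params["ndvi"]
    assert scaling.transform("ndvi", m + 2 * sd) == pytest.approx(2.0)


def test_zero_variance_covariate_is_named():
    t = pd.DataFrame({"case": [1, 0, 1, 0], "ndvi": [1.0, 1.0, 1.0, 1.0]})
    with pytest.raises(ValueError, match="ndvi"):
        ts.standardize(t, ["ndvi"])


def test_attach_covariates_values(fitted_chain, small_stack, weather60):
    table = fitted_chain["table"]
    # wind covariates come straight from the station: a due-south wind row
    # carries cos_wind_dir = -1 by the station convention
    w2 = weather60.copy()
    w2.loc[:, "cos_wind_dir"] = -1.0
    sub = table.head(20)[["stratum_id", "case", "x", "y", "timestamp"]]
    out = ts.attach_covariates(sub, small_stack, fitted_chain["thermal"], w2)
    assert np.allclose(out["cos_wind_dir"], -1.0)
    # pixel lookup agrees with direct raster sampling
    assert np.allclose(
        out["ndvi"], small_stack.raster("ndvi").sample(out["x"], out["y"])
    )
    # max-daily is shared across equal-elevation same-sector rows of a stratum
    assert "t_max_daily" in out.columns and "t_hourly" in out.columns


def test_hourly_covariate_equals_station_for_null_model(small_stack, weather60):
    null = ts.ThermalResults(
        intercept=0.0, station_coef=1.0, lapse=0.0,
        sector_offsets=np.zeros(3), resid_sd=0.0,
        station_elevation=1951.0, nobs=0, time_span=("", ""),
    )
    sub = _obs([(100, 100), (300, 300)])
    t2 = ts.attach_covariates(sub.assign(stratum_id=0, case=1), small_stack, null, weather60)
    hr = pd.to_datetime(t2["timestamp"]).dt.floor("h")
    w = weather60.set_index(pd.to_datetime(weather60["timestamp"]))
    assert np.allclose(t2["t_hourly"], w["temp_station"].reindex(hr).to_numpy())


def test_relative_change_rule():
    # both below the negligible-effect floor: counts as unchanged
    assert relative_coefficient_change([0.01], [0.03]) == 0.0
    assert relative_coefficient_change([1.0], [1.04]) == pytest.approx(0.04)
    assert relative_coefficient_change([0.05], [0.5]) == np.inf


def test_sensitivity_matches_brute_force_oracle(small_stack, weather60, fitted_chain):
    """The reported stabilization ratio equals one found by an independent
    refitting loop over the same seeds."""
    obs = fitted_chain["obs"].head(120).reset_index(drop=True)
    dom = ts.availability_domain(obs, "large")
    spec = ModelSpec((("ndvi",), ("slope",)), temperature=None)
    ratios = [2, 5, 10, 15]
    res = ts.availability_sensitivity(
        obs, dom, small_stack, spec, ratios, reps=2, seed=77,
        thermal=fitted_chain["thermal"], weather=weather60,
    )
    # brute force: identical pipeline calls, written out longhand
    rows = []
    for ri, ratio in enumerate(ratios):
        reps = []
        for rep in range(2):
            t = ts.sample_available(obs, dom, ratio, small_stack, seed=77 + 1000 * ri + rep)
            t = ts.attach_covariates(t, small_stack, fitted_chain["thermal"], weather60)
            t, scal = ts.standardize(t, covariates=["ndvi", "slope"])
            reps.append(RSFModel(t, spec, scal).fit().params.drop("intercept"))
        rows.append(pd.concat(reps, axis=1).mean(axis=1))
    changes = [
        relative_coefficient_change(rows[i].to_numpy(), rows[i + 1].to_numpy())
        for i in range(len(ratios) - 1)
    ]
    stable = None
    for i in range(len(ratios) - 1):
        if all(c < 0.05 for c in changes[i:]):
            stable = ratios[i]
            break
    assert res.max_rel_change == pytest.approx(changes)
    assert res.stable_ratio == stable


def test_sensitivity_null_truth_stable_at_first_ratio(gaussian_pixels):
    """beta = 0 world: estimates hover near zero at every ratio, so the
    first ratio already counts as stable."""
    rng = np.random.default_rng(0)
    n = 600
    pts = [(x, y) for x, y in zip(rng.uniform(5, 595, n), rng.uniform(5, 595, n))]
    # corner sightings pin the MCP to the sampling square, so used and
    # available points share one uniform distribution exactly
    pts += [(5, 5), (595, 5), (595, 595), (5, 595)]
    obs = _obs(pts)
    stack = ts.generate_landscape(ts.LandscapeConfig(nrows=60, ncols=60, seed=5))
    dom = ts.availability_domain(obs, "large")
    spec = ModelSpec((("ndvi",), ("slope",)), temperature=None)
    res = ts.availability_sensitivity(obs, dom, stack, spec, [2, 5, 10], reps=4, seed=5)
    assert res.stable_ratio == 2
    assert np.abs(res.coefficients.to_numpy()).max() < 0.25


def test_geojson_export(fitted_chain, tmp_path):
    p = tmp_path / "dom.geojson"
    fitted_chain["domain"].to_geojson(p)
    import json

    obj = json.loads(p.read_text())
    assert obj["geometry"]["type"] == "Polygon"
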