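"""RSF estimation: closed forms, likelihood oracles, invariances, mixed fits."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import thermoselect as ts
from thermoselect.mixedlogit import fit_mixed_logit
from thermoselect.rsf import (
    ModelSpec,
    RSFModel,
    RSFResults,
    build_design,
    compare_aic,
)


def _binary_table():
    rows = []
    for case, a, n in [(1, 1, 30), (1, 0, 10), (0, 1, 20), (0, 0, 20)]:
        rows += [{"case": case, "z_cov": float(a)}] * n
    return pd.DataFrame(rows)


def test_two_by_two_design_recovers_log_odds_ratio():
    """used 30A/10B vs available 20A/20B -> beta = ln((30/10)/(20/20)) = ln 3."""
    fit = RSFModel(_binary_table(), ModelSpec((("cov",),), temperature=None)).fit()
    assert fit.params["cov"] == pytest.approx(np.log(3), abs=1e-6)


def test_constant_column_is_named():
    t = _binary_table()
    t["z_flat"] = 1.5
    spec = ModelSpec((("cov",), ("flat",)), temperature=None)
    with pytest.raises(ValueError, match="flat"):
        RSFModel(t, spec)


def test_loglik_matches_hand_coded_bernoulli(gaussian_pixels, recovery_truth):
    table, scal = ts.simulate_used_available(gaussian_pixels, recovery_truth, 200, 5, seed=1)
    model = RSFModel(table, recovery_truth.spec, scal)
    fit = model.fit()
    # independent hand evaluation of the Bernoulli log-likelihood
    X, names = build_design(recovery_truth.spec, table)
    beta = fit.params[names].to_numpy()
    eta = X @ beta
    y = table["case"].to_numpy()
    ll = float(np.sum(y * np.log(1 / (1 + np.exp(-eta))) + (1 - y) * np.log(1 - 1 / (1 + np.exp(-eta)))))
    assert fit.llf == pytest.approx(ll, abs=1e-8)
    assert fit.aic == pytest.approx(2 * len(beta) - 2 * ll, abs=1e-8)


def test_fit_invariant_to_row_order_and_stratum_labels(gaussian_pixels, recovery_truth):
    table, scal = ts.simulate_used_available(gaussian_pixels, recovery_truth, 300, 10, seed=2)
    fit = RSFModel(table, recovery_truth.spec, scal).fit()
    rng = np.random.default_rng(0)
    shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
    shuffled["stratum_id"] = rng.permutation(shuffled["stratum_id"].to_numpy())
    fit2 = RSFModel(shuffled, recovery_truth.spec, scal).fit()
    assert np.allclose(fit.params.to_numpy(), fit2.params.to_numpy(), atol=1e-10)


def test_parameter_recovery_short(gaussian_pixels, recovery_truth):
    table, scal = ts.simulate_used_available(gaussian_pixels, recovery_truth, 2000, 15, seed=3)
    fit = RSFModel(table, recovery_truth.spec, scal).fit()
    est = fit.params[["a", "b", "t", "t^2"]].to_numpy()
    assert np.all(np.abs(est - recovery_truth.beta) < 0.1)


def test_r2_formula_and_ordering(gaussian_pixels, recovery_truth):
    table, scal = ts.simulate_used_available(gaussian_pixels, recovery_truth, 500, 10, seed=4)
    model = RSFModel(table, recovery_truth.spec, scal)
    fit = model.fit()
    m, c = fit.r2_glmm()
    assert m == pytest.approx(c)  # no random variance
    # plug-in check: fixed-predictor variance pi^2/3 gives exactly 1/2
    spec1 = ModelSpec((("a",),), temperature=None)
    m1 = RSFModel(table, spec1, scal)
    f1 = m1.fit()
    var_z = np.var(m1.exog[:, 1])
    f1.params["a"] = np.pi / np.sqrt(3 * var_z)  # forces var(fixed predictor) = pi^2/3
    f1.params["intercept"] = 0.0
    var_f = np.var(m1.exog[:, 1:] @ f1.params.to_numpy()[1:])
    assert var_f == pytest.approx(np.pi**2 / 3, rel=1e-6)
    mm, cc = f1.r2_glmm()
    assert mm == pytest.approx(0.5, rel=1e-6)
    # synthetic random variance raises conditional above marginal
    f1.random_variances = {"individual": 1.0}
    mm2, cc2 = f1.r2_glmm()
    assert cc2 > mm2
    assert mm2 < mm


def test_intercept_only_model_has_zero_marginal_r2(gaussian_pixels, recovery_truth):
    table, scal = ts.simulate_used_available(gaussian_pixels, recovery_truth, 200, 5, seed=5)
    fit = RSFModel(table, ModelSpec((), temperature=None), scal).fit()
    m, c = fit.r2_glmm()
    assert m == 0.0 and c == 0.0


def test_score_identities(small_stack, weather60, fitted_chain):
    fit = fitted_chain["fit"]
    # all covariates at their fitting means -> z = 0 -> w = exp(0) = 1
    z0 = {f"z_{v}": 0.0 for v in fit.spec.variables}
    assert fit.score(z0)[0] == pytest.approx(1.0)
    # single-term fit beta = ln 2 at z = 1 -> w = 2
    single = RSFResults.from_coefficients(
        ModelSpec((("v",),), temperature=None), pd.Series({"v": np.log(2)})
    )
    assert single.score({"z_v": 1.0})[0] == pytest.approx(2.0)
    # raster mode equals looped per-pixel scalar evaluation
    tmax = ts.predict_temperature(
        fitted_chain["thermal"], small_stack, weather60, "2011-06-01", mode="max_daily"
    )
    raster = fit.score_raster(small_stack, {}, temp_raster=tmax)
    scaling = fit.scaling
    beta = fit.params
    rows, cols = np.nonzero(small_stack.valid)
    for i in np.linspace(0, len(rows) - 1, 25).astype(int):
        r, c = rows[i], cols[i]
        zt = scaling.transform("t_max_daily", tmax.data[r, c])
        zn = scaling.transform("ndvi", small_stack["ndvi"][r, c])
        zs = scaling.transform("slope", small_stack["slope"][r, c])
        w = np.exp(
            beta["t_max_daily"] * zt
            + beta["t_max_daily^2"] * zt**2
            + beta["ndvi"] * zn
            + beta["slope"] * zs
        )
        assert raster.data[r, c] == pytest.approx(w, rel=1e-12)
    # positivity everywhere
    assert np.all(raster.data[raster.valid] > 0)


def test_score_raster_names_missing_variable(small_stack, fitted_chain):
    fit = fitted_chain["fit"]
    with pytest.raises(KeyError, match="t_max_daily"):
        fit.score_raster(small_stack, {})  # no temperature source supplied


def test_score_raster_equals_scalar_loop(small_stack):
    spec = ModelSpec((("ndvi",), ("slope",)), temperature=None)
    scaling = ts.ScalingParams({"ndvi": (0.4, 0.2), "slope": (30.0, 12.0)})
    fit = RSFResults.from_coefficients(spec, pd.Series({"ndvi": 0.7, "slope": -0.4}), scaling)
    raster = fit.score_raster(small_stack, {})
    for r in range(0, 60, 13):
        for c in range(0, 60, 13):
            z1 = scaling.transform("ndvi", small_stack["ndvi"][r, c])
            z2 = scaling.transform("slope", small_stack["slope"][r, c])
            assert raster.data[r, c] == pytest.approx(np.exp(0.7 * z1 - 0.4 * z2), rel=1e-12)


def test_concave_temperature_response_peaks_at_vertex():
    spec = ModelSpec((("temp",), ("temp", "temp")), temperature="max_daily")
    b1, b2 = -0.23, -0.082  # concave: negative quadratic
    fit = RSFResults.from_coefficients(
        spec, pd.Series({"t_max_daily": b1, "t_max_daily^2": b2})
    )
    zs = np.linspace(-5, 5, 2001)
    w = fit.score(pd.DataFrame({"z_t_max_daily": zs}))
    zstar = -b1 / (2 * b2)
    assert zs[np.argmax(w)] == pytest.approx(zstar, abs=0.01)


def test_compare_aic_contract(gaussian_pixels, recovery_truth):
    table, scal = ts.simulate_used_available(gaussian_pixels, recovery_truth, 300, 10, seed=6)
    fit = RSFModel(table, recovery_truth.spec, scal).fit()
    assert compare_aic(fit, fit) == 0.0
    table2 = table.head(500)
    fit2 = RSFModel(table2, recovery_truth.spec, scal).fit()
    with pytest.raises(ValueError, match="same rows"):
        compare_aic(fit, fit2)


def test_extra_noise_parameter_costs_two_minus_chi2():
    """Wilks: adding a pure-noise parameter changes AIC by 2 - chi2_1 on
    average, so the mean penalty over 200 simulations is ~1."""
    rng = np.random.default_rng(7)
    spec0 = ModelSpec((("a",),), temperature=None)
    spec1 = ModelSpec((("a",), ("noise",)), temperature=None)
    diffs = []
    for _ in range(200):
        n = 400
        za = rng.normal(0, 1, n)
        zn = rng.normal(0, 1, n)
        p = 1 / (1 + np.exp(-(-1.0 + 0.8 * za)))
        t = pd.DataFrame({"case": rng.random(n) < p, "z_a": za, "z_noise": zn})
        t["case"] = t["case"].astype(int)
        f0 = RSFModel(t, spec0).fit()
        f1 = RSFModel(t, spec1).fit()
        diffs.append(f1.aic - f0.aic)
    assert np.mean(diffs) == pytest.approx(1.0, abs=0.35)


def test_fixed_effects_match_r_glm(tmp_path, gaussian_pixels, recovery_truth):
    """Independent oracle: R's glm on the same table gives the same beta."""
    table, scal = ts.simulate_used_available(gaussian_pixels, recovery_truth, 400, 10, seed=8)
    fit = RSFModel(table, recovery_truth.spec, scal).fit()
    csv = tmp_path / "tab.csv"
    table.rename(columns={"t^2": "tsq"}).to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(
        textwrap.dedent(
            f"""
            d <- read.csv("{csv}")
            d$z_t2 <- d$z_t^2
            m <- glm(case ~ z_a + z_b + z_t + z_t2, data = d, family = binomial)
            cat(sprintf("%.10f\\n", coef(m)))
            """
        )
    )
    out = subprocess.run(
        ["Rscript", "--vanilla", str(script)], capture_output=True, text=True, check=True
    )
    r_coefs = np.array([float(v) for v in out.stdout.split()])
    mine = fit.params[["intercept", "a", "b", "t", "t^2"]].to_numpy()
    assert np.allclose(mine, r_coefs, atol=1e-6)


def test_mixed_fit_matches_lme4_laplace(tmp_path):
    """Random-intercept logistic: Laplace fit agrees with lme4::glmer
    (also Laplace) on a grouped fixture with genuine between-group variance."""
    rng = np.random.default_rng(9)
    n_groups, per = 40, 25
    g = np.repeat(np.arange(n_groups), per)
    u = rng.normal(0, 1.0, n_groups)
    x = rng.normal(0, 1, n_groups * per)
    eta = -0.5 + 0.9 * x + u[g]
    y = (rng.random(len(eta)) < 1 / (1 + np.exp(-eta))).astype(int)
    X = np.column_stack([np.ones_like(x), x])
    out = fit_mixed_logit(y, X, {"grp": g})
    csv = tmp_path / "mix.csv"
    pd.DataFrame({"y": y, "x": x, "g": g}).to_csv(csv, index=False)
    script = tmp_path / "mix.R"
    script.write_text(
        textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(y ~ x + (1 | g), data = d, family = binomial)
            cat(sprintf("%.8f\\n", fixef(m)))
            cat(sprintf("%.8f\\n", as.numeric(VarCorr(m)$g)))
            cat(sprintf("%.8f\\n", as.numeric(logLik(m))))
            """
        )
    )
    res = subprocess.run(
        ["Rscript", "--vanilla", str(script)], capture_output=True, text=True, check=True
    )
    vals = [float(v) for v in res.stdout.split()]
    r_beta, r_var, r_ll = vals[:2], vals[2], vals[3]
    assert np.allclose(out["beta"], r_beta, atol=0.03)
    assert out["sigma2"]["grp"] == pytest.approx(r_var, abs=0.1)
    assert out["llf"] == pytest.approx(r_ll, abs=0.5)


def test_mixed_path_collapses_to_fixed_when_variance_zero(gaussian_pixels, recovery_truth):
    table, scal = ts.simulate_used_available(gaussian_pixels, recovery_truth, 300, 5, seed=10)
    table["individual_id"] = np.repeat(np.arange(60), len(table) // 60)
    spec = ModelSpec(
        recovery_truth.spec.terms, temperature=None, random_effects=("individual_id",)
    )
    fit = RSFModel(table, spec, scal).fit(method="mixed")
    assert fit.random_variances == {"individual_id": 0.0}
    m, c = fit.r2_glmm()
    assert m == pytest.approx(c)


def test_results_serialization_roundtrip(tmp_path, gaussian_pixels, recovery_truth):
    table, scal = ts.simulate_used_available(gaussian_pixels, recovery_truth, 200, 5, seed=11)
    fit = RSFModel(table, recovery_truth.spec, scal).fit()
    p = tmp_path / "fit.json"
    fit.to_json(p)
    back = RSFResults.from_json(p)
    assert np.allclose(back.params.to_numpy(), fit.params.to_numpy())
    z = {f"z_{v}": 0.7 for v in fit.spec.variables}
    assert back.score(z)[0] == pytest.approx(fit.score(z)[0])
    # coefficient table carries the published layout
    tbl = fit.coefficient_table()
    assert list(tbl.columns) == ["beta", "SE", "z", "p"]
    assert "intercept" not in tbl.index
    assert "AIC" in fit.summary() or "AIC:" in fit.summary()


def test_spec_marginality_and_placeholders():
    with pytest.raises(ValueError, match="main effect"):
        ModelSpec((("a", "b"),), temperature=None)
    spec = ModelSpec.full_structure()
    assert ("temp", "ndvi") in spec.terms
    # removable terms exclude mains that appear in interactions
    removable = spec.removable_terms()
    assert ("temp",) not in removable
    assert ("cos_aspect", "cos_wind_dir", "wind_speed") in removable
    assert spec.with_temperature("hourly").term_names[0].startswith("t_hourly")


from hypothesis import given, settings, strategies as st


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    beta=st.floats(-2, 2, allow_nan=False),
    z0=st.floats(-3, 3, allow_nan=False),
    dz=st.floats(0.1, 2, allow_nan=False),
)
def test_log_score_linear_in_each_covariate(beta, z0, dz):
    """log w is linear in each standardized covariate (no quadratic term):
    equal z-steps multiply the score by a constant factor."""
    fit = RSFResults.from_coefficients(
        ModelSpec((("v",),), temperature=None), pd.Series({"v": beta})
    )
    w = fit.score(pd.DataFrame({"z_v": [z0, z0 + dz, z0 + 2 * dz]}))
    assert np.all(w > 0)
    assert np.log(w[1]) - np.log(w[0]) == pytest.approx(np.log(w[2]) - np.log(w[1]), abs=1e-9)
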