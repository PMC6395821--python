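"""Used/available logistic model and the exponential resource selection function.

The estimation target is the RSF ``w(x) = exp(b1*z1 + ... + bn*zn)`` over
standardized covariates, estimated from a stratified used (1) vs available
(0) design by maximum-likelihood logistic regression.  The default
estimator is the fixed-effects fit; random intercepts (stratum nested in
individual, crossed group) are available behind ``fit(method="mixed")``
via a Laplace approximation.  Scoring drops the intercept (and any random
effects), as is standard for exponential RSFs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
import pandas as pd
from scipy import stats

from .design import ScalingParams
from .raster import Raster

TEMP_PLACEHOLDER = "temp"
TEMP_COLUMNS = {"max_daily": "t_max_daily", "hourly": "t_hourly"}


def term_name(term) -> str:
    """Canonical name: products joined by ':', squares rendered as '^2'."""
    from collections import Counter

    parts = []
    for var, power in sorted(Counter(term).items()):
        parts.append(f"{var}^{power}" if power > 1 else var)
    return ":".join(parts)


@dataclass(frozen=True)
class ModelSpec:
    """Term list plus the temperature-metric hypothesis and random flags.

    Terms are tuples of covariate names multiplied on the standardized
    scale; a repeated name is a polynomial term (``("ndvi", "ndvi")`` is
    NDVI squared).  The placeholder ``"temp"`` resolves to the chosen
    temperature metric so the max-daily and hourly hypotheses share one
    structure.
    """

    terms: tuple
    temperature: str | None = "max_daily"  # "max_daily" | "hourly" | None
    random_effects: tuple = ()  # column names used as intercept factors

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(tuple(t) for t in self.terms))
        if self.temperature is not None and self.temperature not in TEMP_COLUMNS:
            raise ValueError("temperature must be 'max_daily', 'hourly' or None")
        # marginality: every interaction's parents must be present
        names = {term_name(t) for t in self.terms}
        for t in self.terms:
            if len(set(t)) > 1:
                for v in set(t):
                    if (v,) not in [tuple(x) for x in self.terms]:
                        raise ValueError(f"interaction {term_name(t)} lacks main effect {v}")
        if len(names) != len(self.terms):
            raise ValueError("duplicate terms in spec")

    def resolved_terms(self):
        """Terms with the temperature placeholder mapped to its column."""
        col = TEMP_COLUMNS.get(self.temperature)
        out = []
        for t in self.terms:
            if TEMP_PLACEHOLDER in t and col is None:
                raise ValueError("spec uses a temperature term but no metric is set")
            out.append(tuple(col if v == TEMP_PLACEHOLDER else v for v in t))
        return out

    @property
    def term_names(self):
        return [term_name(t) for t in self.resolved_terms()]

    @property
    def variables(self):
        """Unique underlying covariates, after metric resolution."""
        seen = []
        for t in self.resolved_terms():
            for v in t:
                if v not in seen:
                    seen.append(v)
        return seen

    def with_temperature(self, metric: str) -> "ModelSpec":
        return _dc_replace(self, temperature=metric)

    def drop_term(self, term) -> "ModelSpec":
        terms = tuple(t for t in self.terms if tuple(t) != tuple(term))
        return _dc_replace(self, terms=terms)

    def removable_terms(self):
        """Terms not contained in any higher-order term (marginality)."""
        from collections import Counter

        out = []
        for t in self.terms:
            ct = Counter(t)
            blocked = False
            for o in self.terms:
                if tuple(o) == tuple(t):
                    continue
                co = Counter(o)
                if all(co[k] >= v for k, v in ct.items()):
                    blocked = True
                    break
            if not blocked:
                out.append(tuple(t))
        return out

    @classmethod
    def full_structure(cls, temperature="max_daily", random_effects=()):
        """The a-priori full model: mains + quadratics + ecological interactions."""
        mains = [
            "temp",
            "ndvi",
            "slope",
            "cos_aspect",
            "log_dist_trail",
            "dist_safe",
            "group_size",
            "cos_wind_dir",
            "wind_speed",
            "julian_day",
            "solar",
        ]
        terms = [(m,) for m in mains]
        terms += [(m, m) for m in mains if m != "solar"]
        terms += [
            ("log_dist_trail", "group_size"),
            ("dist_safe", "group_size"),
            ("temp", "ndvi"),
            ("cos_aspect", "cos_wind_dir"),
            ("cos_aspect", "wind_speed"),
            ("cos_wind_dir", "wind_speed"),
            ("temp", "julian_day"),
            ("ndvi", "julian_day"),
            ("slope", "julian_day"),
            ("cos_aspect", "julian_day"),
            ("log_dist_trail", "julian_day"),
            ("dist_safe", "julian_day"),
            ("cos_aspect", "cos_wind_dir", "wind_speed"),
        ]
        return cls(tuple(terms), temperature=temperature, random_effects=tuple(random_effects))


def build_design(spec: ModelSpec, table: pd.DataFrame, intercept: bool = True):
    """Design matrix of term products from the ``z_``-prefixed columns."""
    cols, names = [], []
    if intercept:
        cols.append(np.ones(len(table)))
        names.append("intercept")
    for t in spec.resolved_terms():
        col = np.ones(len(table))
        for v in t:
            zc = f"z_{v}"
            if zc not in table.columns:
                raise KeyError(f"missing standardized column {zc!r} required by term {term_name(t)}")
            col = col * table[zc].to_numpy(float)
        cols.append(col)
        names.append(term_name(t))
    return np.column_stack(cols), names


def bernoulli_loglike(y, X, params):
    """Plain Bernoulli log-likelihood of a logistic linear predictor."""
    eta = X @ np.asarray(params, float)
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


class RSFModel:
    """Used/available logistic model over a standardized stratified table.

    Parameters
    ----------
    table : DataFrame with a ``case`` column (1 used / 0 available) and a
        ``z_<name>`` column per covariate the spec references.
    spec : the term structure and temperature hypothesis.
    scaling : the ScalingParams that produced the ``z_`` columns; carried
        into the results for projection-time reuse.
    """

    def __init__(self, table: pd.DataFrame, spec: ModelSpec, scaling: ScalingParams | None = None):
        if "case" not in table.columns:
            raise ValueError("table needs a 'case' column (1 used / 0 available)")
        self.table = table.reset_index(drop=True)
        self.spec = spec
        self.scaling = scaling
        self.endog = self.table["case"].to_numpy(float)
        self.exog, self.exog_names = build_design(spec, self.table)
        sds = self.exog[:, 1:].std(axis=0)
        if np.any(sds == 0):
            offending = [n for n, s in zip(self.exog_names[1:], sds) if s == 0]
            raise ValueError(f"constant column(s) make the fit inestimable: {offending}")

    @classmethod
    def from_dataframe(cls, table, spec, scaling=None):
        return cls(table, spec, scaling)

    def loglike(self, params) -> float:
        return bernoulli_loglike(self.endog, self.exog, params)

    def fit(self, method: str = "fixed", gtol: float = 1e-8, maxiter: int = 500) -> "RSFResults":
        if method == "fixed" or not self.spec.random_effects:
            return self._fit_fixed(gtol=gtol, maxiter=maxiter)
        if method == "mixed":
            return self._fit_mixed()
        raise ValueError("method must be 'fixed' or 'mixed'")

    def _fit_fixed(self, gtol=1e-8, maxiter=500) -> "RSFResults":
        import statsmodels.api as sm

        model = sm.Logit(self.endog, self.exog)
        try:
            res = model.fit(method="newton", maxiter=maxiter, tol=1e-10, disp=False)
        except Exception:
            res = model.fit(method="lbfgs", maxiter=5 * maxiter, pgtol=gtol, disp=False)
        if not res.mle_retvals.get("converged", True):
            raise RuntimeError(
                "logistic fit did not converge; check for separation in terms "
                + ", ".join(self.exog_names[1:])
            )
        params = pd.Series(res.params, index=self.exog_names)
        bse = pd.Series(res.bse, index=self.exog_names)
        variances = {f: 0.0 for f in self.spec.random_effects}
        return RSFResults(
            model=self,
            params=params,
            bse=bse,
            llf=float(res.llf),
            nobs=int(res.nobs),
            random_variances=variances,
            method="fixed",
            cov_params=np.asarray(res.cov_params()),
        )

    def _fit_mixed(self) -> "RSFResults":
        from .mixedlogit import fit_mixed_logit

        codes = {}
        for f in self.spec.random_effects:
            if f not in self.table.columns:
                raise KeyError(f"random-effect factor column {f!r} missing from table")
            codes[f] = self.table[f].to_numpy()
        out = fit_mixed_logit(self.endog, self.exog, codes)
        if all(v == 0.0 for v in out["sigma2"].values()):
            # spec'd degeneracy path: no random-effect contribution detected
            res = self._fit_fixed()
            res.random_variances = {f: 0.0 for f in self.spec.random_effects}
            return res
        params = pd.Series(out["beta"], index=self.exog_names)
        bse = pd.Series(out["se"], index=self.exog_names)
        return RSFResults(
            model=self,
            params=params,
            bse=bse,
            llf=out["llf"],
            nobs=len(self.endog),
            random_variances=out["sigma2"],
            method="mixed",
            cov_params=out["cov"],
            extra_df=len(codes),
        )


@dataclass
class RSFResults:
    """Fitted coefficients, uncertainty and diagnostics of one RSF."""

    model: RSFModel | None
    params: pd.Series
    bse: pd.Series
    llf: float
    nobs: int
    random_variances: dict = field(default_factory=dict)
    method: str = "fixed"
    cov_params: np.ndarray | None = None
    extra_df: int = 0  # variance components counted in the AIC

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    @property
    def scaling(self) -> ScalingParams | None:
        return self.model.scaling

    @property
    def df_model(self) -> int:
        return len(self.params) + self.extra_df

    @property
    def aic(self) -> float:
        return 2.0 * self.df_model - 2.0 * self.llf

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.zvalues)), index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        zc = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - zc * self.bse, "upper": self.params + zc * self.bse}
        )

    def r2_glmm(self):
        """Latent-scale (marginal, conditional) R^2 for the binomial-logit model.

        marginal = var(fixed predictor) / (var(fixed) + sum(random var) + pi^2/3);
        the conditional version adds the random-intercept variances to the
        numerator.  With zero random variance the two coincide.
        """
        X = self.model.exog[:, 1:]
        beta = self.params.to_numpy()[1:]
        var_f = float(np.var(X @ beta))
        var_r = float(sum(self.random_variances.values()))
        denom = var_f + var_r + np.pi**2 / 3.0
        return var_f / denom, (var_f + var_r) / denom

    def score(self, z: pd.DataFrame | dict) -> np.ndarray:
        """RSF score w = exp(sum beta_i z-term_i); intercept dropped."""
        if isinstance(z, dict):
            z = pd.DataFrame({k: np.atleast_1d(v) for k, v in z.items()})
        X, names = build_design(self.spec, z, intercept=False)
        beta = self.params.reindex(names).to_numpy()
        return np.exp(X @ beta)

    def score_raster(self, stack, context: dict, temp_raster: Raster | None = None) -> Raster:
        """Evaluate the RSF per pixel.

        Pixel covariates come from the stack, standardized with the fit's
        ScalingParams; ``context`` supplies raw scalars (julian_day,
        group_size, wind...) shared across pixels; the temperature layer
        comes from ``temp_raster`` (already in deg C).
        """
        if self.scaling is None:
            raise ValueError("results carry no ScalingParams; cannot standardize rasters")
        layer_map = {
            "elevation": "dem",
            "slope": "slope",
            "cos_aspect": "cos_aspect",
            "ruggedness": "ruggedness",
            "ndvi": "ndvi",
            "log_dist_trail": "log_dist_trail",
            "dist_safe": "dist_safe",
        }
        valid = stack.valid
        temp_col = TEMP_COLUMNS.get(self.spec.temperature)
        z = {}
        for var in self.spec.variables:
            if var == temp_col and temp_raster is not None:
                raw = temp_raster.data[valid]
            elif var in layer_map and layer_map[var] in stack:
                raw = stack[layer_map[var]][valid]
            elif var in context:
                raw = np.full(int(valid.sum()), float(context[var]))
            else:
                raise KeyError(f"no source for covariate {var!r}: provide it in context")
            z[f"z_{var}"] = self.scaling.transform(var, raw)
        w = self.score(pd.DataFrame(z))
        out = np.full(valid.shape, stack.nodata)
        out[valid] = w
        return Raster(out, stack.georef, stack.nodata)

    def coefficient_table(self) -> pd.DataFrame:
        """Per-term beta, SE, z, p — the published coefficient-table layout."""
        keep = [n for n in self.params.index if n != "intercept"]
        return pd.DataFrame(
            {
                "beta": self.params[keep],
                "SE": self.bse[keep],
                "z": self.zvalues[keep],
                "p": self.pvalues[keep],
            }
        )

    def summary(self) -> str:
        m, c = self.r2_glmm()
        lines = [
            "Resource selection function (used/available logistic fit)",
            f"  method: {self.method}    nobs: {self.nobs}",
            f"  logLik: {self.llf:.3f}    AIC: {self.aic:.3f}",
            f"  marginal R2: {m:.3f}    conditional R2: {c:.3f}",
        ]
        for f, v in self.random_variances.items():
            lines.append(f"  random intercept var({f}): {v:.4g}")
        lines.append("")
        tbl = pd.concat(
            [self.params, self.bse, self.zvalues, self.pvalues], axis=1,
            keys=["beta", "SE", "z", "p"],
        )
        lines.append(tbl.to_string(float_format=lambda v: f"{v: .5f}"))
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        obj = {
            "terms": [list(t) for t in self.spec.terms],
            "temperature": self.spec.temperature,
            "random_effects": list(self.spec.random_effects),
            "params": {k: float(v) for k, v in self.params.items()},
            "bse": {k: float(v) for k, v in self.bse.items()},
            "llf": self.llf,
            "aic": self.aic,
            "nobs": self.nobs,
            "method": self.method,
            "random_variances": self.random_variances,
            "scaling": self.scaling.to_dict() if self.scaling else None,
        }
        text = json.dumps(obj, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_coefficients(
        cls, spec: ModelSpec, params: pd.Series, scaling: ScalingParams | None = None,
        bse: pd.Series | None = None,
    ) -> "RSFResults":
        """Scoring-only results from an externally supplied coefficient table."""
        shell = RSFModel.__new__(RSFModel)
        shell.spec = spec
        shell.scaling = scaling
        shell.table = None
        shell.exog = None
        if "intercept" not in params.index:
            params = pd.concat([pd.Series({"intercept": 0.0}), params])
        params = params.reindex(["intercept"] + spec.term_names)
        if params.isna().any():
            missing = params.index[params.isna()].tolist()
            raise ValueError(f"coefficient table lacks terms: {missing}")
        if bse is None:
            bse = pd.Series(np.nan, index=params.index)
        else:
            bse = bse.reindex(params.index)
        return cls(model=shell, params=params, bse=bse, llf=np.nan, nobs=0)

    @classmethod
    def from_json(cls, path) -> "RSFResults":
        with open(path) as fh:
            obj = json.load(fh)
        spec = ModelSpec(
            tuple(tuple(t) for t in obj["terms"]),
            temperature=obj["temperature"],
            random_effects=tuple(obj["random_effects"]),
        )
        scaling = ScalingParams.from_dict(obj["scaling"]) if obj.get("scaling") else None
        res = cls.from_coefficients(
            spec,
            pd.Series(obj["params"]),
            scaling,
            bse=pd.Series(obj["bse"]),
        )
        res.llf = obj["llf"]
        res.nobs = obj["nobs"]
        res.method = obj["method"]
        res.random_variances = obj["random_variances"]
        return res


def fit_rsf(spec: ModelSpec, table: pd.DataFrame, scaling=None, method="fixed") -> RSFResults:
    """Convenience wrapper: build the model and fit."""
    return RSFModel(table, spec, scaling).fit(method=method)


def compare_aic(fit_maxdaily: RSFResults, fit_hourly: RSFResults) -> float:
    """AIC(hourly) - AIC(max-daily): positive favours the max-daily hypothesis."""
    if fit_maxdaily.nobs != fit_hourly.nobs:
        raise ValueError("fits must use the same rows to compare AIC")
    return fit_hourly.aic - fit_maxdaily.aic
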