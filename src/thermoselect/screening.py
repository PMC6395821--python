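"""Covariate-reduction protocol: collinearity, multicollinearity, step-AIC.

Mirrors the standard habitat-modelling screening recipe: (i) Pearson
pairwise screen at |r| = 0.7, keeping the member of each violating pair
that stays informative conditional on the other (joint logistic Wald |z|),
with per-covariate random-forest OOB AUC (500 trees by default) as the
reported importance ranking and a domain-override escape hatch; (ii) a VIF
loop at threshold 3 dropping the least important offender; (iii)
deterministic greedy backward AIC elimination under a marginality
constraint.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ScreeningReport:
    correlation: pd.DataFrame
    vif: pd.Series
    dropped: list  # (name, reason)
    retained: list
    importance: pd.Series
    n_trees: int
    r_threshold: float
    vif_threshold: float

    def to_json(self, path=None) -> str:
        obj = {
            "retained": self.retained,
            "dropped": [[n, r] for n, r in self.dropped],
            "importance": {k: float(v) for k, v in self.importance.items()},
            "vif": {k: float(v) for k, v in self.vif.items()},
            "thresholds": {"r": self.r_threshold, "vif": self.vif_threshold},
            "n_trees": self.n_trees,
        }
        text = json.dumps(obj, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def log_text(self) -> str:
        lines = [f"screen: |r| <= {self.r_threshold}, VIF <= {self.vif_threshold}"]
        for name, reason in self.dropped:
            lines.append(f"  dropped {name}: {reason}")
        lines.append(f"  retained: {', '.join(self.retained)}")
        return "\n".join(lines)


def _rf_importance(table: pd.DataFrame, covariates, n_trees, seed) -> pd.Series:
    """Predictive importance of each covariate for the case/control label.

    Importance is the out-of-bag AUC of a random forest grown on the
    single covariate (n_trees trees).  Scoring covariates one at a time is
    deliberate: joint-forest permutation importance cannot separate a
    covariate from a strongly collinear partner, because the ensemble
    substitutes one for the other — precisely the situation this ranking
    has to adjudicate.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.metrics import roc_auc_score

    y = table["case"].to_numpy(int)
    out = {}
    for cov in covariates:
        rf = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed, n_jobs=1,
            min_samples_leaf=20, oob_score=True, bootstrap=True,
        )
        rf.fit(table[[cov]].to_numpy(float), y)
        out[cov] = roc_auc_score(y, rf.oob_decision_function_[:, 1])
    return pd.Series(out)


def _conditional_z(table: pd.DataFrame, a: str, b: str) -> tuple:
    """Wald |z| of each pair member in a joint logistic fit on the label."""
    import statsmodels.api as sm

    xa = table[a].to_numpy(float)
    xb = table[b].to_numpy(float)
    X = np.column_stack(
        [np.ones(len(table)), (xa - xa.mean()) / xa.std(), (xb - xb.mean()) / xb.std()]
    )
    res = sm.Logit(table["case"].to_numpy(int), X).fit(disp=False, maxiter=200)
    z = np.abs(res.params[1:] / res.bse[1:])
    return float(z[0]), float(z[1])


def _vif(table: pd.DataFrame, covariates) -> pd.Series:
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    X = np.column_stack([np.ones(len(table))] + [table[c].to_numpy(float) for c in covariates])
    return pd.Series(
        [variance_inflation_factor(X, i + 1) for i in range(len(covariates))],
        index=covariates,
    )


def collinearity_screen(
    table: pd.DataFrame,
    covariates,
    r_threshold: float = 0.7,
    vif_threshold: float = 3.0,
    n_trees: int = 500,
    seed: int = 0,
    keep_overrides: dict | None = None,
) -> ScreeningReport:
    """Reduce a covariate set until all |r| <= r_threshold and VIF <= vif_threshold.

    ``keep_overrides`` maps a covariate to the partner it beats regardless
    of importance rank (the ecological-relevance escape hatch, e.g. keep
    NDVI over elevation).  Ties in importance break alphabetically: the
    alphabetically later name is dropped.
    """
    covariates = list(covariates)
    keep_overrides = keep_overrides or {}
    dropped = []

    # constant covariates can never be standardized or ranked
    for c in list(covariates):
        if table[c].std() == 0:
            covariates.remove(c)
            dropped.append((c, "zero variance"))

    if len(covariates) < 2:
        raise ValueError("need at least 2 non-constant covariates to screen")
    if table["case"].nunique() < 2:
        raise ValueError("table must contain both used and available rows")

    importance = _rf_importance(table, covariates, n_trees, seed)

    def pick_loser(a, b):
        for keeper, beaten in keep_overrides.items():
            if {a, b} == {keeper, beaten}:
                return beaten, f"collinear with {keeper} (domain override)"
        # conditional comparison: in a joint fit the member that carries
        # the information keeps its Wald |z|; the shadow's collapses.
        # Far more stable for near-duplicates than marginal importance.
        try:
            za, zb = _conditional_z(table, a, b)
        except Exception:  # separation/singularity: fall back to importance
            za, zb = importance[a], importance[b]
        if za == zb:
            loser = max(a, b)
        else:
            loser = a if za < zb else b
        winner = b if loser == a else a
        return loser, f"collinear with {winner} (less informative conditionally)"

    while True:
        corr = table[covariates].corr(method="pearson")
        tri = corr.where(np.triu(np.ones_like(corr, dtype=bool), k=1))
        worst = tri.abs().stack().sort_values(ascending=False)
        if worst.empty or worst.iloc[0] <= r_threshold:
            break
        a, b = worst.index[0]
        loser, reason = pick_loser(a, b)
        covariates.remove(loser)
        dropped.append((loser, f"|r|={worst.iloc[0]:.3f} {reason}"))
        if len(covariates) < 2:
            break

    while len(covariates) >= 2:
        vif = _vif(table, covariates)
        if vif.max() <= vif_threshold:
            break
        over = vif[vif > vif_threshold].index
        loser = importance[over].idxmin()
        dropped.append((loser, f"VIF={vif[loser]:.2f} above {vif_threshold} (lowest importance)"))
        covariates.remove(loser)

    final_corr = table[covariates].corr(method="pearson")
    final_vif = _vif(table, covariates) if len(covariates) >= 2 else pd.Series(1.0, index=covariates)
    report = ScreeningReport(
        correlation=final_corr,
        vif=final_vif,
        dropped=dropped,
        retained=covariates,
        importance=importance,
        n_trees=n_trees,
        r_threshold=r_threshold,
        vif_threshold=vif_threshold,
    )
    logger.info(report.log_text())
    return report


def step_aic_prune(spec, table, scaling=None, method: str = "fixed"):
    """Greedy backward AIC elimination respecting marginality.

    At each step the removable term (one not nested in any retained
    higher-order term) whose removal lowers the AIC most is dropped; the
    procedure stops when no removal improves AIC.  Candidate fits that
    fail to converge are skipped and logged.  Returns (pruned spec, log).
    """
    from .rsf import RSFModel, term_name

    log = []
    current = spec
    current_aic = RSFModel(table, current, scaling).fit(method=method).aic
    while True:
        best_term, best_aic = None, current_aic
        for t in current.removable_terms():
            cand = current.drop_term(t)
            if not cand.terms:
                continue
            try:
                aic = RSFModel(table, cand, scaling).fit(method=method).aic
            except Exception as exc:  # noqa: BLE001 - skipped per protocol
                log.append(f"candidate drop {term_name(t)} failed: {exc}")
                continue
            if aic < best_aic - 1e-9:
                best_term, best_aic = t, aic
        if best_term is None:
            break
        log.append(
            f"dropped {term_name(best_term)}: AIC {current_aic:.3f} -> {best_aic:.3f}"
        )
        current, current_aic = current.drop_term(best_term), best_aic
    return current, log
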