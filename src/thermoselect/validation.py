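"""k-fold cross-validation for presence/available designs (Boyce method).

Strata — one used point with its available points — are partitioned into k
folds.  For each fold the model is refitted on the other k-1 folds, the
withheld fold is scored, scores are binned (default: deciles of the
training folds' available-point scores, i.e. equal-availability bins), and
the area-adjusted frequency of withheld used points per bin is rank-
correlated (Spearman, average ranks for ties) with the bin order.  Strong
positive correlation means used points concentrate in high-score bins.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def area_adjusted_frequency(used_scores, available_scores, bin_edges):
    """Area-adjusted frequency per score bin.

    For bin i, AAF_i is (used count / available count) normalized to sum 1
    over bins with availability.  Bins are half-open [lo, hi), the last
    closed.  Bins with no available points get NaN, are flagged in the
    returned mask and excluded from the normalization.

    Returns (aaf, used_counts, available_counts, valid_mask).
    """
    used_scores = np.asarray(used_scores, float)
    available_scores = np.asarray(available_scores, float)
    edges = np.asarray(bin_edges, float)
    n_bins = len(edges) - 1

    def counts(x):
        idx = np.digitize(x, edges, right=False) - 1
        idx[np.isclose(x, edges[-1])] = n_bins - 1  # last bin closed
        idx = idx[(idx >= 0) & (idx < n_bins)]
        return np.bincount(idx, minlength=n_bins).astype(float)

    used = counts(used_scores)
    avail = counts(available_scores)
    valid = avail > 0
    if not valid.all():
        logger.warning("%d empty-availability bins excluded from AAF", int((~valid).sum()))
    ratio = np.full(n_bins, np.nan)
    ratio[valid] = used[valid] / avail[valid]
    total = ratio[valid].sum()
    aaf = np.full(n_bins, np.nan)
    if total > 0:
        aaf[valid] = ratio[valid] / total
    else:
        aaf[valid] = 0.0
    return aaf, used, avail, valid


@dataclass
class ValidationResult:
    fold_rho: list
    fold_aaf: list  # one frequency vector per fold
    fold_edges: list
    k: int
    n_bins: int
    seed: int
    fold_strata: list = field(default_factory=list)

    @property
    def mean_rho(self) -> float:
        return float(np.mean(self.fold_rho))

    def to_json(self, path=None) -> str:
        obj = {
            "k": self.k,
            "n_bins": self.n_bins,
            "seed": self.seed,
            "fold_rho": [float(r) for r in self.fold_rho],
            "mean_rho": self.mean_rho,
            "fold_aaf": [[None if np.isnan(v) else float(v) for v in a] for a in self.fold_aaf],
        }
        text = json.dumps(obj, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def plot(self, path):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        for i, aaf in enumerate(self.fold_aaf):
            ax.plot(
                np.arange(1, len(aaf) + 1), aaf, marker="o",
                label=f"fold {i + 1} (rho={self.fold_rho[i]:.3f})",
            )
        ax.set_xlabel("RSF score bin (rank)")
        ax.set_ylabel("area-adjusted frequency")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _decile_edges(scores, n_bins):
    edges = np.quantile(scores, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    # guard against duplicate quantiles in heavy-tailed scores
    for i in range(1, len(edges)):
        if edges[i] <= edges[i - 1]:
            edges[i] = np.nextafter(edges[i - 1], np.inf)
    return edges


def spearman_aaf(aaf):
    """Spearman correlation between AAF and bin rank over occupied bins."""
    aaf = np.asarray(aaf, float)
    ok = ~np.isnan(aaf)
    ranks = np.arange(1, len(aaf) + 1)[ok]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(ranks, aaf[ok]).statistic
    return float(rho)


def kfold_boyce(
    spec,
    table: pd.DataFrame,
    k: int = 5,
    n_bins: int = 10,
    seed: int = 0,
    scaling=None,
    by: str = "stratum",
    binning: str = "available_deciles",
    method: str = "fixed",
) -> ValidationResult:
    """Area-adjusted k-fold validation of an RSF specification.

    Folds partition strata (or individuals, ``by='individual'``) so a used
    point never shares a fold boundary with its availables.  ``binning``
    is 'available_deciles' (default) or 'fixed_width'.
    """
    from .rsf import RSFModel

    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    key = "stratum_id" if by == "stratum" else "individual_id"
    units = table[key].unique()
    rng.shuffle(units)
    folds = np.array_split(units, k)

    fold_rho, fold_aaf, fold_edges, fold_strata = [], [], [], []
    for fi, test_units in enumerate(folds):
        test_mask = table[key].isin(test_units)
        train, test = table[~test_mask], table[test_mask]
        fit = RSFModel(train, spec, scaling).fit(method=method)
        train_avail = fit.score(train[train["case"] == 0])
        test_used = fit.score(test[test["case"] == 1])
        test_avail = fit.score(test[test["case"] == 0])
        if binning == "available_deciles":
            edges = _decile_edges(train_avail, n_bins)
        elif binning == "fixed_width":
            lo, hi = train_avail.min(), train_avail.max()
            edges = np.linspace(lo, hi, n_bins + 1)
            edges[0], edges[-1] = -np.inf, np.inf
        else:
            raise ValueError("binning must be 'available_deciles' or 'fixed_width'")
        if len(test_used) < n_bins:
            warnings.warn(
                f"fold {fi + 1} has fewer used points ({len(test_used)}) than bins",
                stacklevel=2,
            )
        aaf, _, _, _ = area_adjusted_frequency(test_used, test_avail, edges)
        fold_rho.append(spearman_aaf(aaf))
        fold_aaf.append(aaf)
        fold_edges.append(edges)
        fold_strata.append(list(test_units))
    return ValidationResult(fold_rho, fold_aaf, fold_edges, k, n_bins, seed, fold_strata)
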