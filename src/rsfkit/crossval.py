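"""k-fold cross-validation of fitted RSFs (area-adjusted frequency ranks).

The procedure follows the standard Boyce-style validation adapted to
use-availability mixed models: rows are randomly binned into k classes
stratified by response; for each held-out class the model is refit on
the remainder and held-out rows are scored by the fixed-effect linear
predictor (random effects at their population mean of zero, since
held-out groups may be unseen). Held-out scores are cut into ``n_bins``
equal-available-count bins (edges from the held-out available-score
quantiles; an equal-width variant is available behind a flag), the
area-adjusted frequency of each bin is the held-out used share divided
by the held-out available share, and the Spearman rank correlation
between bin rank and that frequency summarizes predictive success.
Per-fold p-values are combined with Fisher's method.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .glmm import ModelSpec, build_model_matrix, fit_glmm

__all__ = ["CVResult", "kfold_crossvalidate", "hourly_crossvalidate", "area_adjusted_frequencies"]


@dataclasses.dataclass
class CVResult:
    """Per-fold and mean Spearman rho between bin rank and area-adjusted
    frequency."""

    fold_rhos: list[float]
    mean_rho: float
    rho_range: tuple[float, float]
    combined_p: float
    n_bins: int
    n_folds: int
    bin_tables: list[pd.DataFrame]
    flags: list[str]

    def to_json(self, path=None) -> str:
        import json

        s = json.dumps(
            {
                "mean_rho": self.mean_rho,
                "rho_range": list(self.rho_range),
                "fold_rhos": self.fold_rhos,
                "combined_p": self.combined_p,
                "n_bins": self.n_bins,
                "n_folds": self.n_folds,
                "flags": self.flags,
            },
            indent=1,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def area_adjusted_frequencies(
    scores: np.ndarray,
    response: np.ndarray,
    n_bins: int = 10,
    equal_width: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Bin held-out rows by RSF score and compute used/available shares.

    Bin edges come from the held-out *available* scores (equal-count
    quantiles by default). Degenerate edges (ties) merge bins, which is
    flagged.
    """
    avail_scores = scores[response == 0]
    if len(avail_scores) == 0:
        raise ValueError("no available rows in the held-out fold")
    if equal_width:
        edges = np.linspace(avail_scores.min(), avail_scores.max(), n_bins + 1)
    else:
        edges = np.quantile(avail_scores, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    flags = []
    if len(edges) - 1 < n_bins:
        flags.append(f"merged ties: {n_bins} -> {len(edges) - 1} bins")
    idx = np.clip(np.searchsorted(edges, scores, side="right") - 1, 0, len(edges) - 2)
    rows = []
    n_used = max((response == 1).sum(), 1)
    n_avail = max((response == 0).sum(), 1)
    for b in range(len(edges) - 1):
        sel = idx == b
        used_share = (response[sel] == 1).sum() / n_used
        avail_share = (response[sel] == 0).sum() / n_avail
        rows.append(
            {
                "bin": b + 1,
                "used_share": used_share,
                "avail_share": avail_share,
                "area_adjusted_freq": used_share / avail_share if avail_share > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows), flags


def kfold_crossvalidate(
    table: pd.DataFrame,
    spec: ModelSpec,
    k: int = 10,
    n_bins: int = 10,
    seed: int = 0,
    equal_width: bool = False,
    method: str = "laplace",
) -> CVResult:
    """k-fold cross-validation of one model structure on one table."""
    if k < 2:
        raise ValueError("k must be at least 2")
    y = table["response"].to_numpy()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rhos, pvals, tables, flags = [], [], [], []
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        train = table.iloc[train_idx]
        test = table.iloc[test_idx]
        fit = fit_glmm(build_model_matrix(train, spec), method=method)
        test_design = build_model_matrix(test, spec, scaling=fit.scaling)
        scores = test_design.X @ fit.coefficients["estimate"].to_numpy()
        bins, fl = area_adjusted_frequencies(
            scores, test_design.y, n_bins=n_bins, equal_width=equal_width
        )
        flags.extend(fl)
        rho, p = stats.spearmanr(bins["bin"], bins["area_adjusted_freq"])
        rhos.append(float(rho))
        pvals.append(float(p) if np.isfinite(p) else 1.0)
        tables.append(bins)
    combined = stats.combine_pvalues(np.clip(pvals, 1e-300, 1.0), method="fisher").pvalue
    return CVResult(
        fold_rhos=rhos,
        mean_rho=float(np.mean(rhos)),
        rho_range=(float(np.min(rhos)), float(np.max(rhos))),
        combined_p=float(combined),
        n_bins=n_bins,
        n_folds=k,
        bin_tables=tables,
        flags=flags,
    )


def hourly_crossvalidate(
    hourly_tables: Mapping[int, pd.DataFrame],
    spec: ModelSpec,
    k: int = 10,
    n_bins: int = 10,
    seed: int = 0,
    method: str = "laplace",
) -> tuple[CVResult, pd.DataFrame]:
    """Cross-validate each hourly model and average across the 24 hours.

    Returns the across-hour summary (mean of the per-hour mean rhos,
    their range, Fisher-combined p) plus a per-hour frame.
    """
    per_hour = []
    for h in sorted(hourly_tables):
        cv = kfold_crossvalidate(
            hourly_tables[h], spec, k=k, n_bins=n_bins, seed=seed + h, method=method
        )
        per_hour.append(
            {"hour": h, "mean_rho": cv.mean_rho, "combined_p": cv.combined_p}
        )
    df = pd.DataFrame(per_hour)
    combined = stats.combine_pvalues(
        np.clip(df["combined_p"], 1e-300, 1.0), method="fisher"
    ).pvalue
    summary = CVResult(
        fold_rhos=list(df["mean_rho"]),
        mean_rho=float(df["mean_rho"].mean()),
        rho_range=(float(df["mean_rho"].min()), float(df["mean_rho"].max())),
        combined_p=float(combined),
        n_bins=n_bins,
        n_folds=k,
        bin_tables=[],
        flags=[],
    )
    return summary, df
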