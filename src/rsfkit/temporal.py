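"""Diel (raised-cosine) and lunar analyses of hourly selection coefficients.

The diel analysis fits the selected home-range model structure
separately to each of the 24 hourly use-availability tables and
regresses each covariate's hourly coefficient series on fixed-phase
raised-cosine templates:

* single raised cosine, peak at local noon, trough at midnight:
  ``r1(h) = (1 + cos(2 pi (h - 12) / 24)) / 2``;
* double raised cosine, peaks at 06:00 and 18:00 (dawn/dusk):
  ``r2(h) = (1 + cos(2 pi (h - 6) / 12)) / 2``.

Over a full 24-h cycle the two templates are orthogonal after centring
(first vs second harmonic), so a pure day-night signal does not load on
the dawn-dusk template and vice versa. The F statistic of the ordinary
least-squares regression (df 1, n-2) is invariant to affine transforms
of the template, so the "raised" 0..1 scaling is a readability choice
with no inferential effect.

The lunar analysis extracts a covariate x Moon interaction from a fitted
T/ST-structure model and predicts relative selection across the 0-100%
illumination range.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import FitResult, ModelSpec, build_model_matrix, fit_glmm

__all__ = [
    "single_raised_cosine",
    "double_raised_cosine",
    "raised_cosine_regression",
    "fit_hourly_models",
    "coefficient_series",
    "diel_analysis",
    "lunar_interaction",
    "RaisedCosineFit",
    "DielResult",
    "LunarEffect",
]


def single_raised_cosine(hours) -> np.ndarray:
    """Noon-peak template on [0, 1]: one cycle per day."""
    h = np.asarray(hours, dtype=float)
    return (1.0 + np.cos(2.0 * np.pi * (h - 12.0) / 24.0)) / 2.0


def double_raised_cosine(hours) -> np.ndarray:
    """Dawn/dusk template on [0, 1]: peaks at 06:00 and 18:00."""
    h = np.asarray(hours, dtype=float)
    return (1.0 + np.cos(2.0 * np.pi * (h - 6.0) / 12.0)) / 2.0


@dataclasses.dataclass
class RaisedCosineFit:
    template: str
    slope: float
    intercept: float
    F: float
    p: float
    df: tuple[int, int]
    r2: float
    fitted: np.ndarray


def raised_cosine_regression(
    series: Sequence[float],
    template: str = "single",
    hours: Sequence[int] | None = None,
    weights: Sequence[float] | None = None,
) -> RaisedCosineFit:
    """OLS regression of an hourly coefficient series on a diel template.

    At least 20 of the 24 hours must be present (pass ``hours`` for an
    incomplete series). ``weights`` enables variance-weighted least
    squares using the hourly within-model variances. A constant series
    returns F = 0, p = 1.
    """
    y = np.asarray(series, dtype=float)
    h = np.arange(24) if hours is None else np.asarray(hours, dtype=float)
    ok = np.isfinite(y)
    y, h = y[ok], h[ok]
    n = len(y)
    if n < 20:
        raise ValueError("need at least 20 hourly coefficients")
    if template == "single":
        r = single_raised_cosine(h)
    elif template == "double":
        r = double_raised_cosine(h)
    else:
        raise ValueError(f"unknown template {template!r}")
    w = np.ones(n) if weights is None else 1.0 / np.asarray(weights, dtype=float)[ok]
    sw = w.sum()
    rbar, ybar = (w * r).sum() / sw, (w * y).sum() / sw
    sxx = (w * (r - rbar) ** 2).sum()
    sxy = (w * (r - rbar) * (y - ybar)).sum()
    if sxx <= 0 or np.allclose(y, y[0]):
        return RaisedCosineFit(template, 0.0, float(y.mean()), 0.0, 1.0,
                               (1, n - 2), 0.0, np.full(n, y.mean()))
    slope = sxy / sxx
    intercept = ybar - slope * rbar
    fitted = intercept + slope * r
    rss = (w * (y - fitted) ** 2).sum()
    tss = (w * (y - ybar) ** 2).sum()
    if rss <= 1e-300:
        return RaisedCosineFit(template, float(slope), float(intercept), math.inf, 0.0,
                               (1, n - 2), 1.0, fitted)
    F = (tss - rss) / (rss / (n - 2))
    p = float(stats.f.sf(F, 1, n - 2))
    return RaisedCosineFit(template, float(slope), float(intercept), float(F), p,
                           (1, n - 2), float(1 - rss / tss), fitted)


def fit_hourly_models(
    hourly_tables: Mapping[int, pd.DataFrame],
    spec: ModelSpec,
    method: str = "laplace",
) -> dict[int, FitResult]:
    """Fit the selected model structure to each of the 24 hourly tables.

    Non-convergent hours are kept but flagged; downstream regressions
    drop them from the coefficient series.
    """
    fits = {}
    for h in sorted(hourly_tables):
        design = build_model_matrix(hourly_tables[h], spec)
        fits[h] = fit_glmm(design, method=method)
    return fits


def coefficient_series(
    fits: Mapping[int, FitResult], covariate: str, side: str = "inside"
) -> pd.DataFrame:
    """Hourly coefficient series for a covariate on one InOut side.

    Inside the protected core the selection coefficient is the covariate
    main effect; outside it is main effect + covariate:InOut interaction
    (variance from the joint covariance). Non-convergent hours yield NaN.
    """
    rows = []
    for h, fit in sorted(fits.items()):
        if not fit.converged:
            rows.append((h, np.nan, np.nan))
            continue
        terms = list(fit.coefficients.index)
        est = fit.coef(covariate)
        var = fit.se(covariate) ** 2
        inter = f"{covariate}:InOut"
        if side == "outside" and inter in terms:
            i, j = terms.index(covariate), terms.index(inter)
            est = est + fit.coef(inter)
            var = fit.vcov[i, i] + fit.vcov[j, j] + 2 * fit.vcov[i, j]
        rows.append((h, est, var))
    return pd.DataFrame(rows, columns=["hour", "estimate", "variance"])


@dataclasses.dataclass
class DielResult:
    """Raised-cosine diel tests for every covariate x InOut side."""

    series: dict[tuple[str, str], pd.DataFrame]
    tests: pd.DataFrame  # covariate, side, F/p for both templates
    hourly_aic: pd.Series

    def to_csv(self, path) -> None:
        self.tests.to_csv(path, index=False)


def diel_analysis(
    fits: Mapping[int, FitResult],
    covariates: Sequence[str] | None = None,
    weighted: bool = False,
) -> DielResult:
    """Run both raised-cosine regressions per covariate and InOut side."""
    any_fit = next(iter(fits.values()))
    covs = list(covariates or any_fit.spec.covariates)
    sides = ["inside", "outside"] if "InOut" in any_fit.spec.interactions else ["inside"]
    series, rows = {}, []
    for c in covs:
        for s in sides:
            sr = coefficient_series(fits, c, s)
            series[(c, s)] = sr
            ok = np.isfinite(sr["estimate"])
            kw = dict(hours=sr.loc[ok, "hour"].to_numpy())
            if weighted:
                kw["weights"] = sr.loc[ok, "variance"].to_numpy()
            f1 = raised_cosine_regression(sr.loc[ok, "estimate"], "single", **kw)
            f2 = raised_cosine_regression(sr.loc[ok, "estimate"], "double", **kw)
            rows.append(
                {
                    "covariate": c, "side": s,
                    "F_single": f1.F, "p_single": f1.p, "amp_single": f1.slope,
                    "F_double": f2.F, "p_double": f2.p, "amp_double": f2.slope,
                }
            )
    hourly_aic = pd.Series(
        {h: f.aic for h, f in fits.items() if f.converged}, name="AIC"
    )
    return DielResult(series=series, tests=pd.DataFrame(rows), hourly_aic=hourly_aic)


@dataclasses.dataclass
class LunarEffect:
    covariate: str
    estimate: float
    se: float
    z: float
    p: float
    curve: pd.DataFrame  # moon_pct x covariate grid of relative selection


def lunar_interaction(
    fit: FitResult, covariate: str, z_grid: np.ndarray | None = None
) -> LunarEffect:
    """Extract a covariate x Moon interaction and its prediction curve.

    The curve gives relative selection exp((b_cov + b_int * m) z) for
    moon illumination m = 0, 10, ..., 100% over a standardized covariate
    grid; at 0% it reduces to the main effect alone.
    """
    term = f"{covariate}:Moon"
    if term not in fit.coefficients.index:
        raise KeyError(f"model {fit.spec.name!r} has no {term} term")
    est, se = fit.coef(term), fit.se(term)
    z = est / se if se > 0 else 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    zg = np.linspace(-2, 2, 41) if z_grid is None else np.asarray(z_grid, float)
    b0 = fit.coef(covariate)
    curve = pd.DataFrame(
        {
            f"moon_{m}": np.exp(np.clip((b0 + est * m / 100.0) * zg, -700, 700))
            for m in range(0, 101, 10)
        },
        index=pd.Index(zg, name=f"{covariate}_z"),
    )
    return LunarEffect(covariate=covariate, estimate=float(est), se=float(se),
                       z=float(z), p=float(p), curve=curve)
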