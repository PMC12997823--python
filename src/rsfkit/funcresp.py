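"""Individual-level functional responses in habitat selection.

A functional response is a dependence of selection strength on
availability. It is tested here as the Pearson correlation, across
individuals, between landscape-level and home-range-level selection
ratios (mean covariate at used points / mean at available points) for
one covariate, separately for individuals whose ranges lie inside vs
outside the protected core. A negative correlation means individuals
that are more exposed to a feature at the landscape scale avoid it more
strongly within their home range.

Level definitions mirror the sampling design: an individual's
landscape-level "used" points are its share of the MCP random points
(home-range placement), its home-range-level "used" points are its
relocations, and home-range availability is restricted to its own MCP
points while the landscape availability pool is shared. Proximity to
water enters as raw distance, so a ratio above 1 reads "used points
farther from water than available".
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import COVARIATES

__all__ = ["selection_ratios", "functional_response_test", "functional_response_table"]


def _side_of(used: pd.DataFrame) -> pd.Series:
    """Inside/outside classification per individual: majority of its
    used rows relative to the protected core."""
    return (
        used.groupby("individual_id")["in_out"]
        .agg(lambda s: "inside" if (s == "inside").mean() >= 0.5 else "outside")
    )


def selection_ratios(
    landscape_table: pd.DataFrame,
    homerange_table: pd.DataFrame,
    min_used: int = 30,
) -> pd.DataFrame:
    """Per individual x covariate x level selection ratios.

    Ratio = mean covariate over used points / mean over available
    points; the landscape available pool is shared across individuals,
    home-range availability is the individual's own MCP points.
    Individuals with fewer than ``min_used`` used rows at either level
    are excluded with a warning.
    """
    sides = _side_of(homerange_table[homerange_table["response"] == 1])
    rows = []
    excluded = set()
    for level, table in (("landscape", landscape_table), ("homerange", homerange_table)):
        used = table[table["response"] == 1]
        avail = table[table["response"] == 0]
        for ind, grp in used.groupby("individual_id"):
            if len(grp) < min_used:
                excluded.add(str(ind))
                continue
            if level == "landscape":
                base = avail
            else:
                base = avail[avail["individual_id"] == ind]
            for cov in COVARIATES:
                denom = base[cov].mean()
                rows.append(
                    {
                        "individual_id": ind,
                        "covariate": cov,
                        "level": level,
                        "ratio": grp[cov].mean() / denom if denom != 0 else np.nan,
                        "side": sides.get(ind, "inside"),
                    }
                )
    if excluded:
        warnings.warn(
            f"excluded individuals with < {min_used} used rows: {sorted(excluded)}",
            RuntimeWarning,
        )
    out = pd.DataFrame(
        rows, columns=["individual_id", "covariate", "level", "ratio", "side"]
    )
    if out.empty:
        return out
    # keep only individuals present at both levels
    counts = out.groupby("individual_id")["level"].nunique()
    keep = counts[counts == 2].index
    return out[out["individual_id"].isin(keep)].reset_index(drop=True)


def functional_response_test(
    ratios: pd.DataFrame, covariate: str, side: str
) -> tuple[float, float]:
    """Pearson correlation between the two levels' ratios across individuals.

    Requires at least five individuals on the given side; raises on zero
    variance in either ratio vector.
    """
    sub = ratios[(ratios["covariate"] == covariate) & (ratios["side"] == side)]
    wide = sub.pivot(index="individual_id", columns="level", values="ratio").dropna()
    if len(wide) < 5:
        raise ValueError(
            f"need at least 5 individuals on side {side!r} (have {len(wide)})"
        )
    x = wide["landscape"].to_numpy()
    y = wide["homerange"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a selection-ratio vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def functional_response_table(ratios: pd.DataFrame) -> pd.DataFrame:
    """Correlation estimate and p per covariate x side (where testable)."""
    rows = []
    for side in ("outside", "inside"):
        for cov in COVARIATES:
            try:
                r, p = functional_response_test(ratios, cov, side)
            except ValueError:
                r, p = np.nan, np.nan
            rows.append({"covariate": cov, "side": side, "estimate": r, "p": p})
    return pd.DataFrame(rows)
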