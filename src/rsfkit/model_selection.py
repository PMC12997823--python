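"""Hypothesis-set construction, AIC ranking and the delta-AIC-ratio statistic.

The candidate set contrasts risk-coping strategies: forage maximization
(f), risk minimization (r) and their trade-off (fr), each generic (G),
spatially adjusted inside/outside the protected core (S), temporally
adjusted by lunar illumination (T) or both (ST), plus a woody-cover-only
null model ("0"). Temporal structures require the within-home-range
design, so the landscape level uses the first seven structures and the
home-range level all thirteen.

Support for a named set of hypothesis models is summarized by the
delta-AIC ratio: the mean delta-AIC across all hypothesis models divided
by the mean delta-AIC within the set. Values above 1 indicate
above-average support. The null model is excluded from both means; this
convention is pinned by a regression test that reproduces every ratio
printed for the published impala AIC table (including the null
reproduces none of them).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .glmm import FitResult, ModelSpec

__all__ = [
    "LANDSCAPE_MODELS",
    "HOMERANGE_MODELS",
    "MODEL_SETS",
    "model_set",
    "compare",
    "delta_aic_ratio",
    "all_set_ratios",
    "ModelComparison",
]

LANDSCAPE_MODELS = ("0", "Gf", "Gr", "Gfr", "Sf", "Sr", "Sfr")
HOMERANGE_MODELS = (
    "0", "Gf", "Gr", "Gfr", "Sf", "Sr", "Sfr",
    "Tf", "Tr", "Tfr", "STf", "STr", "STfr",
)

#: named model sets: prefix sets share a spatial/temporal structure,
#: suffix sets share a covariate block.
MODEL_SETS = ("G", "S", "T", "ST", "f", "r", "fr")


def model_set(level: str) -> list[ModelSpec]:
    """All candidate model structures for the given analysis level."""
    if level == "landscape":
        names = LANDSCAPE_MODELS
    elif level == "homerange":
        names = HOMERANGE_MODELS
    else:
        raise ValueError(f"unknown level {level!r}")
    return [ModelSpec.from_name(n, level) for n in names]


def set_members(set_name: str, available: Iterable[str]) -> list[str]:
    """Hypothesis models belonging to a named set, within those available."""
    if set_name not in MODEL_SETS:
        raise KeyError(f"unknown model set {set_name!r}")
    out = []
    for name in available:
        if name == "0":
            continue
        prefix = name.rstrip("fr")
        suffix = name[len(prefix):]
        if set_name in ("G", "S", "T", "ST"):
            if prefix == set_name:
                out.append(name)
        elif suffix == set_name:
            out.append(name)
    return out


@dataclasses.dataclass
class ModelComparison:
    """AIC ranking of one level's candidate set plus per-set support ratios."""

    level: str
    table: pd.DataFrame  # index: model name; columns: df, AIC, dAIC (+ tie flag)
    ratios: dict[str, float]
    best: str
    ties: list[str]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="model")

    def to_json(self, path=None) -> str:
        import json

        s = json.dumps(
            {
                "level": self.level,
                "best": self.best,
                "table": self.table.reset_index()
                .rename(columns={"index": "model"})
                .to_dict(orient="records"),
                "delta_aic_ratios": {k: round(v, 2) for k, v in self.ratios.items()},
            },
            indent=1,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def compare(fits: Sequence[FitResult], level: str = "homerange") -> ModelComparison:
    """Rank converged fits by AIC and compute every set's delta-AIC ratio.

    Non-converged fits are excluded with a warning. Ties on AIC are
    flagged and broken toward the model with fewer df.
    """
    usable = []
    for f in fits:
        if not f.converged:
            warnings.warn(
                f"excluding non-converged model {f.spec.name!r} from comparison",
                RuntimeWarning,
            )
            continue
        usable.append(f)
    if len(usable) < 2:
        raise ValueError("need at least two converged fits to compare")
    rows = pd.DataFrame(
        {
            "df": [f.df for f in usable],
            "AIC": [f.aic for f in usable],
        },
        index=[f.spec.name for f in usable],
    )
    return compare_from_aic(rows, level=level)


def compare_from_aic(table: pd.DataFrame, level: str = "homerange") -> ModelComparison:
    """Build a comparison from a frame with columns df, AIC (or dAIC)."""
    tab = table.copy()
    if "dAIC" not in tab.columns:
        tab["dAIC"] = tab["AIC"] - tab["AIC"].min()
    order = tab.sort_values(["dAIC", "df"]).index
    tab = tab.loc[order]
    best = tab.index[0]
    min_d = tab["dAIC"].iloc[0]
    ties = list(tab.index[np.isclose(tab["dAIC"], min_d)])
    ties = ties if len(ties) > 1 else []
    ratios = all_set_ratios(tab["dAIC"])
    return ModelComparison(level=level, table=tab, ratios=ratios, best=str(best), ties=ties)


def delta_aic_ratio(
    delta_aics: Mapping[str, float], set_names: Sequence[str] | str
) -> float:
    """Mean delta-AIC over all hypothesis models / mean over the given set.

    ``set_names`` is either a named set ("G", "S", "T", "ST", "f", "r",
    "fr") or an explicit list of member model names. The null model "0"
    is excluded from both means. A set mean of zero with a nonzero
    overall mean yields +inf with a warning.
    """
    d = {k: float(v) for k, v in dict(delta_aics).items()}
    hypothesis = [k for k in d if k != "0"]
    if not hypothesis:
        raise ValueError("no hypothesis models supplied")
    if isinstance(set_names, str):
        members = set_members(set_names, d.keys())
    else:
        members = [m for m in set_names if m != "0"]
    if not members:
        raise ValueError("empty model set")
    missing = [m for m in members if m not in d]
    if missing:
        raise KeyError(f"delta-AIC missing for {missing}")
    overall = float(np.mean([d[k] for k in hypothesis]))
    within = float(np.mean([d[m] for m in members]))
    if within == 0.0:
        if overall == 0.0:
            return 1.0
        warnings.warn("set mean delta-AIC is zero; ratio is infinite", RuntimeWarning)
        return math.inf
    return overall / within


def all_set_ratios(delta_aics: Mapping[str, float]) -> dict[str, float]:
    """Delta-AIC ratio for every named set with members in the comparison."""
    out = {}
    for s in MODEL_SETS:
        if set_members(s, dict(delta_aics).keys()):
            out[s] = delta_aic_ratio(delta_aics, s)
    return out
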