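"""Factor scoring and the dichotomous inhibited-temperament call.

Given per-animal, per-day behavioral item measurements, this module
computes standardized Activity and Emotionality factor scores for each of
the two testing days, classifies each animal as inhibited or not
(inhibited = below the cohort mean on *both* factors across the two
days), builds the continuous inhibition composite, and provides the
rank-based inverse normal transformation applied to phenotypes before
variance-component analysis.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .items import ACTIVITY, EMOTIONALITY, factor_items

__all__ = [
    "FactorLoadings",
    "default_loadings",
    "score_factors",
    "classify_it",
    "inverse_normal_transform",
    "SCORE_COLUMNS",
]

SCORE_COLUMNS = ["activity_d1", "activity_d2", "emotionality_d1", "emotionality_d2"]


@dataclasses.dataclass(frozen=True)
class FactorLoadings:
    """Per-item weights for the Activity and Emotionality factors.

    The factor structure was established by factor analysis on a separate
    cohort, so the loadings are an *input* here.  The default is unit
    weights (with the registry's sign conventions) on z-scored items.
    Item sets must be disjoint between factors.
    """

    activity: Mapping[str, float]
    emotionality: Mapping[str, float]

    def __post_init__(self) -> None:
        overlap = set(self.activity) & set(self.emotionality)
        if overlap:
            raise ValueError(f"items in both factors: {sorted(overlap)}")
        if not self.activity or not self.emotionality:
            raise ValueError("each factor needs at least one item")

    @property
    def items(self) -> list[str]:
        return list(self.activity) + list(self.emotionality)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"activity": dict(self.activity), "emotionality": dict(self.emotionality)},
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "FactorLoadings":
        raw = json.loads(Path(path).read_text())
        return cls(activity=raw["activity"], emotionality=raw["emotionality"])


def default_loadings() -> FactorLoadings:
    """Unit-weight loadings on the registry's items and signs."""
    return FactorLoadings(
        activity={it.name: float(it.sign) for it in factor_items(ACTIVITY)},
        emotionality={it.name: float(it.sign) for it in factor_items(EMOTIONALITY)},
    )


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd


def score_factors(
    records: pd.DataFrame,
    loadings: FactorLoadings | None = None,
) -> pd.DataFrame:
    """Compute day-wise standardized factor scores from behavioral items.

    Parameters
    ----------
    records
        One row per animal x day; columns ``animal``, ``day`` (1 or 2) and
        one column per item.  Dichotomous items are 0/1 and enter the
        z-scoring like any other item.
    loadings
        Item weights per factor; default unit weights.

    Returns
    -------
    DataFrame indexed by animal with columns ``activity_d1``,
    ``activity_d2``, ``emotionality_d1``, ``emotionality_d2``; each score
    is the loading-weighted sum of within-day z-scored items,
    standardized to cohort mean 0 / SD 1.

    Raises
    ------
    ValueError
        If any animal is missing a day or an item value.  Zero-variance
        items are excluded with a warning (they carry no information).
    """
    loadings = loadings or default_loadings()
    need = {"animal", "day", *loadings.items}
    missing_cols = need - set(records.columns)
    if missing_cols:
        raise ValueError(f"records missing column(s): {sorted(missing_cols)}")
    days = set(records["day"].unique())
    if not days <= {1, 2}:
        raise ValueError(f"day must be 1 or 2, got {sorted(days)}")

    counts = records.groupby("animal")["day"].agg(["size", "nunique"])
    bad = counts[(counts["size"] != 2) | (counts["nunique"] != 2)]
    if len(bad):
        raise ValueError(
            f"animals without exactly one record per day: {bad.index.tolist()[:10]}"
        )
    na_rows = records[loadings.items].isna().any(axis=1)
    if na_rows.any():
        raise ValueError(
            "missing item values for animals: "
            f"{records.loc[na_rows, 'animal'].unique().tolist()[:10]}"
        )

    out: dict[str, pd.Series] = {}
    for day in (1, 2):
        sub = records[records["day"] == day].set_index("animal")
        for factor, weights in (
            (ACTIVITY, loadings.activity),
            (EMOTIONALITY, loadings.emotionality),
        ):
            score = np.zeros(len(sub))
            used = 0
            for item, w in weights.items():
                vals = sub[item].to_numpy(dtype=float)
                if vals.std(ddof=0) == 0.0:
                    warnings.warn(
                        f"item {item!r} has zero variance on day {day}; excluded",
                        stacklevel=2,
                    )
                    continue
                score += w * _zscore(vals)
                used += 1
            if used == 0:
                raise ValueError(f"no informative items for {factor} on day {day}")
            out[f"{factor}_d{day}"] = pd.Series(_zscore(score), index=sub.index)

    scores = pd.DataFrame(out)[SCORE_COLUMNS]
    scores.index.name = "animal"
    return scores


def classify_it(scores: pd.DataFrame, rule: str = "day_average") -> pd.DataFrame:
    """Label each animal inhibited / not inhibited from its factor scores.

    Default rule (``"day_average"``): average each factor over the two
    days; an animal is inhibited iff *both* day-averaged factors fall
    strictly below their cohort means.  The stricter ``"all_four"`` rule
    requires every one of the four day x factor scores below its mean.
    Exact ties with the mean count as not inhibited.

    Also returns ``it_continuous``, the continuous inhibition composite:
    minus the mean of the four standardized scores (higher = more
    inhibited).
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 animals to define cohort means")
    missing = set(SCORE_COLUMNS) - set(scores.columns)
    if missing:
        raise ValueError(f"scores missing column(s): {sorted(missing)}")
    if scores[SCORE_COLUMNS].isna().any().any():
        raise ValueError("scores contain missing values")

    act = scores[["activity_d1", "activity_d2"]].mean(axis=1)
    emo = scores[["emotionality_d1", "emotionality_d2"]].mean(axis=1)
    if rule == "day_average":
        inhibited = (act < act.mean()) & (emo < emo.mean())
    elif rule == "all_four":
        below = scores[SCORE_COLUMNS] < scores[SCORE_COLUMNS].mean(axis=0)
        inhibited = below.all(axis=1)
    else:
        raise ValueError(f"unknown rule {rule!r}")

    return pd.DataFrame(
        {
            "inhibited": inhibited,
            "it_continuous": -scores[SCORE_COLUMNS].mean(axis=1),
        },
        index=scores.index,
    )


def inverse_normal_transform(values: np.ndarray | pd.Series) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset.

    Maps value with rank ``r`` (average ranks for ties) among ``n`` to
    ``Phi^-1((r - 3/8) / (n + 1/4))``.  Strictly monotone in the input up
    to ties; used to normalize phenotypes before REML.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D vector of at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if np.all(x == x[0]):
        raise ValueError("all values equal; transform undefined")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.375) / (len(x) + 0.25))
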