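"""Standardized deviance scores and dominant-subphenotype assignment.

Each of the four metabolic measures is converted to a cohort Z-score
oriented so that positive values mean a more abnormal phenotype (the
disposition index and incretin effect are negated first, since high values
of those are healthy).  A participant's dominant subphenotype is the measure
with the highest deviance; when the runner-up is within ``delta`` (default
0.5) the pair is co-dominant, and when two or more others fall within
``delta`` of the top the participant is unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "MEASURE_COLUMNS",
    "DEVIANCE_COLUMNS",
    "DevianceScorer",
    "deviance_scores",
    "assign_dominance",
    "Assignment",
    "summarize_dominance",
]

#: profile columns holding the four measures, in canonical order
MEASURE_COLUMNS = ("sspg", "di", "ie_pct", "hepatic_ir")
#: deviance axes, aligned with MEASURE_COLUMNS
DEVIANCE_COLUMNS = ("muscle_ir", "beta_cell", "incretin", "hepatic_ir")
#: measures negated before standardization (higher raw value = healthier)
_NEGATED = ("di", "ie_pct")

_IR_AXES = {"muscle_ir", "hepatic_ir"}
_SECRETION_AXES = {"beta_cell", "incretin"}


class DevianceScorer(BaseEstimator, TransformerMixin):
    """Cohort standardizer producing the four deviance scores.

    Parameters
    ----------
    ddof : int, default 1
        Delta degrees of freedom of the standard deviation (1 = sample SD).

    Attributes
    ----------
    mean_ : ndarray of shape (4,) — cohort means of the oriented measures
    scale_ : ndarray of shape (4,) — cohort SDs of the oriented measures
    """

    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def _oriented(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in MEASURE_COLUMNS if c not in X.columns]
        if missing:
            raise ValueError(f"profiles missing measure columns {missing}")
        M = X.loc[:, list(MEASURE_COLUMNS)].to_numpy(dtype=float).copy()
        for j, col in enumerate(MEASURE_COLUMNS):
            if col in _NEGATED:
                M[:, j] = -M[:, j]
        return M

    def fit(self, X: pd.DataFrame, y=None):
        M = self._oriented(X)
        M = M[~np.isnan(M).any(axis=1)]
        if M.shape[0] < 2:
            raise ValueError("need >= 2 complete participants to standardize")
        self.mean_ = M.mean(axis=0)
        self.scale_ = M.std(axis=0, ddof=self.ddof)
        if np.any(self.scale_ == 0):
            raise ValueError("degenerate cohort: a measure has zero SD")
        self.n_features_in_ = 4
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "mean_")
        M = self._oriented(X)
        Z = (M - self.mean_) / self.scale_
        return pd.DataFrame(Z, index=X.index, columns=list(DEVIANCE_COLUMNS))


def deviance_scores(profiles: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Deviance (Z) scores of a cohort of metabolic profiles.

    Participants with any of the four measures missing are excluded from
    both the cohort statistics and the output.
    """
    complete = profiles.dropna(subset=list(MEASURE_COLUMNS))
    dropped = len(profiles) - len(complete)
    if dropped:
        import logging

        logging.getLogger(__name__).info(
            "excluded %d participants with incomplete measures", dropped
        )
    scorer = DevianceScorer(ddof=ddof).fit(complete)
    return scorer.transform(complete)


@dataclass(frozen=True)
class Assignment:
    """Dominance call for one participant."""

    category: str  # "dominant" | "co_dominant" | "unclassified"
    primary: str | None = None
    secondary: str | None = None

    def __str__(self) -> str:
        if self.category == "dominant":
            return f"dominant({self.primary})"
        if self.category == "co_dominant":
            return f"co_dominant({self.primary},{self.secondary})"
        return "unclassified"


def assign_dominance(deviances: pd.Series | dict, delta: float = 0.5) -> Assignment:
    """Dominance rule on one participant's four deviance scores.

    With scores sorted descending d1 >= d2 >= d3 >= d4: dominant(top) when
    d1 - d2 >= delta; co-dominant(top two) when d1 - d2 < delta but
    d1 - d3 >= delta; unclassified when d1 - d3 < delta.
    """
    d = pd.Series(deviances, dtype=float)
    d = d.loc[[c for c in DEVIANCE_COLUMNS if c in d.index]]
    if len(d) != 4:
        raise ValueError(f"need the four deviance axes, got {list(d.index)}")
    if d.isna().any() or not np.isfinite(d.to_numpy()).all():
        raise ValueError("deviance scores must be finite")
    order = d.sort_values(ascending=False, kind="stable")
    d1, d2, d3 = order.iloc[0], order.iloc[1], order.iloc[2]
    if d1 - d2 >= delta:
        return Assignment("dominant", order.index[0])
    if d1 - d3 >= delta:
        # canonical ordering of the co-dominant pair for stable reporting
        pair = sorted(
            (order.index[0], order.index[1]), key=DEVIANCE_COLUMNS.index
        )
        return Assignment("co_dominant", pair[0], pair[1])
    return Assignment("unclassified")


def summarize_dominance(assignments: "pd.Series | list[Assignment]") -> dict:
    """Cohort counts of dominant/co-dominant/unclassified assignments.

    Returns a dict with per-axis dominant counts, co-dominant pair counts,
    the unclassified count, and the insulin-resistance-axis /
    secretion-axis totals (participants dominant or co-dominant in muscle
    and/or hepatic IR, respectively beta-cell and/or incretin).
    """
    if isinstance(assignments, pd.Series):
        assignments = list(assignments)
    dominant = {axis: 0 for axis in DEVIANCE_COLUMNS}
    pairs: dict[tuple[str, str], int] = {}
    unclassified = 0
    ir_axis_total = 0
    secretion_axis_total = 0
    for a in assignments:
        involved: set[str] = set()
        if a.category == "dominant":
            dominant[a.primary] += 1
            involved = {a.primary}
        elif a.category == "co_dominant":
            key = (a.primary, a.secondary)
            pairs[key] = pairs.get(key, 0) + 1
            involved = set(key)
        else:
            unclassified += 1
        if involved & _IR_AXES:
            ir_axis_total += 1
        if involved & _SECRETION_AXES:
            secretion_axis_total += 1
    n_dominant = sum(dominant.values())
    n_co = sum(pairs.values())
    return {
        "n": n_dominant + n_co + unclassified,
        "dominant": dominant,
        "n_dominant": n_dominant,
        "co_dominant_pairs": pairs,
        "n_co_dominant": n_co,
        "unclassified": unclassified,
        "ir_axis_total": ir_axis_total,
        "secretion_axis_total": secretion_axis_total,
    }
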