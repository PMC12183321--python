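"""Engineered features of the 16-point OGTT glucose curve.

Fourteen shape features are extracted per curve: glucose at fixed times
(G_0, G_60, G_120, G_180), the peak (G_Peak) and its timing/slopes
(T_baseline2peak, S_baseline2peak, S_peak2end), trapezoid areas (AUC plus
the baseline-relative positive/negative/incremental decomposition pAUC,
nAUC, iAUC = pAUC - nAUC), the curve arc length (CurveSize) and the
coefficient of variation of the sampled values (CV).

Integrals, peak search and slopes are defined on [0, 180] min with the t=0
value as baseline; the pre-load -10-min sample enters only the CV, which is
computed over all 16 sampled values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .curves import CANONICAL_GRID, GlucoseCurve

__all__ = [
    "FEATURE_NAMES",
    "impute_curve",
    "extract_features",
    "CurveFeaturizer",
    "feature_phenotype_correlations",
]

FEATURE_NAMES = (
    "G_0",
    "G_60",
    "G_120",
    "G_180",
    "G_Peak",
    "CurveSize",
    "AUC",
    "pAUC",
    "nAUC",
    "iAUC",
    "CV",
    "T_baseline2peak",
    "S_baseline2peak",
    "S_peak2end",
)


def impute_curve(curve: GlucoseCurve) -> GlucoseCurve:
    """Fill missing readings: linear interpolation inside, nearest at edges."""
    v = curve.values
    mask = ~np.isnan(v)
    if mask.sum() < 2:
        raise ValueError("need at least two observed points to impute")
    if mask.all():
        return curve
    filled = np.interp(curve.times, curve.times[mask], v[mask])
    return curve.with_values(filled)


def _values_at(times: np.ndarray, values: np.ndarray, t: float) -> float:
    idx = np.flatnonzero(np.isclose(times, t))
    return float(values[idx[0]])


def extract_features(curve: GlucoseCurve) -> pd.Series:
    """The 14 engineered features of a complete canonical curve."""
    if not curve.is_canonical:
        raise ValueError("curve must be on the canonical 16-point grid")
    if not curve.is_complete:
        raise ValueError("curve has missing values; impute first")
    t_all, g_all = curve.times, curve.values
    post = t_all >= 0  # [0, 180] window for integrals, peak and slopes
    t, g = t_all[post], g_all[post]

    g0 = _values_at(t, g, 0.0)
    peak_idx = int(np.argmax(g))  # argmax returns the earliest maximum
    g_peak = float(g[peak_idx])
    t_peak = float(t[peak_idx])

    auc = float(np.trapezoid(g, t))
    pauc = float(np.trapezoid(np.maximum(g - g0, 0.0), t))
    nauc = float(np.trapezoid(np.maximum(g0 - g, 0.0), t))
    curve_size = float(np.sum(np.hypot(np.diff(t), np.diff(g))))
    cv = float(np.std(g_all, ddof=1) / np.mean(g_all))

    s_up = (g_peak - g0) / t_peak if t_peak > 0 else 0.0
    s_down = (
        (_values_at(t, g, 180.0) - g_peak) / (180.0 - t_peak)
        if t_peak < 180.0
        else 0.0
    )
    return pd.Series(
        {
            "G_0": g0,
            "G_60": _values_at(t, g, 60.0),
            "G_120": _values_at(t, g, 120.0),
            "G_180": _values_at(t, g, 180.0),
            "G_Peak": g_peak,
            "CurveSize": curve_size,
            "AUC": auc,
            "pAUC": pauc,
            "nAUC": nauc,
            "iAUC": pauc - nauc,
            "CV": cv,
            "T_baseline2peak": t_peak,
            "S_baseline2peak": float(s_up),
            "S_peak2end": float(s_down),
        }
    )


class CurveFeaturizer(BaseEstimator, TransformerMixin):
    """Stateless transformer: (n, 16) canonical curve matrix -> (n, 14) features.

    Rows are glucose values sampled on the canonical grid.  Fits nothing;
    provided for composition with sklearn pipelines.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != CANONICAL_GRID.size:
            raise ValueError("expected an (n, 16) canonical curve matrix")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        rows = [
            extract_features(
                GlucoseCurve("_", "plasma", "_", CANONICAL_GRID, row)
            ).to_numpy()
            for row in X
        ]
        return np.asarray(rows)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)


def feature_phenotype_correlations(
    features: pd.DataFrame, measures: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r (with t-test p) between each curve feature and each measure.

    Returns a tidy frame with columns feature, measure, r, p, significant
    (p < 0.05).  Zero-variance features yield NaN r/p.
    """
    joined = features.join(measures, how="inner", lsuffix="_f")
    if len(joined) < 3:
        raise ValueError("need >= 3 complete participants")
    records = []
    for f in features.columns:
        for m in measures.columns:
            x = joined[f].to_numpy(dtype=float)
            y = joined[m].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            x, y = x[ok], y[ok]
            if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
                r, p = float("nan"), float("nan")
            else:
                r, p = stats.pearsonr(x, y)
            records.append(
                {
                    "feature": f,
                    "measure": m,
                    "r": r,
                    "p": p,
                    "significant": bool(p < 0.05) if p == p else False,
                }
            )
    return pd.DataFrame.from_records(records)
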