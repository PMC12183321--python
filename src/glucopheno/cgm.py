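"""At-home CGM traces: windowing, resampling, averaging and concordance.

A continuous glucose monitor samples interstitial glucose every 5 minutes.
For an at-home OGTT the trace is windowed to the 3 hours following glucola
ingestion, small sensor gaps are interpolated, the series is resampled onto
the canonical 16-point grid so the curve-feature machinery applies
unchanged, and repeat tests are averaged pointwise.  Concordance between
settings (plasma vs clinic CGM, the two home tests, plasma vs mean home
curve) is summarized by per-participant Pearson correlations and the
intra-individual per-timepoint coefficient of variation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .curves import CANONICAL_GRID, CGM_GRID, GlucoseCurve

__all__ = [
    "align_cgm_to_ogtt",
    "resample_to_canonical",
    "average_home_tests",
    "concordance_report",
    "intraindividual_cv",
]


def align_cgm_to_ogtt(
    trace: GlucoseCurve,
    t0: float,
    max_consecutive_missing: int = 2,
    step: float = 5.0,
) -> GlucoseCurve:
    """Re-index a CGM trace to minutes since glucola start and fill gaps.

    The trace must cover [t0, t0+180]; runs of more than
    ``max_consecutive_missing`` missing 5-min readings are refused.
    """
    rel = trace.times - t0
    grid = np.arange(0.0, 180.0 + 0.5 * step, step)
    present = ~np.isnan(trace.values)
    rel_obs, val_obs = rel[present], trace.values[present]
    if rel_obs.size < 2 or rel_obs.min() > 0 or rel_obs.max() < 180:
        raise ValueError("trace does not cover the [t0, t0+180] window")
    # largest run of grid points without a reading within step/2
    has_reading = np.array(
        [np.any(np.abs(rel_obs - t) < step / 2) for t in grid]
    )
    run = longest = 0
    for h in has_reading:
        run = 0 if h else run + 1
        longest = max(longest, run)
    if longest > max_consecutive_missing:
        raise ValueError(
            f"gap of {longest} consecutive missing readings exceeds "
            f"tolerance {max_consecutive_missing}"
        )
    values = np.interp(grid, rel_obs, val_obs)
    return GlucoseCurve(
        trace.participant_id, trace.source, trace.test_id, grid, values
    )


def resample_to_canonical(windowed: GlucoseCurve) -> GlucoseCurve:
    """Linear interpolation of a [0, 180] curve onto the 16-point grid.

    The pre-load -10-min slot has no CGM analogue and is filled with the
    t=0 value (a synthetic baseline sample).
    """
    if windowed.times.min() > 0 or windowed.times.max() < 180:
        raise ValueError("windowed curve must span [0, 180] minutes")
    post = CANONICAL_GRID[CANONICAL_GRID >= 0]
    values = np.interp(post, windowed.times, windowed.values)
    full = np.concatenate([[values[0]], values])  # -10 min := t=0 value
    return GlucoseCurve(
        windowed.participant_id,
        windowed.source,
        windowed.test_id,
        CANONICAL_GRID,
        full,
    )


def average_home_tests(curves: list[GlucoseCurve]) -> GlucoseCurve:
    """Pointwise mean of repeat tests on a common grid."""
    if not curves:
        raise ValueError("need at least one curve")
    base = curves[0]
    for c in curves[1:]:
        if c.times.shape != base.times.shape or not np.allclose(
            c.times, base.times
        ):
            raise ValueError("curves are not on a common grid")
    mean_values = np.mean([c.values for c in curves], axis=0)
    return GlucoseCurve(
        base.participant_id, base.source, "mean", base.times, mean_values
    )


def _pair_r(a: GlucoseCurve, b: GlucoseCurve) -> float:
    if a.times.shape != b.times.shape or not np.allclose(a.times, b.times):
        raise ValueError("curve pair is not on a common grid")
    if np.std(a.values) == 0 or np.std(b.values) == 0:
        return float("nan")
    return float(stats.pearsonr(a.values, b.values)[0])


def concordance_report(
    pairs: dict[str, tuple[GlucoseCurve, GlucoseCurve]]
) -> pd.DataFrame:
    """Per-participant Pearson r for curve pairs, plus cohort quartiles.

    ``pairs`` maps participant id to a (curve, curve) tuple on a shared
    grid.  Constant series yield NaN r and are flagged.  The cohort summary
    (median, Q1, Q3, n) is attached as ``DataFrame.attrs['summary']``.
    """
    records = [
        {"participant_id": pid, "r": _pair_r(a, b)}
        for pid, (a, b) in pairs.items()
    ]
    out = pd.DataFrame.from_records(records)
    r = out["r"].dropna()
    out.attrs["summary"] = {
        "median": float(r.median()) if len(r) else float("nan"),
        "q1": float(r.quantile(0.25)) if len(r) else float("nan"),
        "q3": float(r.quantile(0.75)) if len(r) else float("nan"),
        "n": int(len(r)),
        "n_undefined": int(out["r"].isna().sum()),
    }
    return out


def intraindividual_cv(repeats: list[GlucoseCurve]) -> tuple[np.ndarray, float]:
    """Per-timepoint CV (%) across repeat tests and the overall mean CV.

    CV_t = sample SD / mean of the repeat readings at timepoint t; the
    overall figure averages across timepoints.
    """
    if len(repeats) < 2:
        raise ValueError("need at least two repeat tests")
    base = repeats[0]
    for c in repeats[1:]:
        if c.times.shape != base.times.shape or not np.allclose(
            c.times, base.times
        ):
            raise ValueError("repeat tests are not on a common grid")
    V = np.vstack([c.values for c in repeats])
    cv = V.std(axis=0, ddof=1) / V.mean(axis=0) * 100.0
    return cv, float(np.mean(cv))
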