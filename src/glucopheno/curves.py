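"""Core time-series containers for glucose and analyte measurements.

The clinical-research-unit (CTRU) oral glucose-tolerance test samples plasma
glucose on a fixed 16-point grid spanning -10 to 180 minutes; insulin and
C-peptide are drawn at 7 of those timepoints, incretin hormones at 4.  At-home
tests are captured by a continuous glucose monitor (CGM) at 5-minute
resolution.  These containers carry one series each, with enough labelling
(participant, source, test) to cross-reference a cohort's files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: canonical CTRU OGTT sampling grid, minutes relative to glucola start
CANONICAL_GRID = np.array(
    [-10, 0, 10, 15, 20, 30, 40, 50, 60, 75, 90, 105, 120, 135, 150, 180],
    dtype=float,
)

#: insulin / C-peptide sampling grid (minutes)
CPEPTIDE_GRID = np.array([0, 15, 30, 60, 90, 120, 180], dtype=float)

#: incretin-hormone (GLP-1, GIP, glucagon) sampling grid (minutes)
INCRETIN_GRID = np.array([0, 30, 60, 120], dtype=float)

#: 5-minute CGM grid over the 3-h test window
CGM_GRID = np.arange(0, 181, 5, dtype=float)

GLUCOSE_SOURCES = ("plasma", "cgm_clinic", "cgm_home")
TEST_TYPES = ("OGTT", "IIGI")
ANALYTES = ("cpeptide", "insulin", "glucose", "GLP1", "GIP", "glucagon")


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass
class GlucoseCurve:
    """One glucose time series on a stated grid.

    Parameters
    ----------
    participant_id : str
    source : {"plasma", "cgm_clinic", "cgm_home"}
    test_id : str
        Identifier distinguishing repeat tests of one participant.
    times : array of minutes, strictly increasing
    values : array of glucose, mg/dl; NaN marks a missing reading
    """

    participant_id: str
    source: str
    test_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = _as_float_array(self.times)
        self.values = _as_float_array(self.values)
        if self.source not in GLUCOSE_SOURCES:
            raise ValueError(f"unknown glucose source {self.source!r}")
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-d and equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        observed = self.values[~np.isnan(self.values)]
        if np.any(observed <= 0):
            raise ValueError("glucose values must be positive where present")

    @property
    def is_canonical(self) -> bool:
        """True when sampled exactly on the 16-point CTRU grid."""
        return self.times.shape == CANONICAL_GRID.shape and np.allclose(
            self.times, CANONICAL_GRID
        )

    @property
    def is_complete(self) -> bool:
        return not np.any(np.isnan(self.values))

    def with_values(self, values) -> "GlucoseCurve":
        return replace(self, values=_as_float_array(values))


@dataclass
class AnalyteSeries:
    """Concentrations of one analyte during one test (OGTT or IIGI).

    Units follow assay convention: C-peptide pmol/l, insulin uIU/ml,
    glucose mg/dl, incretins pg/ml.
    """

    participant_id: str
    test_type: str
    analyte: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = _as_float_array(self.times)
        self.values = _as_float_array(self.values)
        if self.test_type not in TEST_TYPES:
            raise ValueError(f"unknown test type {self.test_type!r}")
        if self.analyte not in ANALYTES:
            raise ValueError(f"unknown analyte {self.analyte!r}")
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-d and equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values[~np.isnan(self.values)] < 0):
            raise ValueError("concentrations must be non-negative")

    def auc(self, t_min: float = 0.0, t_max: float = 180.0) -> float:
        """Trapezoid area under the series restricted to [t_min, t_max]."""
        mask = (self.times >= t_min) & (self.times <= t_max)
        if mask.sum() < 2:
            raise ValueError("need at least two points inside the AUC window")
        return float(np.trapezoid(self.values[mask], self.times[mask]))
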