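"""Shape-only reduced representation of OGTT glucose curves.

Each curve is Z-normalized (removing amplitude so only the shape remains),
smoothed with a cubic smoothing spline, and projected onto the top two
principal components of the *training* curves:

    X_reduced = (X - mean_vector) @ W

with W the 16 x 2 loading matrix.  Fitting the basis on training data only
and projecting held-out curves through the stored mean and loadings is what
keeps cross-validation leak-free; composed in an sklearn Pipeline the refit
happens inside every fold automatically.

The smoothing parameter follows a normalized convention s in [0, 1]:
s = 0 interpolates the data, s = 1 degenerates to the least-squares straight
line, mapped internally to the penalized-spline weight
lam = s / (1 - s) * mean(dt)^3.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .curves import CANONICAL_GRID

__all__ = [
    "znormalize",
    "smooth_curve",
    "preprocess_curves",
    "ReducedRepresentation",
]


def znormalize(values: np.ndarray) -> np.ndarray:
    """Per-curve Z-score: output has mean 0 and (population) SD 1."""
    v = np.asarray(values, dtype=float)
    sd = v.std()
    if sd == 0:
        raise ValueError("constant curve cannot be Z-normalized")
    return (v - v.mean()) / sd


def smooth_curve(
    values: np.ndarray,
    times: np.ndarray = CANONICAL_GRID,
    smoothing_parameter: float = 0.35,
) -> np.ndarray:
    """Cubic smoothing spline evaluated back at the input times.

    smoothing_parameter 0 reproduces the input exactly (interpolation),
    1 returns the least-squares straight line.
    """
    s = float(smoothing_parameter)
    if not 0.0 <= s <= 1.0:
        raise ValueError("smoothing_parameter must lie in [0, 1]")
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape:
        raise ValueError("times and values must align")
    if s == 0.0:
        return v.copy()
    if s == 1.0:
        slope, intercept = np.polyfit(t, v, 1)
        return slope * t + intercept
    lam = s / (1.0 - s) * float(np.mean(np.diff(t))) ** 3
    spline = make_smoothing_spline(t, v, lam=lam)
    return np.asarray(spline(t), dtype=float)


def preprocess_curves(
    X: np.ndarray,
    times: np.ndarray = CANONICAL_GRID,
    smoothing_parameter: float = 0.35,
) -> np.ndarray:
    """Z-normalize then smooth every row of an (n, p) curve matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.vstack(
        [smooth_curve(znormalize(row), times, smoothing_parameter) for row in X]
    )


class ReducedRepresentation(BaseEstimator, TransformerMixin):
    """Train-only PCA basis over preprocessed glucose curves.

    Parameters
    ----------
    n_components : int, default 2
    smoothing_parameter : float, default 0.35
        Normalized cubic-smoothing-spline parameter applied (after per-curve
        Z-normalization) before the PCA.  Set ``preprocess=False`` when the
        input rows are already normalized and smoothed.
    preprocess : bool, default True

    Attributes
    ----------
    mean_vector_ : (p,) training mean of the preprocessed curves
    loadings_ : (p, n_components) orthonormal loading matrix W, each
        column's largest-magnitude element forced positive
    explained_variance_ratio_ : (n_components,) fractions, non-increasing
    """

    def __init__(
        self,
        n_components: int = 2,
        smoothing_parameter: float = 0.35,
        preprocess: bool = True,
        times: np.ndarray = CANONICAL_GRID,
    ):
        self.n_components = n_components
        self.smoothing_parameter = smoothing_parameter
        self.preprocess = preprocess
        self.times = times

    def _prep(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.preprocess:
            X = preprocess_curves(X, self.times, self.smoothing_parameter)
        return X

    def fit(self, X, y=None):
        X = self._prep(X)
        if X.shape[0] < 3:
            raise ValueError("need at least 3 training curves")
        pca = PCA(n_components=self.n_components, svd_solver="full")
        pca.fit(X)
        W = pca.components_.T.copy()  # (p, k)
        # deterministic sign: largest-magnitude element of each loading > 0
        for j in range(W.shape[1]):
            i = int(np.argmax(np.abs(W[:, j])))
            if W[i, j] < 0:
                W[:, j] = -W[:, j]
        self.mean_vector_ = pca.mean_.copy()
        self.loadings_ = W
        self.explained_variance_ = pca.explained_variance_.copy()
        self.explained_variance_ratio_ = pca.explained_variance_ratio_.copy()
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "loadings_")
        X = self._prep(X)
        if X.shape[1] != self.mean_vector_.size:
            raise ValueError("curve length does not match the fitted basis")
        return (X - self.mean_vector_) @ self.loadings_

    def project(self, curve: np.ndarray) -> np.ndarray:
        """Project a single preprocessed curve; returns a length-2 vector."""
        return self.transform(np.atleast_2d(curve))[0]
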