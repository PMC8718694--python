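"""Regression-feature extraction from flux trajectories.

Each reaction-flux time series is summarised by an ordinary least-squares
line fit of flux on time: the fitted intercept and gradient, the
coefficient of determination R², and the mean squared residual.  Together
the four capture the trend (gradient), the operating level (intercept),
the linearity (R²) and the roughness/oscillation (MSE) of a trajectory.
Feature sets are then projected to two principal components so that
wild-type boundaries can be drawn in a plane.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .errors import DegenerateInputError, InvalidArgumentError
from .types import FeatureVector, FluxSeries


def fit_linear_features(series: FluxSeries) -> FeatureVector:
    """Fit flux = intercept + gradient * time by ordinary least squares.

    R² is 1 - SS_res/SS_tot.  For a zero-variance (constant) series
    SS_tot is 0 and the constant fit is exact, so R² is defined as 1.

    Raises
    ------
    DegenerateInputError
        If the series has fewer than 2 points or fewer than 2 distinct
        time values (the slope is then unidentifiable).
    """
    t, y = series.times, series.values
    if t.size < 2 or np.unique(t).size < 2:
        raise DegenerateInputError(
            "need at least 2 distinct time points to fit a line"
        )
    centred = y - y.mean()
    ss_tot = float(centred @ centred)
    if ss_tot == 0.0:
        # constant series: the flat line is an exact fit
        return FeatureVector(
            intercept=float(y[0]), gradient=0.0, r_squared=1.0, mse=0.0
        )
    gradient, intercept = np.polyfit(t, y, 1)
    residuals = y - (intercept + gradient * t)
    ss_res = float(residuals @ residuals)
    r_squared = float(min(1.0, 1.0 - ss_res / ss_tot))  # guard fp noise
    return FeatureVector(
        intercept=float(intercept),
        gradient=float(gradient),
        r_squared=r_squared,
        mse=ss_res / t.size,
    )


@dataclass(frozen=True)
class ReducedScores:
    """Principal-component projection of a feature matrix.

    ``scores`` are the n x k PC coordinates; ``loadings`` the p x k
    orthonormal projection weights; ``feature_means`` / ``feature_scales``
    the standardisation applied before centring, so new points can be
    projected consistently via :meth:`transform`.
    """

    scores: np.ndarray
    explained_variance_fraction: float
    loadings: np.ndarray
    feature_means: np.ndarray
    feature_scales: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project new rows into the fitted PC space."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = (X - self.feature_means) / self.feature_scales
        return Z @ self.loadings


def reduce_features(
    feature_matrix: np.ndarray,
    n_components: int = 2,
    standardise: bool = True,
) -> ReducedScores:
    """Project an n x p feature matrix onto its top principal components.

    Features are z-standardised by default before the PCA: intercept and
    MSE live on wildly different scales, and without scaling the
    largest-variance feature dominates the components.  Columns with zero
    variance get unit scale.  Each loading column's sign is fixed by
    making its largest-magnitude entry positive, so results are
    reproducible across linear-algebra backends.
    """
    X = np.asarray(feature_matrix, dtype=float)
    if X.ndim != 2:
        raise InvalidArgumentError("feature matrix must be 2-D")
    n, p = X.shape
    if n < n_components:
        raise InvalidArgumentError(
            f"need at least n_components={n_components} rows, got {n}"
        )
    if not np.isfinite(X).all():
        raise InvalidArgumentError("feature matrix contains non-finite values")

    if standardise:
        scaler = StandardScaler().fit(X)
        means = scaler.mean_.copy()
        scales = scaler.scale_.copy()  # zero-variance columns -> 1.0
    else:
        means = np.zeros(p)
        scales = np.ones(p)
    Z = (X - means) / scales

    k = min(n_components, p)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Z)
    loadings = pca.components_.T.copy()
    for j in range(k):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1

    total_var = float(np.var(Z, axis=0, ddof=1).sum()) if n > 1 else 0.0
    if total_var == 0.0:
        evf = 0.0
    else:
        evf = float(np.sum(pca.explained_variance_ratio_))
    # PCA centres Z again internally; fold its mean into the recorded means
    means = means + pca.mean_ * scales
    return ReducedScores(
        scores=scores,
        explained_variance_fraction=evf,
        loadings=loadings,
        feature_means=means,
        feature_scales=scales,
    )


def feature_matrix(vectors: list[FeatureVector]) -> np.ndarray:
    """Stack feature vectors into an n x 4 matrix in canonical column
    order (intercept, gradient, r_squared, mse)."""
    if not vectors:
        return np.empty((0, 4))
    return np.vstack([v.as_array() for v in vectors])
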