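"""PCA of logged EPT spectra.

Band energies span several orders of magnitude, so spectra are log10
transformed with a positive floor before a column-centred (optionally
unit-variance) PCA. Components carry a deterministic sign convention —
the largest-magnitude loading of each component is positive — so scores
and loadings are reproducible across runs and linear-algebra backends.
Axis attribution reports how strongly a component separates two groups
(standardised mean score difference) and which frequency bands dominate
its loading vector.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_array, check_is_fitted

from .spectral import BAND_WIDTH_HZ

logger = logging.getLogger(__name__)

__all__ = [
    "log_transform",
    "LogSpectraPCA",
    "PCAResult",
    "fit_pca",
    "AxisAttribution",
    "attribute_axes",
]


def log_transform(energy, floor: float):
    """log10 of the energy, floored at a small positive value.

    Empty bands (zero energy) map to log10(floor), keeping every cell
    finite without letting the floor dominate the variance.
    """
    if not floor > 0:
        raise ValueError("floor must be positive")
    return np.log10(np.maximum(np.asarray(energy, dtype=float), floor))


class LogSpectraPCA(TransformerMixin, BaseEstimator):
    """Centred PCA of log10 band energies with a deterministic sign.

    Parameters
    ----------
    floor : float or None
        Log floor; None picks the smallest positive observed energy
        times 1e-3 at fit time.
    scale : {"none", "unit"}
        Optional unit-variance scaling of the logged columns before the
        decomposition (covariance vs correlation PCA).

    Attributes
    ----------
    loadings_ : (n_bands, n_components) array
        Orthonormal component loadings, sign-fixed.
    scores_ : (n_rows, n_components) array
        Training-row scores.
    variance_explained_ : (n_components,) array
        Per-component percentage of variance; sums to 100 over all
        retained components (trailing zero-variance components report 0).
    cumulative_variance_ : (n_components,) array
    """

    def __init__(self, floor: float | None = None, scale: str = "none"):
        self.floor = floor
        self.scale = scale

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if X.shape[0] < 3:
            raise ValueError("PCA needs at least 3 rows")
        if np.any(X < 0):
            raise ValueError("band energies must be non-negative")
        if self.scale not in ("none", "unit"):
            raise ValueError("scale must be 'none' or 'unit'")
        if self.floor is not None:
            floor = float(self.floor)
        else:
            positive = X[X > 0]
            floor = float(positive.min()) * 1e-3 if positive.size else 1e-12
        self.floor_ = floor
        logged = log_transform(X, floor)
        self.mean_ = logged.mean(axis=0)
        if self.scale == "unit":
            sd = logged.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            self.scale_ = sd
        else:
            self.scale_ = np.ones(X.shape[1])
        centred = (logged - self.mean_) / self.scale_
        pca = PCA(n_components=None, svd_solver="full")
        scores = pca.fit_transform(centred)
        loadings = pca.components_.T  # (bands, components)
        # deterministic sign: largest-|loading| entry of each component positive
        for j in range(loadings.shape[1]):
            i = int(np.argmax(np.abs(loadings[:, j])))
            if loadings[i, j] < 0:
                loadings[:, j] *= -1
                scores[:, j] *= -1
        self.loadings_ = loadings
        self.scores_ = scores
        self.n_components_ = loadings.shape[1]
        self.n_features_in_ = X.shape[1]
        ratio = pca.explained_variance_ratio_
        self.variance_explained_ = 100.0 * ratio
        self.cumulative_variance_ = np.cumsum(self.variance_explained_)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "loadings_")
        X = check_array(X, dtype=float)
        centred = (log_transform(X, self.floor_) - self.mean_) / self.scale_
        return centred @ self.loadings_

    def inverse_transform(self, scores) -> np.ndarray:
        """Reconstruct the centred log matrix plus column means (log10 units)."""
        check_is_fitted(self, "loadings_")
        return np.asarray(scores) @ self.loadings_.T * self.scale_ + self.mean_


@dataclass
class PCAResult:
    """Scores, loadings and variance shares of one fitted PCA."""

    scores: np.ndarray
    loadings: np.ndarray
    variance_explained: np.ndarray  # percentages
    cumulative_variance: np.ndarray
    row_labels: pd.Index | None = None
    estimator: LogSpectraPCA | None = None


def fit_pca(matrix, scale: str = "none", floor: float | None = None) -> PCAResult:
    """Fit :class:`LogSpectraPCA` on a spectra matrix (rows = embryo-window means)."""
    row_labels = matrix.index if isinstance(matrix, pd.DataFrame) else None
    est = LogSpectraPCA(floor=floor, scale=scale).fit(np.asarray(matrix, dtype=float))
    return PCAResult(
        scores=est.scores_,
        loadings=est.loadings_,
        variance_explained=est.variance_explained_,
        cumulative_variance=est.cumulative_variance_,
        row_labels=row_labels,
        estimator=est,
    )


@dataclass(frozen=True)
class AxisAttribution:
    """Group separation along one component and its dominant bands."""

    component: int
    separation: float  # standardised mean score difference (second group - first)
    top_bands: tuple  # band indices with |loading| >= fraction of the max
    hz_ranges: tuple  # the same bands as (low, high) Hz ranges


def attribute_axes(
    result: PCAResult,
    grouping,
    component: int = 0,
    loading_frac: float = 0.5,
) -> AxisAttribution:
    """Separation score and top-loading bands for one component.

    ``grouping`` assigns each score row to one of exactly two groups; the
    separation is the standardised difference of mean scores (second
    sorted group minus first), so swapping the group labels flips the
    sign but not the magnitude.
    """
    groups = np.asarray(grouping)
    if groups.shape[0] != result.scores.shape[0]:
        raise ValueError("grouping length must match the number of score rows")
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError("axis attribution needs exactly 2 groups")
    s = result.scores[:, component]
    x, y = s[groups == levels[0]], s[groups == levels[1]]
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 rows")
    pooled = np.sqrt(
        ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / (x.size + y.size - 2)
    )
    if pooled == 0:
        separation = 0.0 if y.mean() == x.mean() else math_inf_sign(y.mean() - x.mean())
    else:
        separation = (y.mean() - x.mean()) / pooled
    load = np.abs(result.loadings[:, component])
    top = tuple(int(k) for k in np.flatnonzero(load >= loading_frac * load.max()))
    from .thermal import _contiguous_hz_ranges

    return AxisAttribution(
        component=component,
        separation=float(separation),
        top_bands=top,
        hz_ranges=_contiguous_hz_ranges(list(top)),
    )


def math_inf_sign(x: float) -> float:
    return float(np.inf) if x > 0 else float(-np.inf)
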