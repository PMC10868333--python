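"""Sampling-temperature selection via a thresholded 3×3 portfolio matrix.

Design models expose a temperature (or inverse-temperature α) parameter
trading sequence recovery against diversity.  Each candidate setting is a
point in the recovery × diversity plane; per-axis thresholds from exact
1-D k-means (k = 3) carve the plane into a 3×3 grid, and the recommended
setting is the one in the most attractive occupied cell, ties broken by
distance to the (max recovery, max diversity) vertex.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .errors import ConfigError, InputTooSmallError

BANDS = ("low", "mid", "high")


@dataclass(frozen=True)
class ThresholdPair:
    """Two cut points splitting an axis into low / mid / high bands."""

    low_cut: float
    high_cut: float

    def __post_init__(self) -> None:
        if not self.low_cut < self.high_cut:
            raise ConfigError(
                f"low_cut ({self.low_cut}) must be below high_cut "
                f"({self.high_cut})"
            )

    def band(self, value: float) -> str:
        if value < self.low_cut:
            return "low"
        if value < self.high_cut:
            return "mid"
        return "high"


@dataclass(frozen=True)
class TempPoint:
    """One temperature setting with its mean recovery and diversity."""

    method: str
    parameter_value: float
    recovery: float
    diversity: float
    cell: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        for name, v in (("recovery", self.recovery),
                        ("diversity", self.diversity)):
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1] (got {v})")


# ---------------------------------------------------------------------------
# exact 1-D k-means
# ---------------------------------------------------------------------------

def _kmeans_1d_dp(sorted_vals: np.ndarray, k: int):
    """Optimal SSE partition of sorted 1-D data into k contiguous clusters.

    Dynamic programme over prefix sums; optimal 1-D clusters are always
    contiguous in sorted order, so this is exact and deterministic.
    """
    n = sorted_vals.size
    pre = np.concatenate([[0.0], np.cumsum(sorted_vals)])
    pre2 = np.concatenate([[0.0], np.cumsum(sorted_vals**2)])

    def sse(i: int, j: int) -> float:
        # cost of one cluster over sorted_vals[i:j]
        s, s2, m = pre[j] - pre[i], pre2[j] - pre2[i], j - i
        return s2 - s * s / m

    cost = np.full((k + 1, n + 1), np.inf)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            for i in range(c - 1, j):
                cand = cost[c - 1, i] + sse(i, j)
                if cand < cost[c, j] - 1e-15:
                    cost[c, j] = cand
                    split[c, j] = i
    bounds = [n]
    for c in range(k, 0, -1):
        bounds.append(split[c, bounds[-1]])
    bounds = bounds[::-1]
    centers = np.array([
        sorted_vals[bounds[c]:bounds[c + 1]].mean() for c in range(k)
    ])
    labels = np.concatenate([
        np.full(bounds[c + 1] - bounds[c], c) for c in range(k)
    ])
    return centers, labels, float(cost[k, n])


class KMeans1D(BaseEstimator):
    """Exact, deterministic 1-D k-means (dynamic programming).

    Unlike seeded iterative k-means the optimum is unique up to cluster
    relabelling, so the derived thresholds are reproducible.  Attributes
    after fit: ``cluster_centers_`` (ascending), ``labels_`` (in input
    order, band index ascending with value), ``inertia_``,
    ``thresholds_`` (midpoints of adjacent centers, length k−1).
    """

    def __init__(self, n_clusters: int = 3):
        self.n_clusters = n_clusters

    def fit(self, X, y=None) -> "KMeans1D":
        values = np.asarray(X, dtype=float).ravel()
        k = self.n_clusters
        if np.unique(values).size < k:
            raise InputTooSmallError(
                f"need at least {k} distinct values for {k} clusters"
            )
        order = np.argsort(values, kind="stable")
        centers, sorted_labels, inertia = _kmeans_1d_dp(values[order], k)
        labels = np.empty(values.size, dtype=int)
        labels[order] = sorted_labels
        self.cluster_centers_ = centers
        self.labels_ = labels
        self.inertia_ = inertia
        self.thresholds_ = (centers[:-1] + centers[1:]) / 2.0
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def kmeans_thresholds(values: Sequence[float], k: int = 3) -> ThresholdPair:
    """Axis thresholds: pairwise averages of adjacent optimal-cluster centers.

    Three cluster centers yield exactly two adjacent-pair midpoints, the
    low and high cut of the axis.
    """
    if k != 3:
        raise ConfigError("the 3×3 selection matrix requires k = 3")
    est = KMeans1D(n_clusters=3).fit(values)
    low, high = est.thresholds_
    return ThresholdPair(low_cut=float(low), high_cut=float(high))


# ---------------------------------------------------------------------------
# classification and recommendation
# ---------------------------------------------------------------------------

def classify_parameters(points: Sequence[TempPoint],
                        rec_thresholds: ThresholdPair,
                        div_thresholds: ThresholdPair,
                        axis_scale: tuple[float, float] = (1.0, 1.0),
                        ) -> tuple[list[TempPoint], dict]:
    """Assign each point a 3×3 cell and recommend a parameter setting.

    The best cell is (high, high); if unoccupied, occupied cells are
    ordered by recovery band first, diversity band second.  Ties within
    the winning cell go to the point nearest (after *axis_scale*
    stretching) the vertex of maximal recovery and diversity over the
    point set.  When the winning cell is not (high, high) the
    recommendation carries the flag ``attractive_region_occupied=False``.
    """
    if not points:
        raise InputTooSmallError("no temperature points supplied")
    labelled = [
        replace(p, cell=(rec_thresholds.band(p.recovery),
                         div_thresholds.band(p.diversity)))
        for p in points
    ]
    band_rank = {b: i for i, b in enumerate(BANDS)}
    best_cell = max((band_rank[p.cell[0]], band_rank[p.cell[1]])
                    for p in labelled)
    in_best = [p for p in labelled
               if (band_rank[p.cell[0]], band_rank[p.cell[1]]) == best_cell]
    sx, sy = axis_scale
    vertex = (max(p.recovery for p in labelled),
              max(p.diversity for p in labelled))

    def vertex_distance(p: TempPoint) -> float:
        return float(np.hypot(sx * (p.recovery - vertex[0]),
                              sy * (p.diversity - vertex[1])))

    chosen = min(in_best, key=vertex_distance)
    recommendation = {
        "point": chosen,
        "cell": chosen.cell,
        "vertex_distance": vertex_distance(chosen),
        "attractive_region_occupied": chosen.cell == ("high", "high"),
    }
    return labelled, recommendation


class McKinseySelector(BaseEstimator):
    """Threshold-and-classify temperature selection, sklearn style.

    Fits per-axis :class:`KMeans1D` thresholds on the pooled points of all
    methods/parameters under comparison, classifies every point into the
    3×3 grid and stores a recommendation.
    """

    def __init__(self, axis_scale: tuple[float, float] = (1.0, 1.0)):
        self.axis_scale = axis_scale

    def fit(self, X: Sequence[TempPoint] | pd.DataFrame, y=None):
        points = _as_points(X)
        self.recovery_thresholds_ = kmeans_thresholds(
            [p.recovery for p in points])
        self.diversity_thresholds_ = kmeans_thresholds(
            [p.diversity for p in points])
        self.points_, self.recommendation_ = classify_parameters(
            points, self.recovery_thresholds_, self.diversity_thresholds_,
            axis_scale=tuple(self.axis_scale),
        )
        return self

    @property
    def frame_(self) -> pd.DataFrame:
        if not hasattr(self, "points_"):
            raise NotFittedError("McKinseySelector is not fitted yet")
        return pd.DataFrame([
            {"method": p.method, "parameter": p.parameter_value,
             "recovery": p.recovery, "diversity": p.diversity,
             "recovery_band": p.cell[0], "diversity_band": p.cell[1]}
            for p in self.points_
        ])


def _as_points(X) -> list[TempPoint]:
    if isinstance(X, pd.DataFrame):
        return [
            TempPoint(method=str(r["method"]),
                      parameter_value=float(r["parameter"]),
                      recovery=float(r["recovery"]),
                      diversity=float(r["diversity"]))
            for _, r in X.iterrows()
        ]
    return list(X)
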