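"""Hierarchical clustering of incorporation profiles and time-to-50% labeling.

Complete incorporation profiles (no missing time points) are clustered with
agglomerative hierarchical clustering, Euclidean distance, Ward
minimum-variance linkage, and the tree is cut at K groups. Each cluster's
characteristic speed is summarized by the earliest time its smoothed
conditional mean crosses 50% incorporation. The smoother is a loess-style
local polynomial regression with tricube weights (span = fraction of points
in each window, default degree 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .errors import ConfigError
from .quant_io import ExperimentDesign
from .turnover_kinetics import IncorporationProfile

#: Sentinel for "the smoothed mean never reaches 50% incorporation".
T50_UNDEFINED = math.nan

DEFAULT_SPAN = 0.5
#: Extra equispaced evaluation points added to the sample times.
GRID_POINTS = 200


@dataclass
class ProfileMatrix:
    """Complete-case proteins x time points matrix of incorporation fractions."""

    protein_ids: list[str]
    times_h: list[float]
    values: np.ndarray  # shape (n_proteins, n_times), all entries in [0, 1]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.protein_ids), len(self.times_h)):
            raise ValueError("matrix shape does not match row/column labels")
        if self.values.size and (
            np.any(~np.isfinite(self.values))
            or np.any(self.values < 0)
            or np.any(self.values > 1)
        ):
            raise ValueError("profile matrix entries must be finite and in [0, 1]")

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)


@dataclass
class ClusterResult:
    assignment: dict[str, int]  # protein_id -> cluster label in 1..K
    n_clusters: int
    curves: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    t50_h: dict[int, float] = field(default_factory=dict)

    def members(self, label: int) -> list[str]:
        return [pid for pid, lab in self.assignment.items() if lab == label]


def build_profile_matrix(
    profiles: Sequence[IncorporationProfile],
    design: ExperimentDesign,
    include_control: bool = False,
) -> ProfileMatrix:
    """Keep only proteins with a value at every required time point.

    By default the t=0 control is not required (no heavy signal exists
    before the pulse); pass ``include_control=True`` to require it.
    """
    times = list(design.time_points_h) if include_control else design.pulse_times_h
    ids: list[str] = []
    rows: list[list[float]] = []
    for prof in profiles:
        vals = [prof.points.get(t) for t in times]
        if any(v is None for v in vals):
            continue
        ids.append(prof.protein_id)
        rows.append([float(v) for v in vals])  # type: ignore[arg-type]
    values = np.array(rows, dtype=float) if rows else np.empty((0, len(times)))
    return ProfileMatrix(protein_ids=ids, times_h=times, values=values)


def cluster_profiles(
    matrix: ProfileMatrix,
    n_clusters: int = 8,
    span: float = DEFAULT_SPAN,
    degree: int = 2,
) -> ClusterResult:
    """Ward hierarchical clustering cut at ``n_clusters`` groups.

    Deterministic for a given row order. Per-cluster smoothed mean curves
    and t50 values are computed with :func:`time_to_half_incorporation`.
    """
    if n_clusters < 1:
        raise ConfigError(f"n_clusters must be >= 1, got {n_clusters}")
    if n_clusters > matrix.n_proteins:
        raise ConfigError(
            f"cannot form {n_clusters} clusters from {matrix.n_proteins} complete profiles"
        )
    if n_clusters == 1 or matrix.n_proteins == 1:
        labels = np.ones(matrix.n_proteins, dtype=int)
    else:
        tree = linkage(matrix.values, method="ward", metric="euclidean")
        labels = fcluster(tree, t=n_clusters, criterion="maxclust")
    assignment = {pid: int(lab) for pid, lab in zip(matrix.protein_ids, labels)}

    result = ClusterResult(assignment=assignment, n_clusters=int(labels.max(initial=1)))
    times = np.asarray(matrix.times_h, dtype=float)
    for label in sorted(set(labels.tolist())):
        member_rows = matrix.values[labels == label]
        t50, grid, smoothed = _cluster_summary(member_rows, times, span, degree)
        result.curves[int(label)] = (grid, smoothed)
        result.t50_h[int(label)] = t50
    return result


def smooth_conditional_mean(
    x: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    span: float,
    degree: int = 2,
) -> np.ndarray:
    """Loess: local polynomial regression with tricube weights on *grid*.

    ``span`` is the fraction of points contributing at each evaluation point
    (nearest-neighbor bandwidth), the usual loess convention. The default
    degree 2 matches the loess behind ggplot-style smoothed conditional
    means; degree 1 (local linear) carries a curvature bias of order
    ``f'' * h^2`` that visibly shifts crossing times at wide spans.
    """
    if not (0.0 < span <= 1.0):
        raise ConfigError(f"span must be in (0, 1], got {span}")
    if degree not in (1, 2):
        raise ConfigError(f"smoother degree must be 1 or 2, got {degree}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    window = min(n, max(degree + 1, int(math.ceil(span * n))))
    out = np.empty(grid.size, dtype=float)
    for i, x0 in enumerate(grid):
        d = np.abs(x - x0)
        h = np.partition(d, window - 1)[window - 1]
        if h == 0:
            out[i] = float(np.mean(y[d == 0]))
            continue
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        design = np.vander(x - x0, degree + 1, increasing=True)
        wd = design * w[:, None]
        # value at x0 is the intercept of the weighted polynomial fit
        beta, *_ = np.linalg.lstsq(wd.T @ design, wd.T @ y, rcond=None)
        out[i] = float(beta[0])
    return out


def _evaluation_grid(times: np.ndarray) -> np.ndarray:
    dense = np.linspace(times.min(), times.max(), GRID_POINTS)
    return np.unique(np.concatenate([times, dense]))


def _first_crossing(grid: np.ndarray, curve: np.ndarray, level: float = 0.5) -> float:
    """Earliest upward crossing of *level*, linearly interpolated."""
    for i in range(1, grid.size):
        if curve[i - 1] < level <= curve[i]:
            if curve[i] == curve[i - 1]:
                return float(grid[i])
            frac = (level - curve[i - 1]) / (curve[i] - curve[i - 1])
            return float(grid[i - 1] + frac * (grid[i] - grid[i - 1]))
    if curve.size and curve[0] >= level:
        return float(grid[0])
    return T50_UNDEFINED


def _cluster_summary(
    member_rows: np.ndarray, times: np.ndarray, span: float, degree: int = 2
) -> tuple[float, np.ndarray, np.ndarray]:
    x = np.tile(times, member_rows.shape[0])
    y = member_rows.ravel()
    grid = _evaluation_grid(times)
    smoothed = smooth_conditional_mean(x, y, grid, span, degree)
    return _first_crossing(grid, smoothed), grid, smoothed


def time_to_half_incorporation(
    member_profiles: np.ndarray,
    times_h: Sequence[float],
    smoother_span: float = DEFAULT_SPAN,
    degree: int = 2,
) -> float:
    """Time at which a cluster's smoothed conditional mean first reaches 50%.

    ``member_profiles`` is a (members x times) array of incorporation
    fractions. Returns NaN if the smoothed mean never crosses 0.5.
    """
    member_rows = np.atleast_2d(np.asarray(member_profiles, dtype=float))
    if member_rows.size == 0:
        raise ValueError("cluster must contain at least one profile")
    times = np.asarray(times_h, dtype=float)
    if member_rows.shape[1] != times.size:
        raise ValueError("profile width does not match number of time points")
    t50, _, _ = _cluster_summary(member_rows, times, smoother_span, degree)
    return t50
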