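"""Kernel-density maps of (distance, angle) projections with decile levels.

Each nucleus contributes one point to a 2D plane spanned by one triangle
side and one interior angle; nine such projections exist (3 distances x 3
angles).  The probability density in each plane is estimated with a
Parzen–Rosenblatt window using an isotropic Gaussian kernel of variance
``t``:

    K(x, y, t) = 1 / (2 pi t) * exp(-||x - y||^2 / (2 t))

and the plane is partitioned into ten nested levels U_1 ⊂ … ⊂ U_10, where
U_k is the highest-density region containing the fraction k/10 of the
sample.  Per-level mean and standard-deviation vectors are the summary used
to compare experiments.

Because the two axes carry incommensurate units (μm vs radians) the points
are standardized per axis before kernel evaluation; level statistics are
reported back in original units.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .dataset import TripletDataset
from .geometry import ANGLE_IDS, DISTANCE_IDS, dataset_geometry

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# kernel density


def gaussian_kernel(x: np.ndarray, y: np.ndarray, t: float) -> np.ndarray:
    """The 2D Parzen window: normalizer 1/(2πt), exponent −‖x−y‖²/(2t)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    sq = np.sum((x[:, None, :] - y[None, :, :]) ** 2, axis=-1)
    return np.exp(-sq / (2.0 * t)) / (2.0 * math.pi * t)


@dataclass
class DensityField:
    """A fitted kernel density f(x) = (1/M) Σ_m K(x, y_m, t)."""

    points: np.ndarray  # (M, d)
    bandwidth: float  # kernel variance t

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))

    @property
    def dim(self) -> int:
        return self.points.shape[1]

    def __call__(self, x: np.ndarray, chunk: int = 2048) -> np.ndarray:
        """Evaluate f at query points (n, d) -> (n,)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        t = self.bandwidth
        d = self.dim
        norm = (2.0 * math.pi * t) ** (d / 2.0)
        out = np.empty(len(x))
        for lo in range(0, len(x), chunk):
            hi = min(lo + chunk, len(x))
            sq = np.sum((x[lo:hi, None, :] - self.points[None, :, :]) ** 2, axis=-1)
            out[lo:hi] = np.exp(-sq / (2.0 * t)).sum(axis=1) / (norm * len(self.points))
        return out

    def at_points(self) -> np.ndarray:
        """Density evaluated at the sample itself (includes self-term)."""
        return self(self.points)


def scott_bandwidth(n: int, d: int = 2) -> float:
    """Scott's-rule kernel variance for a standardized d-dim sample."""
    return float(n ** (-2.0 / (d + 4)))


def estimate_density(points: np.ndarray, t: float | None = None) -> DensityField:
    """Fit the Parzen–Rosenblatt estimator; ``t`` defaults to Scott's rule.

    ``points`` should already be on commensurate axes (standardized).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    if t is None:
        t = scott_bandwidth(len(points), points.shape[1])
    elif t <= 0:
        raise ValueError(f"bandwidth t must be > 0, got {t}")
    return DensityField(points, float(t))


# ---------------------------------------------------------------------------
# decile level sets


def decile_levels(f_points: np.ndarray) -> np.ndarray:
    """Assign each point the smallest level k whose region U_k contains it.

    U_k is realized as the ⌈kM/10⌉ densest points; ranking is by f
    descending with ties broken by stable input order (logged when more
    than 1% of points tie).
    """
    f = np.asarray(f_points, dtype=float)
    M = len(f)
    order = np.argsort(-f, kind="stable")
    n_tied = M - len(np.unique(f))
    if n_tied > 0.01 * M:
        logger.info("decile_levels: %d of %d density values tie", n_tied, M)
    cards = np.array([math.ceil(k * M / 10) for k in range(1, 11)])
    positions = np.empty(M, dtype=int)
    positions[order] = np.arange(1, M + 1)
    levels = 1 + np.searchsorted(cards, positions, side="left")
    return levels.astype(int)


@dataclass
class LevelStats:
    """Per-level counts, mean vectors and SD vectors (original units).

    ``mu[k-1]`` and ``sigma[k-1]`` are taken over all points of the
    cumulative region U_k; SD uses the population divisor card_k.
    """

    card: np.ndarray  # (10,)
    mu: np.ndarray  # (10, 2)
    sigma: np.ndarray  # (10, 2)
    undefined: np.ndarray = field(default=None)  # (10,) bool

    def __post_init__(self) -> None:
        if self.undefined is None:
            self.undefined = self.card == 0


def level_statistics(points: np.ndarray, levels: np.ndarray) -> LevelStats:
    """Cumulative per-level mean/SD of the raw (de-standardized) points."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    levels = np.asarray(levels)
    card = np.zeros(10, dtype=int)
    mu = np.full((10, points.shape[1]), np.nan)
    sigma = np.full((10, points.shape[1]), np.nan)
    for k in range(1, 11):
        mask = levels <= k
        card[k - 1] = int(mask.sum())
        if card[k - 1] == 0:
            continue
        sub = points[mask]
        mu[k - 1] = sub.mean(axis=0)
        sigma[k - 1] = sub.std(axis=0, ddof=0)
    return LevelStats(card=card, mu=mu, sigma=sigma)


# ---------------------------------------------------------------------------
# full map


@dataclass
class DensityMap:
    """One fitted (distance, angle) projection with levels and statistics."""

    axis_i: str
    axis_j: str
    points_raw: np.ndarray  # (M, 2), original units
    mean: np.ndarray  # per-axis standardization mean
    scale: np.ndarray  # per-axis standardization SD
    bandwidth: float
    field: DensityField
    f_points: np.ndarray
    levels: np.ndarray
    stats: LevelStats
    grid_x: np.ndarray | None = None
    grid_y: np.ndarray | None = None
    f_grid: np.ndarray | None = None

    @property
    def M(self) -> int:
        return len(self.points_raw)


class KernelLevelMap(BaseEstimator):
    """Estimator that fits the decile level-set density map on 2D points.

    Parameters
    ----------
    bandwidth:
        Kernel variance ``t`` in standardized units; ``None`` = Scott's rule.
    standardize:
        Standardize each axis to zero mean / unit SD before kernel
        evaluation (required when axes carry different units).  External
        (mean, scale) can be injected via ``fit`` for pooled comparisons.
    grid_size:
        Lattice resolution per axis for the rendered field; the lattice is
        only for rendering and mass checks — levels are decided at the data
        points.
    grid_pad:
        Margin beyond the data range, in units of sqrt(t).

    Attributes (after ``fit``)
    --------------------------
    field_ : DensityField           fitted density
    levels_ : (M,) int              decile level of each point
    stats_ : LevelStats             per-level statistics, original units
    map_ : DensityMap               full result container
    """

    def __init__(self, bandwidth=None, standardize=True, grid_size=128, grid_pad=3.0,
                 axis_i="x", axis_j="y"):
        self.bandwidth = bandwidth
        self.standardize = standardize
        self.grid_size = grid_size
        self.grid_pad = grid_pad
        self.axis_i = axis_i
        self.axis_j = axis_j

    def fit(self, X, y=None, mean=None, scale=None, render_grid=True):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] < 10:
            raise ValueError(f"need at least 10 points for decile levels, got {X.shape[0]}")
        if X.shape[1] != 2:
            raise ValueError("X must be (M, 2)")
        if self.standardize:
            self.mean_ = np.asarray(mean, dtype=float) if mean is not None else X.mean(axis=0)
            self.scale_ = np.asarray(scale, dtype=float) if scale is not None else X.std(axis=0, ddof=0)
            if np.any(self.scale_ == 0):
                raise ValueError("an axis has zero spread; cannot standardize")
        else:
            self.mean_ = np.zeros(2)
            self.scale_ = np.ones(2)
        Z = (X - self.mean_) / self.scale_
        self.field_ = estimate_density(Z, self.bandwidth)
        self.bandwidth_ = self.field_.bandwidth
        self.f_points_ = self.field_.at_points()
        self.levels_ = decile_levels(self.f_points_)
        self.stats_ = level_statistics(X, self.levels_)
        gx = gy = fg = None
        if render_grid and self.grid_size:
            pad = self.grid_pad * math.sqrt(self.bandwidth_)
            gx = np.linspace(Z[:, 0].min() - pad, Z[:, 0].max() + pad, self.grid_size)
            gy = np.linspace(Z[:, 1].min() - pad, Z[:, 1].max() + pad, self.grid_size)
            XX, YY = np.meshgrid(gx, gy, indexing="ij")
            fg = self.field_(np.column_stack([XX.ravel(), YY.ravel()])).reshape(XX.shape)
        self.map_ = DensityMap(
            axis_i=self.axis_i, axis_j=self.axis_j, points_raw=X,
            mean=self.mean_, scale=self.scale_, bandwidth=self.bandwidth_,
            field=self.field_, f_points=self.f_points_, levels=self.levels_,
            stats=self.stats_, grid_x=gx, grid_y=gy, f_grid=fg,
        )
        return self

    def grid_mass(self) -> float:
        """Riemann-sum of the rendered lattice (≈ 1 for a generous extent)."""
        if self.map_.f_grid is None:
            raise ValueError("no grid rendered")
        dx = self.map_.grid_x[1] - self.map_.grid_x[0]
        dy = self.map_.grid_y[1] - self.map_.grid_y[0]
        return float(self.map_.f_grid.sum() * dx * dy)


def decile_regions(map_or_field) -> np.ndarray:
    """Level assignment from a fitted map or a vector of point densities."""
    if isinstance(map_or_field, DensityMap):
        return decile_levels(map_or_field.f_points)
    return decile_levels(np.asarray(map_or_field))


def build_map(
    ds: TripletDataset,
    distance_id: str,
    angle_id: str,
    bandwidth: float | None = None,
    mean: np.ndarray | None = None,
    scale: np.ndarray | None = None,
    grid_size: int = 128,
    geometry: "np.ndarray | None" = None,
) -> DensityMap:
    """Build one (distance, angle) map for a dataset.

    ``geometry`` may carry a precomputed invariant table (DataFrame from
    :func:`dataset_geometry`) to avoid recomputation across the battery.
    """
    if distance_id not in DISTANCE_IDS:
        raise ValueError(f"distance_id must be one of {DISTANCE_IDS}")
    if angle_id not in ANGLE_IDS:
        raise ValueError(f"angle_id must be one of {ANGLE_IDS}")
    geo = dataset_geometry(ds) if geometry is None else geometry
    if len(geo) < 10:
        raise ValueError(f"need at least 10 nuclei for decile maps, got {len(geo)}")
    X = np.column_stack([geo[distance_id].to_numpy(), geo[angle_id].to_numpy()])
    est = KernelLevelMap(bandwidth=bandwidth, grid_size=grid_size,
                         axis_i=distance_id, axis_j=angle_id)
    est.fit(X, mean=mean, scale=scale, render_grid=grid_size > 0)
    logger.info("build_map %s/%s: t=%.6g M=%d", distance_id, angle_id,
                est.bandwidth_, len(X))
    return est.map_


def build_all_maps(ds: TripletDataset, bandwidth: float | None = None,
                   grid_size: int = 0) -> dict[tuple[str, str], DensityMap]:
    """The full battery: nine maps, 3 distances x 3 angles."""
    geo = dataset_geometry(ds)
    return {
        (d, a): build_map(ds, d, a, bandwidth=bandwidth, grid_size=grid_size, geometry=geo)
        for d in DISTANCE_IDS
        for a in ANGLE_IDS
    }
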