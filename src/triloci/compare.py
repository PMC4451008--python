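"""Comparing two experiments' density maps and geometry distributions.

Three complementary comparisons:

- *level correlations*: per map and per decile level, ratio-of-statistics
  similarity between the two experiments.  The first approximation ρ1 is
  the product over the two axes of min/max ratios of the level means; the
  second approximation ρ2 further multiplies by the min/max ratios of the
  level SDs, so 0 ≤ ρ2 ≤ ρ1 ≤ 1.  The headline correlation factor c of a
  map is ρ1 at the 30% level (U_3): duplicate experiments of one strain
  reproduce the expected duplicate-reproducibility bound (c > 0.8) under
  ρ1 but not under the stricter ρ2, so ρ1 is the headline statistic.  ρ2
  is reported alongside everywhere.
- *3D iso-volume overlap*: highest-density regions of the (d_rg, d_rb,
  d_gb) cloud at a given mass fraction, compared by cross-membership and by
  lattice Jaccard.
- *univariate battery*: medians, IQRs and two-sided Wilcoxon rank-sum
  p-values for each of the three distances and three angles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import TripletDataset
from .density import DensityField, LevelStats, build_map, decile_levels, scott_bandwidth
from .geometry import ANGLE_IDS, DISTANCE_IDS, dataset_geometry

logger = logging.getLogger(__name__)

HEADLINE_LEVEL = 3  # the "30% contour"


@dataclass
class LevelCorrelation:
    k1: int
    k2: int
    rho1: float
    rho2: float


def _ratio(a: float, b: float) -> float:
    lo, hi = min(a, b), max(a, b)
    return lo / hi


def level_correlation(statsA: LevelStats, statsB: LevelStats, k1: int, k2: int) -> LevelCorrelation:
    """ρ1 / ρ2 between level ``k1`` of A and level ``k2`` of B.

    Means are compared in absolute value (distance and angle axes are
    positive, so this never changes sign in practice); a mean of exactly 0
    on an axis leaves the ratio undefined and raises.
    """
    for k, st, name in ((k1, statsA, "A"), (k2, statsB, "B")):
        if not 1 <= k <= 10:
            raise ValueError(f"level must be in 1..10, got {k}")
        if st.card[k - 1] == 0:
            raise ValueError(f"level {k} of experiment {name} is empty")
    muA, muB = np.abs(statsA.mu[k1 - 1]), np.abs(statsB.mu[k2 - 1])
    sigA, sigB = statsA.sigma[k1 - 1], statsB.sigma[k2 - 1]
    if np.any(muA == 0) or np.any(muB == 0):
        raise ValueError("a level mean is exactly 0 on an axis; ratio undefined")
    rho1 = _ratio(muA[0], muB[0]) * _ratio(muA[1], muB[1])
    rho2 = rho1 * _ratio(sigA[0], sigB[0]) * _ratio(sigA[1], sigB[1])
    return LevelCorrelation(k1, k2, float(rho1), float(rho2))


@dataclass
class CorrelationReport:
    """Diagonal level correlations for all nine maps.

    ``table`` has one row per (map, level): columns ``distance_id,
    angle_id, level, rho1, rho2``.  ``headline`` maps (distance_id,
    angle_id) -> c, the ρ1 at the 30% level; ρ2 at that level is kept
    alongside in ``headline_rho2``.
    """

    table: pd.DataFrame
    headline: dict
    headline_rho2: dict
    bandwidth: float

    def median_headline(self) -> float:
        return float(np.median(list(self.headline.values())))


def compare_experiments(
    dsA: TripletDataset,
    dsB: TripletDataset,
    bandwidth: float | None = None,
) -> CorrelationReport:
    """Build both nine-map batteries in a common frame and correlate levels.

    Standardization is pooled (mean/SD of the concatenated samples per
    axis) and the kernel variance is shared, so level statistics live on
    one scale and the min/max ratios are meaningful.  Refuses mismatched
    channel-to-locus maps.
    """
    if dsA.label_map != dsB.label_map:
        raise ValueError("label_maps differ; loci must correspond between experiments")
    geoA, geoB = dataset_geometry(dsA), dataset_geometry(dsB)
    if len(geoA) < 10 or len(geoB) < 10:
        raise ValueError("both experiments need at least 10 usable nuclei")
    t = bandwidth if bandwidth is not None else scott_bandwidth(
        int(round((len(geoA) + len(geoB)) / 2))
    )
    rows, headline, headline_rho2 = [], {}, {}
    for d in DISTANCE_IDS:
        for a in ANGLE_IDS:
            pooled = np.concatenate(
                [
                    np.column_stack([geoA[d], geoA[a]]),
                    np.column_stack([geoB[d], geoB[a]]),
                ]
            )
            mean, scale = pooled.mean(axis=0), pooled.std(axis=0, ddof=0)
            mapA = build_map(dsA, d, a, bandwidth=t, mean=mean, scale=scale,
                             grid_size=0, geometry=geoA)
            mapB = build_map(dsB, d, a, bandwidth=t, mean=mean, scale=scale,
                             grid_size=0, geometry=geoB)
            for k in range(1, 11):
                lc = level_correlation(mapA.stats, mapB.stats, k, k)
                rows.append((d, a, k, lc.rho1, lc.rho2))
                if k == HEADLINE_LEVEL:
                    headline[(d, a)] = lc.rho1
                    headline_rho2[(d, a)] = lc.rho2
    table = pd.DataFrame(rows, columns=["distance_id", "angle_id", "level", "rho1", "rho2"])
    return CorrelationReport(table=table, headline=headline,
                             headline_rho2=headline_rho2, bandwidth=t)


# ---------------------------------------------------------------------------
# 3D iso-volume overlap (the 50%-mass volumes of the d1/d2/d3 cloud)


@dataclass
class HDROverlap:
    mass: float
    cross_membership_a_in_b: float
    cross_membership_b_in_a: float
    jaccard: float
    threshold_a: float
    threshold_b: float


def _hdr_threshold(f_own: np.ndarray, mass: float) -> float:
    """Density threshold whose superlevel set holds ``mass`` of the points."""
    M = len(f_own)
    n_in = max(1, math.ceil(mass * M))
    return float(np.sort(f_own)[::-1][n_in - 1])


def hdr3d_overlap(
    dsA: TripletDataset,
    dsB: TripletDataset,
    mass: float = 0.5,
    grid_size: int = 32,
    bandwidth: float | None = None,
) -> HDROverlap:
    """Overlap of the two experiments' 3D highest-density iso-volumes.

    The three side lengths (d_rg, d_rb, d_gb) of each nucleus are
    standardized with pooled parameters; per experiment a 3D kernel density
    is fitted and thresholded to enclose ``mass`` of its own points.
    Reported are (a) the fraction of each experiment's HDR members that
    also fall inside the other's iso-volume and (b) the Jaccard index of
    the lattice cells above threshold.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError(f"mass must be in (0, 1), got {mass}")
    geoA, geoB = dataset_geometry(dsA), dataset_geometry(dsB)
    XA = geoA[list(DISTANCE_IDS)].to_numpy()
    XB = geoB[list(DISTANCE_IDS)].to_numpy()
    pooled = np.concatenate([XA, XB])
    mean, scale = pooled.mean(axis=0), pooled.std(axis=0, ddof=0)
    ZA, ZB = (XA - mean) / scale, (XB - mean) / scale
    t = bandwidth if bandwidth is not None else scott_bandwidth(
        int(round((len(ZA) + len(ZB)) / 2)), d=3
    )
    fA, fB = DensityField(ZA, t), DensityField(ZB, t)
    fA_at_A, fB_at_B = fA.at_points(), fB.at_points()
    thrA, thrB = _hdr_threshold(fA_at_A, mass), _hdr_threshold(fB_at_B, mass)
    memA = fA_at_A >= thrA  # A's own HDR members
    memB = fB_at_B >= thrB
    a_in_b = float(np.mean(fB(ZA[memA]) >= thrB)) if memA.any() else float("nan")
    b_in_a = float(np.mean(fA(ZB[memB]) >= thrA)) if memB.any() else float("nan")
    pad = 3.0 * math.sqrt(t)
    axes = [
        np.linspace(pooled_z.min() - pad, pooled_z.max() + pad, grid_size)
        for pooled_z in np.concatenate([ZA, ZB]).T
    ]
    G = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    inA, inB = fA(G) >= thrA, fB(G) >= thrB
    union = np.logical_or(inA, inB).sum()
    jac = float(np.logical_and(inA, inB).sum() / union) if union else 0.0
    return HDROverlap(mass, a_in_b, b_in_a, jac, thrA, thrB)


# ---------------------------------------------------------------------------
# univariate battery


def _wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p-value; exact below n=25 per group when tie-free."""
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) < 25 and len(b) < 25 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def pairwise_tests(dsA: TripletDataset, dsB: TripletDataset) -> pd.DataFrame:
    """Medians, IQRs and Wilcoxon p-values for each distance and angle.

    Angles are reported in degrees (the convention of the boxplot panels);
    p-values are raw — no multiple-testing correction is applied across the
    six variables.
    """
    geoA, geoB = dataset_geometry(dsA), dataset_geometry(dsB)
    rows = []
    for var in [*DISTANCE_IDS, *ANGLE_IDS]:
        a, b = geoA[var].to_numpy(), geoB[var].to_numpy()
        unit = "um"
        if var in ANGLE_IDS:
            a, b = np.degrees(a), np.degrees(b)
            unit = "deg"
        qa, qb = np.percentile(a, [25, 50, 75]), np.percentile(b, [25, 50, 75])
        rows.append(
            {
                "variable": var,
                "unit": unit,
                "median_a": qa[1],
                "median_b": qb[1],
                "iqr_a": qa[2] - qa[0],
                "iqr_b": qb[2] - qb[0],
                "p_value": _wilcoxon_rank_sum(a, b),
            }
        )
    return pd.DataFrame(rows)
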