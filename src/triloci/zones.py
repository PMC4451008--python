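"""Survival-zone polymer model and its inverse problem.

The abstract model represents each of the three linked loci as a node
roaming uniformly and independently inside a planar rectangle, the node's
*survival zone*.  A zone is parameterized by its center and two half-widths
(ε1, ε2).  Sampling one point per zone yields an *abstract configuration*
of the polymer; many configurations yield, per node, the 3x3 correlation
matrix of the local variables (d_i1, d_i2, θ_i) via normalized PCA.

The inverse problem: fix the zone centers from the experimental mean
inter-locus distances (node 1 at (0,0), node 3 at (5,0), node 2 at the
intersection of two circles whose radii conserve the distance proportions),
then search the six half-widths over a grid on [0;5] for the candidate
minimizing the summed Frobenius distance between experimental and abstract
per-node correlation matrices.  The publication-scale grid (step 0.2, zero
excluded) has 25^6 = 5^12 candidates; desk-scale runs use coarser grids.

Sampling uses common random numbers: one fixed set of uniform draws is
rescaled to every candidate's rectangles, so the objective surface is
smooth in ε and the argmin is reproducible and scheduling-independent.

Because the objective is a Monte-Carlo estimate, candidates within its
sampling noise of the minimum are statistically indistinguishable; the
solver resolves this equivalence class by the definition of a survival
zone as the *smallest* region compatible with the data: it selects, among
candidates whose objective lies within ``parsimony_z`` noise SDs of the
minimum, the one with the smallest total zone area (then lexicographically
smallest ε).  Setting ``parsimony_z=0`` recovers the raw argmin.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from joblib import Parallel, delayed
from sklearn.base import BaseEstimator

from .dataset import TripletDataset
from .errors import DegenerateInputError
from .geometry import dataset_geometry, node_variable_table, triangle_variables
from .io import qc_filter

logger = logging.getLogger(__name__)

BASE_INTERVAL = (0.0, 5.0)  # the base interval D for the half-widths
NODE_SCALE = 5.0  # node 1 at (0,0), node 3 at (NODE_SCALE, 0)

NODE_VAR_NAMES = ("d_i1", "d_i2", "theta_i")


# ---------------------------------------------------------------------------
# model containers


@dataclass
class SurvivalZone:
    """Rectangle [cx−ε1, cx+ε1] x [cy−ε2, cy+ε2] in model units."""

    center: np.ndarray
    eps1: float
    eps2: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.center.shape != (2,):
            raise ValueError("center must be a 2-vector")
        if self.eps1 < 0 or self.eps2 < 0:
            raise ValueError("half-widths must be >= 0")

    @property
    def area(self) -> float:
        return 4.0 * self.eps1 * self.eps2

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return (np.abs(pts[:, 0] - self.center[0]) <= self.eps1 + 1e-12) & (
            np.abs(pts[:, 1] - self.center[1]) <= self.eps2 + 1e-12
        )


@dataclass
class SurvivalZoneModel:
    """Exactly three zones (nodes 1, 2, 3) plus center provenance."""

    zones: Sequence[SurvivalZone]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.zones = list(self.zones)
        if len(self.zones) != 3:
            raise ValueError("a model has exactly 3 zones")

    @property
    def centers(self) -> np.ndarray:
        return np.stack([z.center for z in self.zones])

    @property
    def eps(self) -> np.ndarray:
        """(ε1^1, ε2^1, ε1^2, ε2^2, ε1^3, ε2^3)."""
        return np.array([v for z in self.zones for v in (z.eps1, z.eps2)])

    @property
    def total_area(self) -> float:
        return float(sum(z.area for z in self.zones))

    @classmethod
    def from_eps(cls, centers: np.ndarray, eps: np.ndarray, provenance=None) -> "SurvivalZoneModel":
        centers = np.asarray(centers, dtype=float)
        eps = np.asarray(eps, dtype=float)
        zones = [SurvivalZone(centers[i], eps[2 * i], eps[2 * i + 1]) for i in range(3)]
        return cls(zones, provenance or {})


@dataclass
class ConfigurationSet:
    """M' sampled polymer placements, one 2D point per zone."""

    configs: np.ndarray  # (M', 3, 2)
    seed: int | None = None

    @property
    def M(self) -> int:
        return self.configs.shape[0]


@dataclass
class NodeCorrelation:
    """Correlation matrix of (d_i1, d_i2, θ_i) and its eigenvalues."""

    node_index: int
    C: np.ndarray  # (3, 3)
    P: np.ndarray  # eigenvalues, descending


# ---------------------------------------------------------------------------
# normalized PCA


def pca_norm(samples: np.ndarray, node_index: int = 0) -> NodeCorrelation:
    """Normalized PCA of an (M, 3) table: correlation matrix + eigenvalues.

    Columns are standardized to zero mean / unit SD, so the covariance of
    the standardized table is the correlation matrix; eigenvalues sum to 3.
    """
    X = np.asarray(samples, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError(f"samples must be (M, 3), got {X.shape}")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    sd = X.std(axis=0, ddof=0)
    for j, s in enumerate(sd):
        if s == 0.0:
            raise DegenerateInputError(
                f"column {NODE_VAR_NAMES[j]!r} has zero variance"
            )
    Z = (X - X.mean(axis=0)) / sd
    C = (Z.T @ Z) / X.shape[0]
    np.fill_diagonal(C, 1.0)
    eig = np.linalg.eigvalsh(C)[::-1]
    return NodeCorrelation(node_index, C, eig)


def experimental_correlations(geometry_values: np.ndarray) -> list[NodeCorrelation]:
    """Per-node correlations from an (M, 6) invariant table."""
    out = []
    for i in (1, 2, 3):
        nc = pca_norm(node_variable_table(geometry_values, i), node_index=i)
        out.append(nc)
    return out


# ---------------------------------------------------------------------------
# center fixing (conservation of distance proportions)


def fix_centers(mean_d12: float, mean_d23: float, mean_d13: float) -> SurvivalZoneModel:
    """Zone centers from the three experimental mean distances.

    Node 1 sits at (0,0) and node 3 at (5,0); the model scale maps the
    mean 1–3 distance onto 5 model units.  Node 2 is placed at the
    intersection (with non-negative y) of the circle of radius
    r0 = 5·mean_d12/mean_d13 around node 1 and the circle of radius
    r1 = 5·mean_d23/mean_d13 around node 3.  If the mean-distance triangle
    inequality fails the node is placed collinearly at (clamped x, 0) with
    a warning.  Returned zones have zero half-widths (centers only).
    """
    for name, v in (("mean_d12", mean_d12), ("mean_d23", mean_d23), ("mean_d13", mean_d13)):
        if not v > 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    r0 = NODE_SCALE * mean_d12 / mean_d13
    r1 = NODE_SCALE * mean_d23 / mean_d13
    x = (r0**2 - r1**2 + NODE_SCALE**2) / (2.0 * NODE_SCALE)
    y_sq = r0**2 - x**2
    if y_sq < 0:
        logger.warning(
            "fix_centers: mean distances violate the triangle inequality; "
            "placing node 2 collinearly"
        )
        x = float(np.clip(x, 0.0, NODE_SCALE))
        y = 0.0
    else:
        y = math.sqrt(y_sq)
    centers = np.array([[0.0, 0.0], [x, y], [NODE_SCALE, 0.0]])
    return SurvivalZoneModel.from_eps(
        centers, np.zeros(6), provenance={"r0": r0, "r1": r1}
    )


# ---------------------------------------------------------------------------
# forward sampling and objective


def sample_configurations(model: SurvivalZoneModel, m_configs: int, seed=None) -> ConfigurationSet:
    """Draw M' abstract configurations, one uniform point per rectangle."""
    if m_configs < 1:
        raise ValueError("m_configs must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.uniform(-1.0, 1.0, size=(m_configs, 3, 2))
    eps = model.eps.reshape(3, 2)
    configs = model.centers[None, :, :] + eps[None, :, :] * u
    return ConfigurationSet(configs, seed=seed if isinstance(seed, int) else None)


def _node_tables(configs: np.ndarray) -> np.ndarray:
    """(M', 6) invariant table of the planar configurations."""
    return triangle_variables(configs)


def abstract_correlations(configs: ConfigurationSet) -> list[NodeCorrelation]:
    """Per-node correlations of the abstract system."""
    return experimental_correlations(_node_tables(configs.configs))


def model_objective(expC: Sequence[NodeCorrelation], configs: ConfigurationSet) -> float:
    """Σ_i ‖C_i − C_i^a‖_Frobenius over the three nodes.

    Raises :class:`DegenerateInputError` when the abstract geometry has a
    zero-variance local variable (the candidate is then rejected upstream).
    """
    absC = abstract_correlations(configs)
    return float(
        sum(np.linalg.norm(e.C - a.C, ord="fro") for e, a in zip(expC, absC))
    )


# ---------------------------------------------------------------------------
# grid search


def default_grid(step: float = 0.2, lo: float | None = None, hi: float | None = None) -> list[np.ndarray]:
    """Per-parameter ε values: {step, 2·step, …, 5.0}; zero excluded.

    The default step 0.2 on [0;5] gives 25 values per parameter, hence
    25^6 = 5^12 candidates over the six half-widths.
    """
    lo = step if lo is None else lo
    hi = BASE_INTERVAL[1] if hi is None else hi
    n = int(round((hi - lo) / step)) + 1
    values = lo + step * np.arange(n)
    return [values.copy() for _ in range(6)]


def grid_size(grid: Sequence[np.ndarray]) -> int:
    """Number of candidates = product of per-parameter value counts."""
    if len(grid) != 6:
        raise ValueError("grid spec must have 6 parameter axes")
    size = 1
    for axis in grid:
        n = len(np.asarray(axis))
        if n == 0:
            raise ValueError("empty grid axis")
        size *= n
    return size


@dataclass
class SolverResult:
    best_eps: np.ndarray
    best_objective: float
    model: SurvivalZoneModel
    exp_correlations: list
    grid: list
    evaluations: int
    m_configs: int
    seed: int | None
    rejected: int = 0
    min_objective: float = float("nan")  # raw grid minimum (before parsimony)
    noise_sd: float = float("nan")  # Monte-Carlo SD of the objective
    table: "np.ndarray | None" = None  # optional (G, 7) [eps..., objective]

    def to_dict(self) -> dict:
        return {
            "best_eps": [float(v) for v in self.best_eps],
            "best_objective": self.best_objective,
            "min_objective": self.min_objective,
            "noise_sd": self.noise_sd,
            "centers": self.model.centers.tolist(),
            "r0": self.model.provenance.get("r0"),
            "r1": self.model.provenance.get("r1"),
            "grid": [list(map(float, ax)) for ax in self.grid],
            "evaluations": self.evaluations,
            "m_configs": self.m_configs,
            "seed": self.seed,
            "rejected": self.rejected,
        }


def _objective_chunk(eps_chunk: np.ndarray, centers: np.ndarray, U: np.ndarray,
                     expC: np.ndarray) -> np.ndarray:
    """Vectorized objective for a (B, 6) chunk of candidates.

    ``U`` is the common (M', 3, 2) uniform(-1,1) draw shared by every
    candidate; ``expC`` is the stacked (3, 3, 3) experimental matrices.
    Candidates whose abstract geometry degenerates (zero variance in any
    local variable) receive +inf.
    """
    B = eps_chunk.shape[0]
    M = U.shape[0]
    eps = eps_chunk.reshape(B, 1, 3, 2)
    pts = centers[None, None, :, :] + eps * U[None, :, :, :]  # (B, M, 3, 2)
    v = triangle_variables(pts)  # (B, M, 6)
    out = np.empty(B)
    for b in range(B):
        total = 0.0
        for i in (1, 2, 3):
            X = node_variable_table(v[b], i)
            sd = X.std(axis=0, ddof=0)
            if np.any(sd == 0.0):
                total = np.inf
                break
            Z = (X - X.mean(axis=0)) / sd
            C = (Z.T @ Z) / M
            np.fill_diagonal(C, 1.0)
            total += np.linalg.norm(C - expC[i - 1], ord="fro")
        out[b] = total
    return out


def _reduce_best(objectives: np.ndarray, eps_batch: np.ndarray):
    """Deterministic argmin with lexicographic tie-break on the ε vector."""
    best_obj = np.inf
    best_eps = None
    for obj, eps in zip(objectives, eps_batch):
        key = (obj, tuple(eps))
        if best_eps is None or key < (best_obj, tuple(best_eps)):
            best_obj, best_eps = obj, eps
    return best_obj, best_eps


class SurvivalZoneEstimator(BaseEstimator):
    """Grid-search fit of the three survival zones to a triplet dataset.

    Parameters
    ----------
    grid:
        Sequence of six value arrays (one per half-width); ``None`` uses a
        desk-scale 5-value grid {1, 2, 3, 4, 5}.  The publication-scale
        default (``default_grid()``) enumerates 5^12 candidates and is not
        meant for a single workstation.
    m_configs:
        Abstract configurations per candidate (common random numbers).
    seed:
        Seed of the shared uniform draw.
    workers:
        Parallel workers over grid chunks; any worker count yields a
        bit-identical result (global argmin with lexicographic tie-break).
    chunk_size:
        Candidates per vectorized evaluation chunk.
    keep_table:
        Retain the full per-candidate objective table.
    parsimony_z:
        Width of the noise band (in Monte-Carlo SDs of the objective at the
        argmin) within which the smallest-total-area candidate is selected;
        0 disables the second pass and returns the raw argmin.
    noise_repeats:
        Re-evaluations of the argmin candidate (fresh uniform draws) used
        to estimate the objective's Monte-Carlo SD.
    qc_max_pair_distance:
        QC threshold applied before fitting (μm).

    Attributes (after ``fit``)
    --------------------------
    model_ : SurvivalZoneModel     fitted zones (centers + best half-widths)
    result_ : SolverResult         full solver record
    best_eps_, objective_          convenience views
    """

    def __init__(self, grid=None, m_configs=10_000, seed=0, workers=1,
                 chunk_size=64, keep_table=False, parsimony_z=2.0,
                 noise_repeats=5, qc_max_pair_distance=2.5):
        self.grid = grid
        self.m_configs = m_configs
        self.seed = seed
        self.workers = workers
        self.chunk_size = chunk_size
        self.keep_table = keep_table
        self.parsimony_z = parsimony_z
        self.noise_repeats = noise_repeats
        self.qc_max_pair_distance = qc_max_pair_distance

    def fit(self, X, y=None):
        """``X`` is a TripletDataset or an (M, 6) invariant table."""
        if isinstance(X, TripletDataset):
            ds, _ = qc_filter(X, max_pair_distance=self.qc_max_pair_distance)
            geo = dataset_geometry(ds)
            values = geo[["d_rg", "d_rb", "d_gb", "theta_r", "theta_g", "theta_b"]].to_numpy()
        else:
            values = np.asarray(X, dtype=float)
            if values.ndim != 2 or values.shape[1] != 6:
                raise ValueError("X must be a TripletDataset or an (M, 6) invariant table")
        grid = self.grid if self.grid is not None else [np.arange(1.0, 6.0)] * 6
        grid = [np.asarray(ax, dtype=float) for ax in grid]
        n_cand = grid_size(grid)

        # centers from mean distances: d12 = d_rg, d23 = d_gb, d13 = d_rb
        mean_d12 = float(values[:, 0].mean())
        mean_d13 = float(values[:, 1].mean())
        mean_d23 = float(values[:, 2].mean())
        centered = fix_centers(mean_d12, mean_d23, mean_d13)
        expC_list = experimental_correlations(values)
        expC = np.stack([nc.C for nc in expC_list])

        rng = np.random.default_rng(self.seed)
        U = rng.uniform(-1.0, 1.0, size=(self.m_configs, 3, 2))
        centers = centered.centers

        def chunks():
            buf = []
            for cand in itertools.product(*grid):
                buf.append(cand)
                if len(buf) == self.chunk_size:
                    yield np.array(buf)
                    buf = []
            if buf:
                yield np.array(buf)

        def run_pass(eval_chunk):
            if self.workers and self.workers > 1:
                return Parallel(n_jobs=self.workers)(
                    delayed(eval_chunk)(c) for c in chunks()
                )
            return [eval_chunk(c) for c in chunks()]

        # pass 1: global minimum of the common-random-numbers objective
        def eval_min(eps_chunk):
            obj = _objective_chunk(eps_chunk, centers, U, expC)
            local_obj, local_eps = _reduce_best(obj, eps_chunk)
            table = np.column_stack([eps_chunk, obj]) if self.keep_table else None
            return local_obj, local_eps, int(np.isinf(obj).sum()), table

        min_obj, min_eps, rejected = np.inf, None, 0
        tables = []
        for local_obj, local_eps, local_rej, table in run_pass(eval_min):
            rejected += local_rej
            if table is not None:
                tables.append(table)
            if local_eps is None:
                continue
            if min_eps is None or (local_obj, tuple(local_eps)) < (min_obj, tuple(min_eps)):
                min_obj, min_eps = local_obj, local_eps
        if min_eps is None or not np.isfinite(min_obj):
            raise RuntimeError("every grid candidate was rejected as degenerate")

        # Monte-Carlo SD of the objective at the argmin (fresh uniform draws)
        noise_sd = float("nan")
        best_obj, best_eps = float(min_obj), np.asarray(min_eps, dtype=float)
        if self.parsimony_z > 0 and self.noise_repeats >= 2:
            children = np.random.SeedSequence(self.seed).spawn(self.noise_repeats)
            revals = []
            for child in children:
                U2 = np.random.default_rng(child).uniform(-1.0, 1.0, size=U.shape)
                revals.append(_objective_chunk(best_eps[None, :], centers, U2, expC)[0])
            noise_sd = float(np.std(revals, ddof=1))
            tol = self.parsimony_z * noise_sd

            # pass 2: smallest total zone area within the noise band
            def area_of(eps):
                return 4.0 * (eps[..., 0] * eps[..., 1] + eps[..., 2] * eps[..., 3]
                              + eps[..., 4] * eps[..., 5])

            def eval_parsimony(eps_chunk):
                obj = _objective_chunk(eps_chunk, centers, U, expC)
                ok = obj <= min_obj + tol
                if not ok.any():
                    return None
                areas = area_of(eps_chunk[ok])
                sub_eps, sub_obj = eps_chunk[ok], obj[ok]
                best = None
                for a, e, o in zip(areas, sub_eps, sub_obj):
                    key = (a, tuple(e))
                    if best is None or key < best[0]:
                        best = (key, e, o)
                return best

            chosen = None
            for local in run_pass(eval_parsimony):
                if local is None:
                    continue
                if chosen is None or local[0] < chosen[0]:
                    chosen = local
            if chosen is not None:
                best_eps, best_obj = np.asarray(chosen[1], dtype=float), float(chosen[2])

        self.model_ = SurvivalZoneModel.from_eps(centers, best_eps, centered.provenance)
        self.result_ = SolverResult(
            best_eps=best_eps,
            best_objective=best_obj,
            model=self.model_,
            exp_correlations=expC_list,
            grid=grid,
            evaluations=n_cand,
            m_configs=self.m_configs,
            seed=self.seed,
            rejected=rejected,
            min_objective=float(min_obj),
            noise_sd=noise_sd,
            table=np.concatenate(tables) if tables else None,
        )
        self.best_eps_ = self.result_.best_eps
        self.objective_ = self.result_.best_objective
        logger.info(
            "solve_zones: %d candidates, best objective %.6g at eps=%s",
            n_cand, best_obj, np.array2string(self.best_eps_, precision=3),
        )
        return self

    def score(self, X=None, y=None) -> float:
        """Negative objective (sklearn convention: larger is better)."""
        return -self.objective_


def solve_zones(ds, grid=None, m_configs=10_000, seed=0, workers=1, **kwargs) -> SolverResult:
    """Functional wrapper over :class:`SurvivalZoneEstimator`."""
    est = SurvivalZoneEstimator(grid=grid, m_configs=m_configs, seed=seed,
                                workers=workers, **kwargs)
    est.fit(ds)
    return est.result_
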