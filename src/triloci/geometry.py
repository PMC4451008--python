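"""Frame-invariant triangle variables of three tagged loci.

Nine microscope-frame coordinates per nucleus are reduced to six invariants
— the three side lengths and the three interior angles of the triangle
formed by the loci — which do not depend on the (arbitrary) orientation and
position of the nucleus under the objective.  Angles are stored in radians;
reports render degrees.

Node convention: node 1 = channel r, node 2 = g, node 3 = b.  Around node
``i`` the local variables are the two adjacent sides, in the closed-polygon
order (``d_i1`` the side leaving node i forward, ``d_i2`` the side arriving
at it), plus the interior angle ``theta_i``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .dataset import TripletDataset
from .errors import DegenerateGeometryError

logger = logging.getLogger(__name__)

DISTANCE_IDS = ("d_rg", "d_rb", "d_gb")
ANGLE_IDS = ("theta_r", "theta_g", "theta_b")

GEOMETRY_COLUMNS = ["nucleus_id", *DISTANCE_IDS, *ANGLE_IDS]


@dataclass
class GeometricState:
    """Invariant triangle variables of one nucleus (μm, radians)."""

    nucleus_id: str
    d_rg: float
    d_rb: float
    d_gb: float
    theta_r: float
    theta_g: float
    theta_b: float


@dataclass
class NodeVariables:
    """The two adjacent side lengths and interior angle around one node."""

    node_index: int
    d_i1: float
    d_i2: float
    theta_i: float


def triangle_variables(points: np.ndarray) -> np.ndarray:
    """Vectorized invariants for triangles in any ambient dimension.

    Parameters
    ----------
    points:
        Array of shape ``(..., 3, dim)``: the three vertices (r, g, b order)
        of each triangle.

    Returns
    -------
    Array of shape ``(..., 6)``: ``d_rg, d_rb, d_gb, theta_r, theta_g,
    theta_b``.  The arccos argument is clamped to [-1, 1], so collinear
    triangles yield angles of exactly 0 or π rather than NaN.
    """
    points = np.asarray(points, dtype=float)
    p_r, p_g, p_b = points[..., 0, :], points[..., 1, :], points[..., 2, :]
    v_rg = p_g - p_r
    v_rb = p_b - p_r
    v_gb = p_b - p_g
    d_rg = np.linalg.norm(v_rg, axis=-1)
    d_rb = np.linalg.norm(v_rb, axis=-1)
    d_gb = np.linalg.norm(v_gb, axis=-1)

    def angle(u, v, nu, nv):
        # degenerate triangles yield NaN here and are filtered by callers
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.sum(u * v, axis=-1) / (nu * nv)
        return np.arccos(np.clip(c, -1.0, 1.0))

    theta_r = angle(v_rg, v_rb, d_rg, d_rb)
    theta_g = angle(-v_rg, v_gb, d_rg, d_gb)
    theta_b = angle(-v_rb, -v_gb, d_rb, d_gb)
    return np.stack([d_rg, d_rb, d_gb, theta_r, theta_g, theta_b], axis=-1)


def triangle_geometry(t) -> GeometricState:
    """Invariants of one nucleus; raises on coincident spots.

    ``t`` is a :class:`~triloci.dataset.NucleusTriplet` or a (3, 3) array.
    """
    points = t.points if hasattr(t, "points") else np.asarray(t, dtype=float)
    nid = getattr(t, "nucleus_id", "")
    pairs = (("r", "g", 0, 1), ("r", "b", 0, 2), ("g", "b", 1, 2))
    for a, b, i, j in pairs:
        if np.linalg.norm(points[i] - points[j]) == 0.0:
            raise DegenerateGeometryError(
                f"nucleus {nid!r}: channels {a!r} and {b!r} coincide"
            )
    v = triangle_variables(points)
    return GeometricState(nid, *map(float, v))


def node_variables(s: GeometricState, i: int) -> NodeVariables:
    """Local variables around node ``i`` (1=r, 2=g, 3=b)."""
    sides = {("1", "2"): s.d_rg, ("2", "3"): s.d_gb, ("3", "1"): s.d_rb}
    thetas = {1: s.theta_r, 2: s.theta_g, 3: s.theta_b}
    if i == 1:
        return NodeVariables(1, sides[("1", "2")], sides[("3", "1")], thetas[1])
    if i == 2:
        return NodeVariables(2, sides[("2", "3")], sides[("1", "2")], thetas[2])
    if i == 3:
        return NodeVariables(3, sides[("3", "1")], sides[("2", "3")], thetas[3])
    raise ValueError(f"node index must be 1, 2 or 3, got {i}")


# column picks for (d_i1, d_i2, theta_i) out of the 6-column invariant array
_NODE_COLUMNS = {1: (0, 1, 3), 2: (2, 0, 4), 3: (1, 2, 5)}


def node_variable_table(values: np.ndarray, i: int) -> np.ndarray:
    """(M, 3) table of (d_i1, d_i2, theta_i) from an (M, 6) invariant array."""
    if i not in _NODE_COLUMNS:
        raise ValueError(f"node index must be 1, 2 or 3, got {i}")
    return np.asarray(values)[:, list(_NODE_COLUMNS[i])]


def dataset_geometry(ds: TripletDataset) -> pd.DataFrame:
    """Per-nucleus invariant table; degenerate nuclei are skipped and logged.

    Columns: ``nucleus_id, d_rg, d_rb, d_gb, theta_r, theta_g, theta_b``
    (distances μm, angles radians), order preserved.
    """
    if ds.M == 0:
        raise ValueError("dataset is empty")
    v = triangle_variables(ds.coords)
    ok = np.all(v[:, :3] > 0.0, axis=1)
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.info("dataset_geometry: skipped %d degenerate nuclei", n_skipped)
    df = pd.DataFrame(v[ok], columns=[*DISTANCE_IDS, *ANGLE_IDS])
    df.insert(0, "nucleus_id", [ds.nucleus_ids[i] for i in np.flatnonzero(ok)])
    return df


def geometry_table_tsv(geo: pd.DataFrame, path) -> None:
    """Export with angles in degrees, as rendered in reports."""
    out = geo[["nucleus_id", *DISTANCE_IDS]].copy()
    for a in ANGLE_IDS:
        out[a + "_deg"] = np.degrees(geo[a])
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


class TriangleFeatures(TransformerMixin, BaseEstimator):
    """Transformer from raw 9-coordinate rows to the 6 triangle invariants.

    Input rows are ``(x_r, y_r, z_r, x_g, y_g, z_g, x_b, y_b, z_b)``; output
    columns are ``d_rg, d_rb, d_gb, theta_r, theta_g, theta_b``.  Stateless
    (``fit`` only validates), so it composes with sklearn pipelines.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 9:
            raise ValueError(f"X must be (n_samples, 9), got {X.shape}")
        self.n_features_in_ = 9
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 9:
            raise ValueError(f"X must be (n_samples, 9), got {X.shape}")
        return triangle_variables(X.reshape(-1, 3, 3))

    def get_feature_names_out(self, input_features=None):
        return np.array([*DISTANCE_IDS, *ANGLE_IDS])
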