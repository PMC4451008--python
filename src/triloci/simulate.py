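"""Synthetic triplet datasets with the structure the analysis assumes.

Two generators:

- :func:`simulate_from_zones` takes the survival-zone model literally as a
  generative process: per nucleus one planar configuration is drawn (one
  uniform point per zone), lifted to 3D (z = 0), rigidly embedded in a
  random microscope frame (uniform rotation + translation), optionally
  blurred with Gaussian localization noise, and scaled to micrometers.
- :func:`random_sphere_dataset` is the null control: three loci placed
  independently and uniformly inside a sphere (default 2 μm diameter, the
  size of a yeast nucleus).

Both are exactly reproducible from their seed and emit the canonical
:class:`~triloci.dataset.TripletDataset`, so every downstream stage is
testable without any experimental input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .dataset import DEFAULT_LABEL_MAP, TripletDataset
from .zones import SurvivalZone, SurvivalZoneModel, sample_configurations

#: model-unit -> micrometer factor: maps the 0–5 model span (~0.9 μm) into
#: a 2 μm nucleus.
DEFAULT_SCALE = 0.18

#: side of the cubic box (μm) in which random frame translations are drawn
DEFAULT_TRANSLATION_BOX = 2.0


@dataclass
class SimulationSpec:
    """Full recipe for one synthetic dataset (the recovery ground truth)."""

    model: SurvivalZoneModel
    n: int
    seed: int
    scale: float = DEFAULT_SCALE
    noise_sd: float = 0.0  # model units, lateral
    z_noise_factor: float = 1.0  # z SD multiplier (2.0 mimics focal stepping)
    translation_box: float = DEFAULT_TRANSLATION_BOX
    randomize_frames: bool = True
    strain_id: str = "synthetic"
    label_map: dict = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")

    def to_dict(self) -> dict:
        return {
            "centers": self.model.centers.tolist(),
            "eps": self.model.eps.tolist(),
            "n": self.n,
            "seed": self.seed,
            "scale": self.scale,
            "noise_sd": self.noise_sd,
            "z_noise_factor": self.z_noise_factor,
            "translation_box": self.translation_box,
            "randomize_frames": self.randomize_frames,
            "strain_id": self.strain_id,
            "label_map": self.label_map,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _random_rotations(rng: np.random.Generator, n: int) -> np.ndarray:
    """(n, 3, 3) rotation matrices uniform over SO(3) (quaternion method)."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return Rotation.from_quat(q).as_matrix()


def simulate_from_zones(spec: SimulationSpec) -> TripletDataset:
    """Generate a triplet dataset from a survival-zone model."""
    rng = np.random.default_rng(spec.seed)
    configs = sample_configurations(spec.model, spec.n, seed=rng).configs  # (n, 3, 2)
    pts = np.zeros((spec.n, 3, 3))
    pts[:, :, :2] = configs * spec.scale
    if spec.noise_sd > 0:
        sd = np.array([1.0, 1.0, spec.z_noise_factor]) * spec.noise_sd * spec.scale
        pts += rng.normal(size=pts.shape) * sd
    if spec.randomize_frames:
        R = _random_rotations(rng, spec.n)
        t = rng.uniform(0.0, spec.translation_box, size=(spec.n, 1, 3))
        pts = np.einsum("nij,ncj->nci", R, pts) + t
    ids = [f"sim{k:05d}" for k in range(spec.n)]
    return TripletDataset(pts, ids, dict(spec.label_map), spec.strain_id)


def random_sphere_dataset(
    n: int,
    diameter: float = 2.0,
    seed: int | None = None,
    strain_id: str = "random-sphere",
) -> TripletDataset:
    """Null control: three loci uniform and independent in a sphere (μm)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    rng = np.random.default_rng(seed)
    radius = diameter / 2.0
    directions = rng.normal(size=(n, 3, 3))
    directions /= np.linalg.norm(directions, axis=-1, keepdims=True)
    r = radius * rng.uniform(size=(n, 3, 1)) ** (1.0 / 3.0)
    pts = directions * r
    ids = [f"sph{k:05d}" for k in range(n)]
    return TripletDataset(pts, ids, dict(DEFAULT_LABEL_MAP), strain_id)


def apply_random_frames(ds: TripletDataset, seed: int | None = None,
                        translation_box: float = DEFAULT_TRANSLATION_BOX) -> TripletDataset:
    """Re-embed every nucleus in a fresh random rigid frame.

    One shared rotation + translation per nucleus, so all invariant
    geometry is preserved exactly.
    """
    rng = np.random.default_rng(seed)
    R = _random_rotations(rng, ds.M)
    t = rng.uniform(0.0, translation_box, size=(ds.M, 1, 3))
    pts = np.einsum("nij,ncj->nci", R, ds.coords) + t
    return TripletDataset(pts, list(ds.nucleus_ids), dict(ds.label_map), ds.strain_id)


# ---------------------------------------------------------------------------
# reference constraint regimes


def constraint_regimes() -> dict[str, SurvivalZoneModel]:
    """Three constraint regimes of the zone model.

    The *moderate* regime uses the reference rectangles
    Z1=[-1;1]x[-1;1], Z2=[-1;5]x[-1;5], Z3=[3.5;6.5]x[-1.5;1.5]; the
    flexible and constrained regimes keep the same centers and scale the
    half-widths up (x1.5, staying inside the base interval [0;5]) and down
    (x0.5) respectively, so zone areas are strictly ordered
    flexible > moderate > constrained at every node.
    """
    centers = np.array([[0.0, 0.0], [2.0, 2.0], [5.0, 0.0]])
    moderate_eps = np.array([1.0, 1.0, 3.0, 3.0, 1.5, 1.5])
    return {
        "flexible": SurvivalZoneModel.from_eps(centers, 1.5 * moderate_eps),
        "moderate": SurvivalZoneModel.from_eps(centers, moderate_eps),
        "constrained": SurvivalZoneModel.from_eps(centers, 0.5 * moderate_eps),
    }
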