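"""In-memory containers for per-nucleus three-channel spot coordinates.

A *nucleus triplet* is the 3D position (micrometers, microscope frame) of the
three fluorescently tagged loci of one nucleus, one point per color channel
(``r``, ``g``, ``b``).  A :class:`TripletDataset` is an ordered collection of
such triplets together with the channel-to-locus naming (e.g. ``r -> HML``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

CHANNELS = ("r", "g", "b")

DEFAULT_LABEL_MAP = {"r": "HML", "g": "MAT", "b": "HMR"}


@dataclass
class NucleusTriplet:
    """Three 3D spot positions of one nucleus, in micrometers."""

    nucleus_id: str
    r: np.ndarray
    g: np.ndarray
    b: np.ndarray
    cell_cycle_tag: str | None = None

    def __post_init__(self) -> None:
        for ch in CHANNELS:
            v = np.asarray(getattr(self, ch), dtype=float)
            if v.shape != (3,):
                raise ValueError(f"channel {ch!r} must be a 3-vector, got shape {v.shape}")
            setattr(self, ch, v)

    @property
    def points(self) -> np.ndarray:
        """(3, 3) array of the r, g, b positions (rows) in channel order."""
        return np.stack([self.r, self.g, self.b])

    def is_finite(self) -> bool:
        return bool(np.all(np.isfinite(self.points)))

    def pairwise_distances(self) -> np.ndarray:
        """Distances (d_rg, d_rb, d_gb)."""
        p = self.points
        return np.array(
            [
                np.linalg.norm(p[0] - p[1]),
                np.linalg.norm(p[0] - p[2]),
                np.linalg.norm(p[1] - p[2]),
            ]
        )


@dataclass
class TripletDataset:
    """Ordered collection of :class:`NucleusTriplet` with channel labels.

    Parameters
    ----------
    coords:
        Array of shape ``(M, 3, 3)``: nucleus x channel (r, g, b) x (x, y, z),
        micrometers.
    nucleus_ids:
        ``M`` unique identifiers, order matching ``coords``.
    label_map:
        Channel -> locus name, covering exactly ``{"r", "g", "b"}``.
    strain_id:
        Free-text provenance tag.
    """

    coords: np.ndarray
    nucleus_ids: Sequence[str]
    label_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))
    strain_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (3, 3):
            raise ValueError(f"coords must have shape (M, 3, 3), got {self.coords.shape}")
        self.nucleus_ids = [str(n) for n in self.nucleus_ids]
        if len(self.nucleus_ids) != self.coords.shape[0]:
            raise ValueError("nucleus_ids length must match coords")
        if len(set(self.nucleus_ids)) != len(self.nucleus_ids):
            raise ValueError("nucleus_ids must be unique")
        if set(self.label_map) != set(CHANNELS):
            raise ValueError("label_map must cover exactly the channels r, g, b")
        self.label_map = dict(self.label_map)

    @property
    def M(self) -> int:
        """Number of nuclei (states of the fiber)."""
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.M

    def __iter__(self) -> Iterator[NucleusTriplet]:
        for i, nid in enumerate(self.nucleus_ids):
            yield NucleusTriplet(nid, *self.coords[i])

    def __getitem__(self, i: int) -> NucleusTriplet:
        return NucleusTriplet(self.nucleus_ids[i], *self.coords[i])

    def subset(self, index: np.ndarray) -> "TripletDataset":
        """Row-subset preserving order; ``index`` is a boolean or integer index."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return TripletDataset(
            self.coords[index],
            [self.nucleus_ids[i] for i in index],
            dict(self.label_map),
            self.strain_id,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (nucleus, channel)."""
        rows = []
        for i, nid in enumerate(self.nucleus_ids):
            for c, ch in enumerate(CHANNELS):
                x, y, z = self.coords[i, c]
                rows.append((nid, ch, x, y, z))
        return pd.DataFrame(rows, columns=["nucleus_id", "channel", "x", "y", "z"])

    @classmethod
    def from_records(
        cls,
        records: Sequence[NucleusTriplet],
        label_map: Mapping[str, str] | None = None,
        strain_id: str = "",
    ) -> "TripletDataset":
        coords = np.stack([t.points for t in records]) if records else np.empty((0, 3, 3))
        return cls(
            coords,
            [t.nucleus_id for t in records],
            dict(label_map) if label_map else dict(DEFAULT_LABEL_MAP),
            strain_id,
        )

    def equals(self, other: "TripletDataset") -> bool:
        return (
            self.nucleus_ids == other.nucleus_ids
            and self.label_map == other.label_map
            and np.array_equal(self.coords, other.coords)
        )
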