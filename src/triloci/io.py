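"""Reading, writing and quality filtering of spot-coordinate tables.

The canonical on-disk form is a UTF-8 tab-separated table with header
``nucleus_id  channel  x  y  z`` (the *simple* dialect): one row per
(nucleus, channel), coordinates in micrometers with ``.`` as the decimal
separator.  A permissive *spotdistance* dialect is also accepted, with one
row per nucleus and per-channel column blocks ``x_r, y_r, z_r, x_g, ...`` —
the layout produced by spot-localization exports that report all three
channels side by side.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import CHANNELS, DEFAULT_LABEL_MAP, TripletDataset
from .errors import FormatError

logger = logging.getLogger(__name__)

SIMPLE_COLUMNS = ["nucleus_id", "channel", "x", "y", "z"]


@dataclass
class QCReport:
    """Removal counts per reason from :func:`qc_filter`."""

    missing_channel: int = 0
    nonfinite: int = 0
    coincident: int = 0
    too_far: int = 0
    details: dict = field(default_factory=dict)

    @property
    def total_removed(self) -> int:
        return self.missing_channel + self.nonfinite + self.coincident + self.too_far

    def to_dict(self) -> dict:
        return {
            "missing_channel": self.missing_channel,
            "nonfinite": self.nonfinite,
            "coincident": self.coincident,
            "too_far": self.too_far,
            "total_removed": self.total_removed,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def read_triplet_table(
    path: str | Path,
    dialect: str = "simple",
    label_map: dict | None = None,
    strain_id: str = "",
) -> TripletDataset:
    """Read a coordinate table into a :class:`TripletDataset`.

    Nuclei missing one or more channels are excluded with a logged count
    (they cannot form a triangle); duplicated (nucleus, channel) rows are a
    format error.  Row order of first appearance is preserved.
    """
    path = Path(path)
    if dialect == "simple":
        return _read_simple(path, label_map, strain_id)
    if dialect == "spotdistance":
        return _read_spotdistance(path, label_map, strain_id)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'simple' or 'spotdistance'")


def _read_simple(path: Path, label_map, strain_id) -> TripletDataset:
    df = pd.read_csv(path, sep="\t", dtype={"nucleus_id": str, "channel": str},
                     float_precision="round_trip")
    missing = [c for c in SIMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    bad_channel = ~df["channel"].isin(CHANNELS)
    if bad_channel.any():
        row = int(np.flatnonzero(bad_channel.to_numpy())[0])
        raise FormatError(
            f"{path}: row {row + 2}: channel {df['channel'].iloc[row]!r} not in {CHANNELS}"
        )
    for col in ("x", "y", "z"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        raw_na = df[col].isna()
        bad = coerced.isna() & ~raw_na
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{path}: row {row + 2}: non-numeric value {df[col].iloc[row]!r} in column {col!r}"
            )
        df[col] = coerced
    dup = df.duplicated(subset=["nucleus_id", "channel"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise FormatError(
            f"{path}: row {row + 2}: duplicate (nucleus_id, channel) "
            f"({df['nucleus_id'].iloc[row]}, {df['channel'].iloc[row]})"
        )
    return _assemble(df, path, label_map, strain_id)


def _read_spotdistance(path: Path, label_map, strain_id) -> TripletDataset:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    # permissive: locate per-channel blocks named x_r / xr / r_x etc.
    cols = {c.lower().replace(" ", "").replace("-", "_"): c for c in df.columns}
    id_col = None
    for cand in ("nucleus_id", "nucleus", "cell", "id"):
        if cand in cols:
            id_col = cols[cand]
            break
    rows = []
    for i in range(len(df)):
        nid = str(df[id_col].iloc[i]) if id_col else str(i)
        for ch in CHANNELS:
            triple = []
            for ax in ("x", "y", "z"):
                key = None
                for cand in (f"{ax}_{ch}", f"{ax}{ch}", f"{ch}_{ax}", f"{ch}{ax}"):
                    if cand in cols:
                        key = cols[cand]
                        break
                if key is None:
                    raise FormatError(f"{path}: no column found for axis {ax!r} of channel {ch!r}")
                triple.append(df[key].iloc[i])
            rows.append((nid, ch, *triple))
    long = pd.DataFrame(rows, columns=SIMPLE_COLUMNS)
    for col in ("x", "y", "z"):
        long[col] = pd.to_numeric(long[col], errors="coerce")
    return _assemble(long, path, label_map, strain_id)


def _assemble(df: pd.DataFrame, path: Path, label_map, strain_id) -> TripletDataset:
    ids_in_order = list(dict.fromkeys(df["nucleus_id"]))
    coords, kept = [], []
    n_incomplete = 0
    for nid in ids_in_order:
        sub = df[df["nucleus_id"] == nid]
        present = set(sub["channel"])
        if present != set(CHANNELS):
            n_incomplete += 1
            continue
        block = np.empty((3, 3))
        for c, ch in enumerate(CHANNELS):
            row = sub[sub["channel"] == ch].iloc[0]
            block[c] = (row["x"], row["y"], row["z"])
        coords.append(block)
        kept.append(nid)
    if n_incomplete:
        logger.info("%s: excluded %d nuclei with missing channel(s)", path, n_incomplete)
    arr = np.stack(coords) if coords else np.empty((0, 3, 3))
    return TripletDataset(arr, kept, label_map or dict(DEFAULT_LABEL_MAP), strain_id)


def write_triplet_table(ds: TripletDataset, path: str | Path) -> None:
    """Write the simple-dialect TSV; numeric fields round-trip bit-exactly.

    Coordinates are written with :func:`repr`-faithful precision (17
    significant digits) so that ``read_triplet_table`` inverts this function
    exactly on the numeric fields.
    """
    if ds.M == 0:
        raise ValueError("refusing to write an empty dataset")
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(SIMPLE_COLUMNS) + "\n")
        for i, nid in enumerate(ds.nucleus_ids):
            for c, ch in enumerate(CHANNELS):
                x, y, z = (float(v) for v in ds.coords[i, c])
                fh.write(f"{nid}\t{ch}\t{x!r}\t{y!r}\t{z!r}\n")


def qc_filter(
    ds: TripletDataset,
    max_pair_distance: float = 2.5,
    require_complete: bool = True,
) -> tuple[TripletDataset, QCReport]:
    """Remove nuclei that cannot support the triangle analysis.

    Removal reasons, checked in order per nucleus (each nucleus is counted
    once, under the first reason that applies):

    - ``nonfinite``: any NaN/inf coordinate,
    - ``coincident``: two channels at distance exactly 0,
    - ``too_far``: any pairwise distance above ``max_pair_distance`` (μm) —
      spots further apart than a nuclear diameter are mis-associations.

    ``missing_channel`` is reported for datasets assembled from records that
    bypassed the reader (the container itself enforces complete triplets, so
    this counter is normally zero).  The filter is idempotent.
    """
    if max_pair_distance <= 0:
        raise ValueError("max_pair_distance must be > 0")
    keep = np.ones(ds.M, dtype=bool)
    report = QCReport()
    for i in range(ds.M):
        pts = ds.coords[i]
        if not np.all(np.isfinite(pts)):
            report.nonfinite += 1
            keep[i] = False
            continue
        d = np.array(
            [
                np.linalg.norm(pts[0] - pts[1]),
                np.linalg.norm(pts[0] - pts[2]),
                np.linalg.norm(pts[1] - pts[2]),
            ]
        )
        if np.any(d == 0.0):
            report.coincident += 1
            keep[i] = False
            continue
        if np.any(d > max_pair_distance):
            report.too_far += 1
            keep[i] = False
    out = ds.subset(keep)
    if out.M == 0:
        logger.warning("qc_filter removed every nucleus (M=%d before)", ds.M)
    for key, count in report.to_dict().items():
        logger.info("qc_filter %s: %d", key, count)
    return out, report
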