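"""Streamline, parcellation and scalar-volume I/O.

Everything downstream of this module works in one spatial convention:
world RAS millimetres (x increases rightward, y anterior, z superior) with
0-based voxel indices.  On-disk dialects (TCK world mm, TRK voxel-mm with a
header affine) are converted at this boundary via :mod:`nibabel`.

The left hemisphere is world ``x < 0``.  "More lateral" therefore means
*smaller* x on the left and *larger* x on the right; helper
:func:`is_more_lateral` encodes that sign rule once for the whole package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel import streamlines as nib_streamlines

__all__ = [
    "Tractogram",
    "ParcellationVolume",
    "ScalarVolume",
    "FormatError",
    "read_tractogram",
    "write_tractogram",
    "read_parcellation",
    "read_scalar_volume",
    "write_scalar_volume",
    "read_label_table",
    "write_label_table",
    "world_to_voxel",
    "voxel_centers_world",
    "resample_streamline",
    "streamline_voxels",
    "is_more_lateral",
]

LABEL_COLUMNS = ["label_id", "name", "hemisphere", "group", "r", "g", "b"]
PARCEL_GROUPS = ("dorsal", "lateral_occipital", "ventral", "other")


class FormatError(ValueError):
    """Raised for malformed streamline/volume files or label tables."""


def _validate_streamline(points: np.ndarray, index: int) -> np.ndarray:
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise FormatError(f"streamline {index}: expected (n, 3) points, got {pts.shape}")
    if pts.shape[0] < 2:
        raise FormatError(f"streamline {index}: fewer than 2 points")
    if not np.all(np.isfinite(pts)):
        raise FormatError(f"streamline {index}: non-finite coordinates")
    if np.all(pts == pts[0]):
        raise FormatError(f"streamline {index}: all points identical")
    return pts


@dataclass
class Tractogram:
    """A list of streamlines sharing one world space (RAS mm).

    ``voxel_size`` is metadata about the source grid, carried for writers
    that need it (TRK); it does not affect the coordinates.
    """

    streamlines: list[np.ndarray] = field(default_factory=list)
    space_id: str = "RASmm"
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.streamlines = [
            _validate_streamline(s, i) for i, s in enumerate(self.streamlines)
        ]

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def subset(self, indices: Iterable[int]) -> "Tractogram":
        idx = list(indices)
        return Tractogram(
            streamlines=[self.streamlines[i].copy() for i in idx],
            space_id=self.space_id,
            voxel_size=self.voxel_size,
        )


@dataclass
class ScalarVolume:
    """A 3-D real-valued grid (e.g. FA in [0, 1]) with a voxel-to-world affine."""

    values: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.values.ndim != 3:
            raise FormatError("scalar volume must be 3-D")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("scalar volume has non-finite values")
        _check_affine(self.affine)


@dataclass
class ParcellationVolume:
    """Integer label grid + affine + label table.

    Label 0 is background.  Every nonzero label present in the grid must
    appear in the table; the table may list labels absent from the grid.
    """

    labels: np.ndarray
    affine: np.ndarray
    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise FormatError("parcellation grid must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = self.labels.astype(np.int64)
            if not np.array_equal(as_int, self.labels):
                raise FormatError("parcellation grid is not integer-valued")
            self.labels = as_int
        if self.labels.min() < 0:
            raise FormatError("parcellation grid has negative labels")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        _check_affine(self.affine)
        self.table = validate_label_table(self.table)
        present = set(np.unique(self.labels)) - {0}
        known = set(self.table["label_id"])
        orphans = sorted(present - known)
        if orphans:
            raise FormatError(f"grid labels missing from label table: {orphans}")

    # -- lookup helpers -------------------------------------------------
    def name_of(self, label_id: int) -> str:
        row = self.table.loc[self.table["label_id"] == label_id]
        if row.empty:
            raise KeyError(f"label id {label_id} not in table")
        return str(row["name"].iloc[0])

    def labels_in_group(self, group: str, hemisphere: str | None = None) -> list[int]:
        mask = self.table["group"] == group
        if hemisphere is not None:
            mask &= self.table["hemisphere"] == hemisphere
        return [int(v) for v in self.table.loc[mask, "label_id"]]

    def labels_by_name(self, names: Sequence[str], hemisphere: str | None = None) -> list[int]:
        mask = self.table["name"].isin(list(names))
        if hemisphere is not None:
            mask &= self.table["hemisphere"] == hemisphere
        return [int(v) for v in self.table.loc[mask, "label_id"]]


def _check_affine(affine: np.ndarray) -> None:
    if affine.shape != (4, 4):
        raise FormatError(f"affine must be 4x4, got {affine.shape}")
    if not np.all(np.isfinite(affine)):
        raise FormatError("affine has non-finite entries")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise FormatError("affine is not invertible")


def validate_label_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in LABEL_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"label table missing columns: {missing}")
    table = table[LABEL_COLUMNS].copy()
    table["label_id"] = table["label_id"].astype(int)
    if (table["label_id"] <= 0).any():
        raise FormatError("label ids must be positive")
    if table["label_id"].duplicated().any():
        dup = sorted(table.loc[table["label_id"].duplicated(), "label_id"])
        raise FormatError(f"duplicate label ids: {dup}")
    if table.duplicated(subset=["name", "hemisphere"]).any():
        raise FormatError("duplicate (name, hemisphere) rows in label table")
    bad_hemi = set(table["hemisphere"]) - {"L", "R"}
    if bad_hemi:
        raise FormatError(f"unknown hemisphere codes: {sorted(bad_hemi)}")
    bad_group = set(table["group"]) - set(PARCEL_GROUPS)
    if bad_group:
        raise FormatError(f"unknown parcel groups: {sorted(bad_group)}")
    for c in ("r", "g", "b"):
        table[c] = table[c].astype(int)
        if ((table[c] < 0) | (table[c] > 255)).any():
            raise FormatError(f"RGB column {c} outside [0, 255]")
    return table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# spatial convention helpers
# ---------------------------------------------------------------------------

def world_to_voxel(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Map world RAS mm coordinates to 0-based voxel indices.

    Rounds to nearest integer, halves away from zero.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    inv = np.linalg.inv(affine)
    vox = points @ inv[:3, :3].T + inv[:3, 3]
    # round half away from zero (np.round rounds half to even)
    return (np.sign(vox) * np.floor(np.abs(vox) + 0.5)).astype(np.int64)


def voxel_centers_world(indices: np.ndarray, affine: np.ndarray) -> np.ndarray:
    indices = np.atleast_2d(np.asarray(indices, dtype=np.float64))
    return indices @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]


def resample_streamline(points: np.ndarray, step_mm: float) -> np.ndarray:
    """Re-parametrize a polyline by arc length at ``step_mm`` spacing,
    keeping both terminal points."""
    points = np.asarray(points, dtype=np.float64)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    length = s[-1]
    if length <= 0:
        return points[:1]
    targets = np.arange(0.0, length, step_mm)
    if length - targets[-1] > 1e-9:
        targets = np.append(targets, length)
    return np.column_stack([np.interp(targets, s, points[:, k]) for k in range(3)])


def streamline_voxels(
    streamlines: Iterable[np.ndarray], affine: np.ndarray, step_mm: float = 1.0
) -> np.ndarray:
    """Unique voxel indices intersected by any streamline point after
    ``step_mm`` resampling — the common voxel support used for tract
    volume, mean FA and the phantom's FA painting."""
    pts = [resample_streamline(s, step_mm) for s in streamlines]
    if not pts:
        raise ValueError("need at least one streamline")
    return np.unique(world_to_voxel(np.vstack(pts), affine), axis=0)


def is_more_lateral(x_candidate: float, x_reference: float, hemisphere: str) -> bool:
    """Sign rule: lateral = smaller x on the left, larger x on the right."""
    if hemisphere == "L":
        return x_candidate < x_reference
    if hemisphere == "R":
        return x_candidate > x_reference
    raise ValueError(f"hemisphere must be 'L' or 'R', got {hemisphere!r}")


# ---------------------------------------------------------------------------
# tractogram I/O
# ---------------------------------------------------------------------------

def _format_of(path: str | Path, format: str | None) -> str:
    if format is None:
        format = Path(path).suffix.lstrip(".").lower()
    format = format.lower()
    if format not in ("tck", "trk"):
        raise FormatError(f"unsupported tractogram format: {format!r}")
    return format


def read_tractogram(path: str | Path, format: str | None = None) -> Tractogram:
    """Read a TCK or TRK file into world RAS mm.

    TCK stores world mm directly; TRK stores voxel-mm in the header's voxel
    order and is converted through the header's voxel-to-RAS affine.  TRK
    files whose header carries no usable affine are refused rather than
    dialect-guessed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _format_of(path, format)
    cls = nib_streamlines.TckFile if fmt == "tck" else nib_streamlines.TrkFile
    try:
        tfile = cls.load(str(path), lazy_load=False)
    except Exception as exc:  # nibabel raises assorted header errors
        raise FormatError(f"cannot parse {fmt.upper()} file {path}: {exc}") from exc
    if fmt == "trk":
        affine = tfile.header.get("voxel_to_rasmm")
        if affine is None or abs(np.linalg.det(np.asarray(affine)[:3, :3])) < 1e-12:
            raise FormatError(
                f"TRK file {path}: header field 'voxel_to_rasmm' missing or singular"
            )
    # nibabel applies affine_to_rasmm on load -> points are world RAS mm
    raw = [np.asarray(s, dtype=np.float64) for s in tfile.tractogram.streamlines]
    kept = [s for s in raw if s.shape[0] >= 2 and not np.all(s == s[0])]
    n_dropped = len(raw) - len(kept)
    voxel_size = tuple(float(v) for v in tfile.header.get("voxel_sizes", (1.0, 1.0, 1.0)))
    t = Tractogram(streamlines=kept, space_id=f"{fmt}:{path.name}", voxel_size=voxel_size)
    t.n_dropped_degenerate = n_dropped  # type: ignore[attr-defined]
    return t


def write_tractogram(
    t: Tractogram,
    path: str | Path,
    format: str | None = None,
    affine: np.ndarray | None = None,
    dimensions: tuple[int, int, int] | None = None,
) -> Path:
    """Write ``t`` to TCK or TRK.

    TRK requires grid metadata; if ``affine``/``dimensions`` are not given a
    scaled-identity affine from ``t.voxel_size`` and a bounding-box grid are
    used, which round-trips exactly since the points themselves stay world mm.
    """
    path = Path(path)
    fmt = _format_of(path, format)
    sl = [s.astype(np.float64) for s in t.streamlines]
    nt = nib_streamlines.Tractogram(sl, affine_to_rasmm=np.eye(4))
    if fmt == "tck":
        f = nib_streamlines.TckFile(nt)
    else:
        if affine is None:
            affine = np.diag([*t.voxel_size, 1.0])
        affine = np.asarray(affine, dtype=np.float64)
        _check_affine(affine)
        if dimensions is None:
            if sl:
                pts = np.vstack(sl)
                vox = world_to_voxel(pts, affine)
                dimensions = tuple(int(d) for d in (vox.max(axis=0) + 1).clip(min=1))
            else:
                dimensions = (1, 1, 1)
        header = {
            nib_streamlines.trk.Field.VOXEL_TO_RASMM: affine,
            nib_streamlines.trk.Field.VOXEL_SIZES: tuple(float(v) for v in t.voxel_size),
            nib_streamlines.trk.Field.DIMENSIONS: dimensions,
            nib_streamlines.trk.Field.VOXEL_ORDER: b"RAS",
        }
        f = nib_streamlines.TrkFile(nt, header=header)
    f.save(str(path))
    return path


# ---------------------------------------------------------------------------
# volume I/O
# ---------------------------------------------------------------------------

def read_parcellation(volume_path: str | Path, table_path: str | Path) -> ParcellationVolume:
    img = nib.load(str(volume_path))
    data = np.asanyarray(img.dataobj)
    if not np.allclose(data, np.round(data)):
        raise FormatError(f"{volume_path}: parcellation grid is not integer-valued")
    table = read_label_table(table_path)
    return ParcellationVolume(labels=data.astype(np.int64), affine=img.affine, table=table)


def read_scalar_volume(path: str | Path) -> ScalarVolume:
    img = nib.load(str(path))
    return ScalarVolume(values=np.asanyarray(img.dataobj, dtype=np.float64), affine=img.affine)


def write_scalar_volume(vol: ScalarVolume, path: str | Path) -> Path:
    nib.save(nib.Nifti1Image(vol.values.astype(np.float32), vol.affine), str(path))
    return Path(path)


def write_parcellation(parc: ParcellationVolume, volume_path: str | Path, table_path: str | Path) -> None:
    nib.save(nib.Nifti1Image(parc.labels.astype(np.int32), parc.affine), str(volume_path))
    write_label_table(parc.table, table_path)


def read_label_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    return validate_label_table(table)


def write_label_table(table: pd.DataFrame, path: str | Path) -> Path:
    validate_label_table(table).to_csv(path, sep="\t", index=False)
    return Path(path)
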