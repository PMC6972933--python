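"""Endpoint connectomics: connectivity matrices, ratio tables, tract metrics.

Conventions (stated because tool families differ):

* the **connectivity matrix** counts accepted streamlines per unordered
  parcel pair; a streamline with both ends in one parcel is a diagonal
  entry.  The matrix is kept symmetric, and its upper triangle (including
  the diagonal) sums to the accepted streamline count.
* **endpoint ratios** are percentages of endpoints *within a parcel
  group*: each accepted streamline contributes one endpoint to the group
  of each of its two parcels (a diagonal streamline contributes two to the
  same parcel).
* **connection ratios** are percentages of streamlines per parcel pair
  over all accepted streamlines.
* **tract volume** counts unique voxels intersected by any streamline
  point after 1 mm resampling, times the voxel volume — overlapping
  streamlines are not double counted; **mean FA** is the unweighted mean
  over that same voxel set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .selection import SelectionReport
from .tract_io import (
    ParcellationVolume,
    ScalarVolume,
    Tractogram,
    streamline_voxels,
)

__all__ = [
    "ConnectivityMatrix",
    "build_connectivity_matrix",
    "endpoint_ratios",
    "connection_ratios",
    "tract_volume",
    "mean_fa",
    "compute_tract_metrics",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric parcel-by-parcel streamline-termination counts."""

    counts: pd.DataFrame  # index/columns: parcel names
    hemisphere: str

    def __post_init__(self) -> None:
        c = self.counts
        if not c.index.equals(c.columns):
            raise ValueError("matrix rows and columns must carry the same parcels")
        if (c.values < 0).any():
            raise ValueError("negative counts")
        if not np.array_equal(c.values, c.values.T):
            raise ValueError("matrix must be symmetric")

    @property
    def parcels(self) -> list[str]:
        return list(self.counts.index)

    def total(self) -> int:
        """Accepted streamline count = upper triangle incl. diagonal."""
        v = self.counts.values
        return int(np.triu(v).sum())

    def endpoint_counts(self) -> pd.Series:
        """Endpoints per parcel; a diagonal streamline contributes two."""
        v = self.counts.values
        return pd.Series(v.sum(axis=1) + np.diag(v), index=self.counts.index)


def build_connectivity_matrix(
    report: SelectionReport, parc: ParcellationVolume, hemisphere: str
) -> ConnectivityMatrix:
    """Count each accepted streamline into exactly one unordered parcel pair."""
    sub = parc.table[parc.table["hemisphere"] == hemisphere]
    names = list(sub["name"])
    label_to_name = dict(zip(sub["label_id"].astype(int), sub["name"]))
    counts = pd.DataFrame(0, index=names, columns=names, dtype=np.int64)
    for i in report.accepted:
        if i not in report.assignments:
            raise ValueError(f"accepted streamline {i} has no endpoint assignment")
        la, lb = report.assignments[i]
        try:
            a, b = label_to_name[int(la)], label_to_name[int(lb)]
        except KeyError as exc:
            raise ValueError(
                f"streamline {i}: endpoint label {exc} not in hemisphere {hemisphere}"
            ) from exc
        counts.loc[a, b] += 1
        if a != b:
            counts.loc[b, a] += 1
    return ConnectivityMatrix(counts=counts, hemisphere=hemisphere)


def endpoint_ratios(
    m: ConnectivityMatrix, table: pd.DataFrame, groups: Sequence[str] = ("dorsal", "lateral_occipital", "ventral")
) -> dict[str, pd.Series]:
    """Percentage of each group's endpoints falling in each of its parcels.

    Each returned Series sums to 100 (groups with zero endpoints are
    omitted)."""
    sub = table[(table["hemisphere"] == m.hemisphere)]
    ep = m.endpoint_counts()
    out: dict[str, pd.Series] = {}
    for group in groups:
        parcels = [n for n in sub.loc[sub["group"] == group, "name"] if n in ep.index]
        counts = ep.loc[parcels]
        total = counts.sum()
        if total > 0:
            out[group] = 100.0 * counts / total
    return out


def connection_ratios(m: ConnectivityMatrix) -> pd.Series:
    """Percentage of accepted streamlines per unordered parcel pair.

    Indexed by ``(parcel_a, parcel_b)`` with a <= b in matrix order; sums
    to 100."""
    total = m.total()
    if total == 0:
        raise ValueError("empty connectivity matrix")
    names = m.parcels
    v = m.counts.values
    entries = {}
    for i in range(len(names)):
        for j in range(i, len(names)):
            if v[i, j] > 0:
                entries[(names[i], names[j])] = 100.0 * v[i, j] / total
    return pd.Series(entries, dtype=np.float64)


# ---------------------------------------------------------------------------
# voxel-support metrics
# ---------------------------------------------------------------------------

def tract_volume(
    streamlines: Iterable[np.ndarray], affine: np.ndarray, step_mm: float = 1.0
) -> float:
    """Unique-voxel count x voxel volume (mm^3)."""
    vox = streamline_voxels(streamlines, affine, step_mm)
    voxel_volume = abs(np.linalg.det(np.asarray(affine)[:3, :3]))
    return float(len(vox) * voxel_volume)


def mean_fa(
    streamlines: Iterable[np.ndarray], fa: ScalarVolume, step_mm: float = 1.0
) -> float:
    """Unweighted mean FA over the tract's unique voxel set (voxels outside
    the grid are ignored)."""
    vox = streamline_voxels(streamlines, fa.affine, step_mm)
    shape = np.array(fa.values.shape)
    inside = np.all((vox >= 0) & (vox < shape), axis=1)
    vox = vox[inside]
    if len(vox) == 0:
        raise ValueError("no streamline voxel falls inside the FA grid")
    return float(fa.values[vox[:, 0], vox[:, 1], vox[:, 2]].mean())


def compute_tract_metrics(
    t: Tractogram,
    report: SelectionReport,
    parc: ParcellationVolume,
    fa: ScalarVolume | None,
    hemisphere: str,
) -> pd.DataFrame:
    """Per parcel-pair count, volume and mean FA of the accepted streamlines.

    Returns a DataFrame with columns parcel_a, parcel_b, hemisphere,
    n_tracts, volume_mm3, mean_fa (NaN if no FA volume given)."""
    label_to_name = dict(
        zip(parc.table["label_id"].astype(int), parc.table["name"])
    )
    pairs: dict[tuple[str, str], list[int]] = {}
    for i in report.accepted:
        la, lb = report.assignments[i]
        a, b = sorted((label_to_name[int(la)], label_to_name[int(lb)]))
        pairs.setdefault((a, b), []).append(i)
    rows = []
    for (a, b), idx in sorted(pairs.items()):
        sl = [t.streamlines[i] for i in idx]
        rows.append(
            {
                "parcel_a": a,
                "parcel_b": b,
                "hemisphere": hemisphere,
                "n_tracts": len(idx),
                "volume_mm3": tract_volume(sl, parc.affine),
                "mean_fa": mean_fa(sl, fa) if fa is not None else np.nan,
            }
        )
    return pd.DataFrame(
        rows, columns=["parcel_a", "parcel_b", "hemisphere", "n_tracts", "volume_mm3", "mean_fa"]
    )
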