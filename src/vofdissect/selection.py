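"""Virtual dissection of the VOF: atlas-constrained streamline selection.

The selection procedure mirrors how the bundle is dissected from a whole
tractogram in practice:

1. **two-ROI** — keep streamlines whose two terminal points assign to
   parcels of two prescribed groups (dorsal vs ventral/lateral-occipital
   by default), in either end order;
2. **orientation** — keep streamlines whose dominant displacement axis is
   superior-inferior (the "blue" fibers of an RGB direction map), with the
   SI share of total absolute displacement at least ``min_axis_fraction``;
3. **ROA** — discard streamlines touching a region-of-avoidance mask;
4. **posterior / lateral** — keep streamlines that stay posterior to an
   AF-like reference and lateral to an ILF-like reference: the candidate's
   per-z-slab coordinate median is compared against the reference bundle's
   per-slab envelope (its extreme toward the relation direction).

Filters 1-3 are independent per-streamline predicates (any application
order gives the same set); the composed pipeline applies them in the fixed
order above and attributes each rejection to the first failing filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .tract_io import (
    PARCEL_GROUPS,
    ParcellationVolume,
    ScalarVolume,
    Tractogram,
    is_more_lateral,
    voxel_centers_world,
    world_to_voxel,
)

__all__ = [
    "AXES",
    "OrientationResult",
    "SelectionCriteria",
    "SelectionReport",
    "classify_orientation",
    "assign_endpoint_parcel",
    "select_two_roi",
    "filter_orientation",
    "filter_roa",
    "filter_relative_position",
    "run_selection",
]

AXES = ("LR", "AP", "SI")  # x, y, z


@dataclass(frozen=True)
class OrientationResult:
    """Dominant displacement axis and per-axis displacement shares."""

    dominant_axis: str
    fractions: tuple[float, float, float]  # (LR, AP, SI), sums to 1


def classify_orientation(streamline: np.ndarray) -> OrientationResult:
    """Per-axis share of total absolute displacement; dominant = argmax.

    Ties are broken SI > AP > LR, matching the convention that a fiber
    ambiguous between axes is read as vertical last-to-first.
    """
    pts = np.asarray(streamline, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("streamline needs at least 2 points")
    d = np.abs(np.diff(pts, axis=0)).sum(axis=0)
    total = d.sum()
    if total <= 0:
        raise ValueError("zero total displacement")
    fractions = d / total
    order = (2, 1, 0)  # SI first for tie-breaking
    best = max(fractions[k] for k in order)
    dominant = next(k for k in order if fractions[k] == best)
    return OrientationResult(AXES[dominant], tuple(float(f) for f in fractions))


@dataclass
class SelectionCriteria:
    """Parameters of the two-ROI virtual dissection.

    ``group_a`` / ``group_b`` are parcel-group names (``dorsal``,
    ``lateral_occipital``, ``ventral``) and/or explicit parcel names; the
    two resolved label sets must be disjoint.
    """

    group_a: Sequence[str] = ("dorsal",)
    group_b: Sequence[str] = ("ventral", "lateral_occipital")
    hemisphere: str = "L"
    endpoint_radius_mm: float = 2.0
    required_axis: str = "SI"
    min_axis_fraction: float = 0.5
    roa: ScalarVolume | None = None
    lateral_reference: Tractogram | None = None
    posterior_reference: Tractogram | None = None
    slab_mm: float = 5.0
    slab_majority: float = 1.0  # share of shared slabs that must satisfy the relation
    reference_quantile: float = 1.0  # 1.0 = bundle envelope, 0.5 = bundle midline

    def __post_init__(self) -> None:
        if isinstance(self.group_a, str):
            self.group_a = tuple(s.strip() for s in self.group_a.split(","))
        if isinstance(self.group_b, str):
            self.group_b = tuple(s.strip() for s in self.group_b.split(","))
        if self.endpoint_radius_mm < 0:
            raise ValueError("endpoint_radius_mm must be >= 0")
        if not 0.0 <= self.min_axis_fraction <= 1.0:
            raise ValueError("min_axis_fraction must be in [0, 1]")
        if self.required_axis not in AXES:
            raise ValueError(f"required_axis must be one of {AXES}")
        if not 0.0 < self.slab_majority <= 1.0:
            raise ValueError("slab_majority must be in (0, 1]")
        if self.slab_mm <= 0:
            raise ValueError("slab_mm must be positive")
        if not 0.0 <= self.reference_quantile <= 1.0:
            raise ValueError("reference_quantile must be in [0, 1]")

    def resolve_labels(self, parc: ParcellationVolume) -> tuple[set[int], set[int]]:
        a = _resolve_label_set(self.group_a, parc, self.hemisphere)
        b = _resolve_label_set(self.group_b, parc, self.hemisphere)
        if not a or not b:
            raise ValueError("empty parcel group in selection criteria")
        if a & b:
            raise ValueError(f"group_a and group_b overlap on labels {sorted(a & b)}")
        return a, b


def _resolve_label_set(
    entries: Sequence[str], parc: ParcellationVolume, hemisphere: str
) -> set[int]:
    labels: set[int] = set()
    names: list[str] = []
    for entry in entries:
        if entry in PARCEL_GROUPS:
            labels.update(parc.labels_in_group(entry, hemisphere))
        else:
            names.append(entry)
    if names:
        found = parc.labels_by_name(names, hemisphere)
        known = set(parc.table.loc[parc.table["hemisphere"] == hemisphere, "name"])
        missing = [n for n in names if n not in known]
        if missing:
            raise ValueError(f"unknown parcel names for hemisphere {hemisphere}: {missing}")
        labels.update(found)
    return labels


@dataclass
class SelectionReport:
    """Bookkeeping of one selection run.

    ``accepted + sum(rejections.values()) == n_input`` when the filters are
    applied sequentially; each rejection is charged to the first failing
    filter.  ``assignments`` maps accepted streamline index to its
    (group_a parcel, group_b parcel) label ids.
    """

    n_input: int
    accepted: list[int]
    rejections: dict[str, int]
    assignments: dict[int, tuple[int, int]]
    notes: dict[str, int] = field(default_factory=dict)

    def check_conservation(self) -> None:
        total = len(self.accepted) + sum(self.rejections.values())
        if total != self.n_input:
            raise AssertionError(
                f"bookkeeping violated: {len(self.accepted)} accepted + "
                f"{sum(self.rejections.values())} rejected != {self.n_input} input"
            )

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_accepted": len(self.accepted),
            "accepted": [int(i) for i in self.accepted],
            "rejections": {k: int(v) for k, v in self.rejections.items()},
            "assignments": {int(k): [int(a), int(b)] for k, (a, b) in self.assignments.items()},
            "notes": {k: int(v) for k, v in self.notes.items()},
        }


# ---------------------------------------------------------------------------
# endpoint -> parcel assignment
# ---------------------------------------------------------------------------

def _labeled_kdtree(parc: ParcellationVolume) -> tuple[cKDTree, np.ndarray]:
    cached = getattr(parc, "_labeled_kdtree_cache", None)
    if cached is not None:
        return cached
    idx = np.argwhere(parc.labels > 0)
    labels = parc.labels[idx[:, 0], idx[:, 1], idx[:, 2]]
    centers = voxel_centers_world(idx, parc.affine)
    tree = cKDTree(centers)
    parc._labeled_kdtree_cache = (tree, labels)  # type: ignore[attr-defined]
    return tree, labels


def assign_endpoint_parcel(
    point: np.ndarray, parc: ParcellationVolume, radius_mm: float = 2.0
) -> int | None:
    """Parcel label at ``point``: the containing voxel's label if nonzero,
    else the nonzero label of the nearest labeled voxel center within
    ``radius_mm`` (ties on distance broken toward the smaller label id),
    else ``None``."""
    point = np.asarray(point, dtype=np.float64)
    if not np.all(np.isfinite(point)):
        raise ValueError("non-finite endpoint coordinate")
    return assign_endpoint_parcels(point[None, :], parc, radius_mm)[0]


def assign_endpoint_parcels(
    points: np.ndarray, parc: ParcellationVolume, radius_mm: float = 2.0
) -> list[int | None]:
    """Vectorized :func:`assign_endpoint_parcel` over an (n, 3) array."""
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if not np.all(np.isfinite(points)):
        raise ValueError("non-finite endpoint coordinates")
    shape = np.array(parc.labels.shape)
    vox = world_to_voxel(points, parc.affine)
    inside = np.all((vox >= 0) & (vox < shape), axis=1)
    out: list[int | None] = [None] * len(points)
    direct = np.zeros(len(points), dtype=bool)
    if inside.any():
        vi = vox[inside]
        lab = parc.labels[vi[:, 0], vi[:, 1], vi[:, 2]]
        hit = np.zeros(len(points), dtype=bool)
        hit[np.flatnonzero(inside)[lab > 0]] = True
        for j, l in zip(np.flatnonzero(inside)[lab > 0], lab[lab > 0]):
            out[j] = int(l)
        direct = hit
    todo = np.flatnonzero(~direct)
    if len(todo) and radius_mm > 0:
        tree, labels = _labeled_kdtree(parc)
        hits = tree.query_ball_point(points[todo], r=radius_mm + 1e-9)
        for j, cand in zip(todo, hits):
            if not cand:
                continue
            cand = np.asarray(cand)
            d = np.linalg.norm(tree.data[cand] - points[j], axis=1)
            dmin = d.min()
            tied = cand[d <= dmin + 1e-9]
            out[j] = int(labels[tied].min())
    return out


# ---------------------------------------------------------------------------
# individual filters
# ---------------------------------------------------------------------------

def select_two_roi(
    t: Tractogram,
    parc: ParcellationVolume,
    criteria: SelectionCriteria,
    indices: Sequence[int] | None = None,
) -> tuple[list[int], dict[int, tuple[int, int]]]:
    """Indices whose terminal points assign to one group_a and one group_b
    parcel (either end order), plus the (a, b)-ordered assignments."""
    set_a, set_b = criteria.resolve_labels(parc)
    idx = list(range(len(t))) if indices is None else list(indices)
    if not idx:
        return [], {}
    first = np.array([t.streamlines[i][0] for i in idx])
    last = np.array([t.streamlines[i][-1] for i in idx])
    lab_first = assign_endpoint_parcels(first, parc, criteria.endpoint_radius_mm)
    lab_last = assign_endpoint_parcels(last, parc, criteria.endpoint_radius_mm)
    accepted: list[int] = []
    assignments: dict[int, tuple[int, int]] = {}
    for i, la, lb in zip(idx, lab_first, lab_last):
        if la is None or lb is None:
            continue
        if la in set_a and lb in set_b:
            accepted.append(i)
            assignments[i] = (la, lb)
        elif lb in set_a and la in set_b:
            accepted.append(i)
            assignments[i] = (lb, la)
    return accepted, assignments


def filter_orientation(
    t: Tractogram,
    indices: Sequence[int],
    required_axis: str = "SI",
    min_axis_fraction: float = 0.5,
) -> list[int]:
    """Keep streamlines whose dominant axis is ``required_axis`` and whose
    share on that axis is at least ``min_axis_fraction``."""
    k = AXES.index(required_axis)
    kept = []
    for i in indices:
        r = classify_orientation(t.streamlines[i])
        if r.dominant_axis == required_axis and r.fractions[k] >= min_axis_fraction:
            kept.append(i)
    return kept


def filter_roa(t: Tractogram, indices: Sequence[int], roa: ScalarVolume) -> list[int]:
    """Drop any streamline with at least one point in the avoidance mask."""
    mask = roa.values != 0
    shape = np.array(mask.shape)
    kept = []
    for i in indices:
        vox = world_to_voxel(t.streamlines[i], roa.affine)
        inside = np.all((vox >= 0) & (vox < shape), axis=1)
        vi = vox[inside]
        if vi.size and mask[vi[:, 0], vi[:, 1], vi[:, 2]].any():
            continue
        kept.append(i)
    return kept


def _slab_medians(
    streamlines: Iterable[np.ndarray], ids: Iterable[int], axis: int, slab_mm: float
) -> pd.Series:
    """Median of coordinate ``axis`` per (streamline id, z-slab)."""
    frames = []
    for i, pts in zip(ids, streamlines):
        frames.append(
            pd.DataFrame(
                {"id": i, "slab": np.floor(pts[:, 2] / slab_mm).astype(np.int64),
                 "v": pts[:, axis]}
            )
        )
    if not frames:
        return pd.Series(dtype=np.float64)
    df = pd.concat(frames, ignore_index=True)
    return df.groupby(["id", "slab"])["v"].median()


def filter_relative_position(
    t: Tractogram,
    indices: Sequence[int],
    reference: Tractogram,
    relation: str,
    hemisphere: str,
    slab_mm: float = 5.0,
    majority: float = 1.0,
    reference_quantile: float = 1.0,
) -> tuple[list[int], int]:
    """Keep streamlines lateral to / posterior to a reference bundle.

    The shared z-range is partitioned into ``slab_mm`` slabs; in each slab
    occupied by both the candidate and the pooled reference, the candidate's
    median x (``lateral``) or y (``posterior``) is compared with a per-slab
    reference statistic: the reference's ``reference_quantile``-th extreme
    *toward* the relation direction.  The default 1.0 is the bundle's
    envelope (e.g. its most lateral point in the slab), which makes the
    relation mean "beyond the bundle" — in particular a bundle is never
    lateral/posterior to itself; 0.5 compares against the bundle midline.
    A candidate is retained iff the strict relation holds in at least
    ``majority`` of its shared slabs.  Candidates sharing no slab with the
    reference are retained (filter inapplicable); their count is returned
    alongside the kept indices.
    """
    if relation not in ("lateral", "posterior"):
        raise ValueError(f"relation must be 'lateral' or 'posterior', got {relation!r}")
    if len(reference) == 0:
        raise ValueError("reference tractogram is empty")
    indices = list(indices)
    if not indices:
        return [], 0
    axis = 0 if relation == "lateral" else 1
    # orient the quantile toward the relation: smaller values are "further"
    # for left-lateral and posterior, larger for right-lateral
    toward_smaller = relation == "posterior" or hemisphere == "L"
    q = 1.0 - reference_quantile if toward_smaller else reference_quantile
    ref_pts = np.vstack(list(reference))
    ref_df = pd.DataFrame(
        {"slab": np.floor(ref_pts[:, 2] / slab_mm).astype(np.int64), "v": ref_pts[:, axis]}
    )
    ref_stat = ref_df.groupby("slab")["v"].quantile(q)
    cand = _slab_medians((t.streamlines[i] for i in indices), indices, axis, slab_mm)
    kept: list[int] = []
    n_inapplicable = 0
    for i in indices:
        mine = cand.loc[i]
        shared = mine.index.intersection(ref_stat.index)
        if len(shared) == 0:
            n_inapplicable += 1
            kept.append(i)
            continue
        cv = mine.loc[shared].to_numpy()
        rv = ref_stat.loc[shared].to_numpy()
        if relation == "lateral":
            ok = np.array([is_more_lateral(c, r, hemisphere) for c, r in zip(cv, rv)])
        else:
            ok = cv < rv  # more posterior = smaller y
        if ok.mean() >= majority:
            kept.append(i)
    return kept, n_inapplicable


# ---------------------------------------------------------------------------
# composed pipeline
# ---------------------------------------------------------------------------

def run_selection(
    t: Tractogram, parc: ParcellationVolume, criteria: SelectionCriteria
) -> SelectionReport:
    """Apply two-ROI -> orientation -> ROA -> posterior -> lateral, with
    per-filter rejection counts charged to the first failing filter."""
    rejections = {"two_roi": 0, "orientation": 0, "roa": 0, "posterior": 0, "lateral": 0}
    notes: dict[str, int] = {}

    current, assignments = select_two_roi(t, parc, criteria)
    rejections["two_roi"] = len(t) - len(current)

    kept = filter_orientation(t, current, criteria.required_axis, criteria.min_axis_fraction)
    rejections["orientation"] = len(current) - len(kept)
    current = kept

    if criteria.roa is not None:
        kept = filter_roa(t, current, criteria.roa)
        rejections["roa"] = len(current) - len(kept)
        current = kept

    if criteria.posterior_reference is not None and len(current):
        kept, n_na = filter_relative_position(
            t, current, criteria.posterior_reference, "posterior",
            criteria.hemisphere, criteria.slab_mm, criteria.slab_majority,
            criteria.reference_quantile,
        )
        rejections["posterior"] = len(current) - len(kept)
        notes["posterior_inapplicable"] = n_na
        current = kept

    if criteria.lateral_reference is not None and len(current):
        kept, n_na = filter_relative_position(
            t, current, criteria.lateral_reference, "lateral",
            criteria.hemisphere, criteria.slab_mm, criteria.slab_majority,
            criteria.reference_quantile,
        )
        rejections["lateral"] = len(current) - len(kept)
        notes["lateral_inapplicable"] = n_na
        current = kept

    report = SelectionReport(
        n_input=len(t),
        accepted=sorted(current),
        rejections=rejections,
        assignments={i: assignments[i] for i in current},
        notes=notes,
    )
    report.check_conservation()
    return report
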