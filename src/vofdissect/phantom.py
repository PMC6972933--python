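"""Synthetic hemispheric phantom: parcellation, bundles, clutter and FA field.

The phantom emulates the statistical structure the virtual-dissection
pipeline assumes, without any imaging data:

* a posterior cortical "shell" parcellation with three parcel groups —
  dorsal parieto-occipital (V3A, V3B, V3CD, V6, V6A, V7, IP0), lateral
  occipital (LO1-3, V4t, MT, MST, FST) and ventral occipito-temporal
  (V4, V8, PIT, FFC, VVC, VMV1-3, PHA1-3);
* a VOF-like bundle of vertically coursing streamlines whose endpoint
  parcels are drawn from configurable multinomials per group;
* an ILF-like bundle running anterior-posterior strictly medial to the
  VOF corridor, and an AF-like bundle arcing strictly anterior to it;
* clutter streamlines with random geometry that never have both ends in
  cortex, exercising the rejection paths of every filter;
* a smooth FA field elevated along the bundles.

Geometry is stylized, not anatomical: regions are boxes in world RAS mm,
placed so that the separation invariants (VOF dominant-z, ILF medial by a
margin, AF anterior by a margin) hold for *every* generated streamline and
are asserted at generation time.  All randomness flows from one
``numpy.random.Generator`` in a fixed draw order, so a config + seed pair
reproduces the phantom bitwise.  Left/right twins generated from the same
seed are exact mirror images (lateral draws are hemisphere-sign aware).
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .tract_io import (
    ParcellationVolume,
    ScalarVolume,
    Tractogram,
    streamline_voxels,
    validate_label_table,
    world_to_voxel,
    write_parcellation,
    write_scalar_volume,
    write_tractogram,
)

__all__ = [
    "PhantomConfig",
    "Phantom",
    "GROUP_PARCELS",
    "DEFAULT_ENDPOINT_PROPS",
    "default_affine",
    "make_parcellation",
    "make_vof_bundle",
    "make_reference_bundles",
    "make_clutter",
    "make_fa",
    "make_phantom",
    "save_phantom",
]

# parcel roster per group (per hemisphere)
GROUP_PARCELS: dict[str, tuple[str, ...]] = {
    "dorsal": ("V3A", "V3B", "V3CD", "V6", "V6A", "V7", "IP0"),
    "lateral_occipital": ("LO1", "LO2", "LO3", "V4t", "MT", "MST", "FST"),
    "ventral": ("V4", "V8", "PIT", "FFC", "VVC", "VMV1", "VMV2", "VMV3", "PHA1", "PHA2", "PHA3"),
}

# Default endpoint-parcel multinomials.  The named entries are the group
# shares reported for VOF endpoint projections in each hemisphere; the
# remaining probability mass is spread uniformly over the unnamed parcels
# of the group.
_NAMED_PROPS: dict[tuple[str, str], dict[str, float]] = {
    ("dorsal", "L"): {"V3CD": 0.352, "V6A": 0.248, "V3A": 0.148, "IP0": 0.095, "V7": 0.085},
    ("dorsal", "R"): {"V3A": 0.294, "V7": 0.265, "V3CD": 0.167, "IP0": 0.078, "V6A": 0.074},
    ("ventral", "L"): {"V4": 0.620, "PIT": 0.162},
    ("ventral", "R"): {"V4": 0.265, "VMV1": 0.114, "PHA1": 0.102, "PIT": 0.051},
    ("lateral_occipital", "L"): {"LO1": 0.357, "LO2": 0.274, "LO3": 0.215},
    ("lateral_occipital", "R"): {"LO1": 0.234, "LO2": 0.257, "LO3": 0.236},
}


def _fill_props(group: str, named: Mapping[str, float]) -> dict[str, float]:
    roster = GROUP_PARCELS[group]
    unknown = set(named) - set(roster)
    if unknown:
        raise ValueError(f"parcels {sorted(unknown)} not in group {group!r}")
    named_sum = float(sum(named.values()))
    if named_sum > 1.0 + 1e-9 or any(v < 0 for v in named.values()):
        raise ValueError(f"invalid probability vector for group {group!r}")
    rest = [p for p in roster if p not in named]
    fill = (1.0 - named_sum) / len(rest) if rest else 0.0
    props = {p: float(named.get(p, fill)) for p in roster}
    total = sum(props.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"probabilities for group {group!r} sum to {total}, not 1")
    return props


DEFAULT_ENDPOINT_PROPS: dict[tuple[str, str], dict[str, float]] = {
    key: _fill_props(key[0], named) for key, named in _NAMED_PROPS.items()
}

# Region boxes in world mm: (|x| interval, y interval, z interval).  The
# z gaps guarantee dominant superior-inferior displacement for every
# dorsal->ventral and dorsal->lateral streamline (see docs/methods.md).
REGION_BOXES: dict[str, tuple[tuple[float, float], tuple[float, float], tuple[float, float]]] = {
    "dorsal": ((34.0, 50.0), (-80.0, -60.0), (46.0, 70.0)),
    "ventral": ((34.0, 52.0), (-80.0, -60.0), (-70.0, -52.0)),
    "lateral_occipital": ((50.0, 62.0), (-80.0, -60.0), (-48.0, -30.0)),
}

_VOF_MIN_ABS_X = 34.0   # medial wall of the VOF corridor
_VOF_MAX_Y = -60.0      # anterior wall of the VOF corridor


@dataclass
class PhantomConfig:
    """Study conditions for one phantom.

    Counts are per generated hemisphere.  ``endpoint_props_*`` override the
    hemisphere defaults with a parcel-name -> probability mapping (named
    mass < 1 is spread uniformly over the group's unnamed parcels).
    """

    hemisphere: str = "L"                       # "L", "R" or "both"
    grid_shape: tuple[int, int, int] = (64, 96, 80)
    voxel_mm: float = 2.0
    n_vof: int = 2000
    ventral_fraction: float = 0.7               # dorsal->ventral vs dorsal->lateral split
    endpoint_props_dorsal: Mapping[str, float] | None = None
    endpoint_props_ventral: Mapping[str, float] | None = None
    endpoint_props_lateral: Mapping[str, float] | None = None
    n_ilf: int = 300
    n_af: int = 300
    n_clutter: int = 200
    jitter_mm: float = 0.5
    bow_mm: tuple[float, float] = (2.0, 6.0)    # lateral bow of the VOF arc
    step_mm: float = 1.0
    bundle_fa: float = 0.55
    background_fa: float = 0.15
    fa_noise_sd: float = 0.02
    ilf_margin_mm: float = 6.0
    af_margin_mm: float = 10.0
    clutter_clearance_mm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hemisphere not in ("L", "R", "both"):
            raise ValueError(f"hemisphere must be L, R or both, got {self.hemisphere!r}")
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be positive")
        for name in ("n_vof", "n_ilf", "n_af", "n_clutter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.ventral_fraction <= 1.0:
            raise ValueError("ventral_fraction must be in [0, 1]")
        if not 0.0 <= self.bundle_fa <= 1.0:
            raise ValueError("bundle_fa must be in [0, 1]")
        if not 0.0 <= self.background_fa <= 1.0:
            raise ValueError("background_fa must be in [0, 1]")
        if self.jitter_mm < 0 or self.fa_noise_sd < 0:
            raise ValueError("noise scales must be >= 0")
        extent = min(s * self.voxel_mm for s in self.grid_shape) / 2.0
        if self.ilf_margin_mm > extent or self.af_margin_mm > extent:
            raise ValueError("separation margins exceed grid extent")

    def hemispheres(self) -> list[str]:
        return ["L", "R"] if self.hemisphere == "both" else [self.hemisphere]

    def props(self, group: str, hemisphere: str) -> dict[str, float]:
        override = {
            "dorsal": self.endpoint_props_dorsal,
            "ventral": self.endpoint_props_ventral,
            "lateral_occipital": self.endpoint_props_lateral,
        }[group]
        if override is not None:
            return _fill_props(group, override)
        return DEFAULT_ENDPOINT_PROPS[(group, hemisphere)]


@dataclass
class Phantom:
    parcellation: ParcellationVolume
    tractogram: Tractogram
    fa: ScalarVolume
    truth: pd.DataFrame
    config: PhantomConfig

    def bundle_indices(self, bundle: str) -> list[int]:
        return [int(i) for i in self.truth.index[self.truth["bundle"] == bundle]]

    def bundle(self, bundle: str) -> Tractogram:
        return self.tractogram.subset(self.bundle_indices(bundle))


def default_affine(grid_shape: Sequence[int], voxel_mm: float) -> np.ndarray:
    """Scaled-identity affine with voxel centers symmetric about world 0."""
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = [-(n - 1) * voxel_mm / 2.0 for n in grid_shape]
    return affine


def _sign(hemisphere: str) -> float:
    return -1.0 if hemisphere == "L" else 1.0


# ---------------------------------------------------------------------------
# parcellation
# ---------------------------------------------------------------------------

def _default_centroids(group: str, hemisphere: str) -> dict[str, np.ndarray]:
    """Deterministic centroid spread over the two largest box extents.

    Positions are parameterized from the *lateral* edge so that left and
    right hemispheres are exact mirrors.
    """
    (ax0, ax1), (y0, y1), (z0, z1) = REGION_BOXES[group]
    names = GROUP_PARCELS[group]
    k = len(names)
    spans = {"x": ax1 - ax0, "y": y1 - y0, "z": z1 - z0}
    dims = sorted(spans, key=spans.get, reverse=True)[:2]
    na = int(np.ceil(np.sqrt(k)))
    nb = int(np.ceil(k / na))
    s = _sign(hemisphere)
    out: dict[str, np.ndarray] = {}
    for i, name in enumerate(names):
        fa = (i % na + 0.5) / na
        fb = (i // na + 0.5) / nb
        frac = {"x": 0.5, "y": 0.5, "z": 0.5}
        frac[dims[0]] = fa
        frac[dims[1]] = fb
        ax = ax0 + frac["x"] * (ax1 - ax0)
        out[name] = np.array(
            [s * ax, y0 + frac["y"] * (y1 - y0), z0 + frac["z"] * (z1 - z0)]
        )
    return out


def _voxel_centers(grid_shape: Sequence[int], affine: np.ndarray) -> tuple[np.ndarray, ...]:
    axes = [affine[i, i] * np.arange(grid_shape[i]) + affine[i, 3] for i in range(3)]
    return tuple(axes)


def _parcel_color(index: int, total: int) -> tuple[int, int, int]:
    r, g, b = colorsys.hsv_to_rgb((index / max(total, 1)) % 1.0, 0.75, 0.92)
    return int(round(r * 255)), int(round(g * 255)), int(round(b * 255))


def make_parcellation(config: PhantomConfig) -> ParcellationVolume:
    """Build the group-region parcellation (Voronoi within each region)."""
    affine = default_affine(config.grid_shape, config.voxel_mm)
    xs, ys, zs = _voxel_centers(config.grid_shape, affine)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    labels = np.zeros(config.grid_shape, dtype=np.int64)

    rows = []
    label_id = 0
    all_centroids: list[tuple[float, ...]] = []
    hemis = config.hemispheres()
    total = sum(len(GROUP_PARCELS[g]) for g in GROUP_PARCELS) * len(hemis)
    for hemi in hemis:
        s = _sign(hemi)
        hemi_mask = (s * X) > 0
        for group in ("dorsal", "lateral_occipital", "ventral"):
            (ax0, ax1), (y0, y1), (z0, z1) = REGION_BOXES[group]
            region = (
                hemi_mask
                & (np.abs(X) >= ax0) & (np.abs(X) <= ax1)
                & (Y >= y0) & (Y <= y1)
                & (Z >= z0) & (Z <= z1)
                & (labels == 0)
            )
            centroids = _default_centroids(group, hemi)
            names = list(GROUP_PARCELS[group])
            cpts = np.array([centroids[n] for n in names])
            for c in cpts:
                key = tuple(np.round(c, 6))
                if key in all_centroids:
                    raise ValueError(f"overlapping parcel centroids at {key}")
                all_centroids.append(key)
            idx = np.argwhere(region)
            if idx.size:
                pts = np.column_stack([X[region], Y[region], Z[region]])
                d2 = ((pts[:, None, :] - cpts[None, :, :]) ** 2).sum(axis=2)
                nearest = np.argmin(d2, axis=1)
                for j, name in enumerate(names):
                    sel = idx[nearest == j]
                    labels[sel[:, 0], sel[:, 1], sel[:, 2]] = label_id + 1 + j
            for j, name in enumerate(names):
                r, g, b = _parcel_color(label_id + j, total)
                rows.append(
                    {"label_id": label_id + 1 + j, "name": name, "hemisphere": hemi,
                     "group": group, "r": r, "g": g, "b": b}
                )
            label_id += len(names)
    table = validate_label_table(pd.DataFrame(rows))
    return ParcellationVolume(labels=labels, affine=affine, table=table)


def _parcel_voxel_centers(parc: ParcellationVolume, hemisphere: str) -> dict[int, np.ndarray]:
    """World centers of each parcel's voxels, ordered lateral-first.

    The lateral-first ordering makes index draws mirror-covariant between
    hemispheres.
    """
    out: dict[int, np.ndarray] = {}
    s = _sign(hemisphere)
    xs, ys, zs = _voxel_centers(parc.labels.shape, parc.affine)
    for label in parc.table.loc[parc.table["hemisphere"] == hemisphere, "label_id"]:
        idx = np.argwhere(parc.labels == int(label))
        if idx.size == 0:
            raise ValueError(f"parcel label {label} has no voxels")
        centers = np.column_stack([xs[idx[:, 0]], ys[idx[:, 1]], zs[idx[:, 2]]])
        order = np.lexsort((centers[:, 2], centers[:, 1], s * -centers[:, 0]))
        out[int(label)] = centers[order]
    return out


# ---------------------------------------------------------------------------
# streamline geometry helpers
# ---------------------------------------------------------------------------

def _bezier(ctrl: np.ndarray, n: int = 96) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    if len(ctrl) == 4:
        p0, p1, p2, p3 = ctrl
        return ((1 - t) ** 3 * p0 + 3 * (1 - t) ** 2 * t * p1
                + 3 * (1 - t) * t ** 2 * p2 + t ** 3 * p3)
    if len(ctrl) == 3:
        p0, p1, p2 = ctrl
        return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2
    raise ValueError("expected 3 or 4 control points")


def _resample(points: np.ndarray, step: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    length = s[-1]
    if length <= 0:
        raise ValueError("zero-length curve")
    targets = np.arange(0.0, length, step)
    if length - targets[-1] > 1e-9:
        targets = np.append(targets, length)
    return np.column_stack([np.interp(targets, s, points[:, k]) for k in range(3)])


def _smooth_jitter(
    points: np.ndarray,
    rng: np.random.Generator,
    jitter_mm: float,
    sign: float,
    knot_mm: float = 20.0,
    taper_mm: float = 4.0,
) -> np.ndarray:
    """Correlated Gaussian perturbation with per-point s.d. ``jitter_mm``.

    Offsets are drawn at ~``knot_mm`` spacing and linearly interpolated, so
    the perturbation bends the arc instead of roughening it (an iid draw per
    1 mm point would swamp the per-axis displacement totals the orientation
    classifier measures).  The taper pins both terminal points, preserving
    their parcel assignment.  The x component is scaled by ``sign`` so that
    mirror-twin phantoms stay exact mirrors.
    """
    if jitter_mm == 0:
        return points
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    length = s[-1]
    n_knots = max(3, int(length // knot_mm) + 2)
    knots_s = np.linspace(0.0, length, n_knots)
    offsets = rng.normal(0.0, jitter_mm, size=(n_knots, 3))
    offsets[:, 0] *= sign
    interp = np.column_stack([np.interp(s, knots_s, offsets[:, k]) for k in range(3)])
    w = np.minimum(1.0, np.minimum(s, length - s) / taper_mm)
    return points + interp * w[:, None]


def _axis_fractions(points: np.ndarray) -> np.ndarray:
    d = np.abs(np.diff(points, axis=0)).sum(axis=0)
    return d / d.sum()


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------

def make_vof_bundle(
    config: PhantomConfig,
    parcellation: ParcellationVolume,
    rng: np.random.Generator,
    hemisphere: str,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Vertically coursing streamlines with multinomial endpoint parcels.

    Each streamline runs from a dorsal-group parcel down to a ventral- or
    lateral-occipital-group parcel (split by ``ventral_fraction``) along a
    cubic Bezier bowed laterally, resampled at ``step_mm`` with smooth
    jitter.  Terminal points sit exactly on voxel centers of the assigned
    parcels.  Dominant-z orientation is asserted per streamline.
    """
    n = config.n_vof
    s = _sign(hemisphere)
    sub = parcellation.table[parcellation.table["hemisphere"] == hemisphere]
    name_to_label = dict(zip(sub["name"], sub["label_id"]))
    voxels = _parcel_voxel_centers(parcellation, hemisphere)

    streamlines: list[np.ndarray] = []
    records: list[dict] = []
    if n == 0:
        return streamlines, pd.DataFrame(
            columns=["bundle", "hemisphere", "dorsal_parcel", "target_parcel", "target_group"]
        )

    groups = {
        g: (list(GROUP_PARCELS[g]), np.array([config.props(g, hemisphere)[p]
                                              for p in GROUP_PARCELS[g]]))
        for g in ("dorsal", "ventral", "lateral_occipital")
    }
    for g, (_, p) in groups.items():
        if p.size == 0:
            raise ValueError(f"empty probability vector for group {g}")

    # fixed draw order: dorsal parcel, target-group flip, ventral parcel,
    # lateral parcel, then per-streamline voxel picks / bow / jitter
    d_names, d_probs = groups["dorsal"]
    v_names, v_probs = groups["ventral"]
    l_names, l_probs = groups["lateral_occipital"]
    d_idx = rng.choice(len(d_names), size=n, p=d_probs)
    to_ventral = rng.random(n) < config.ventral_fraction
    v_idx = rng.choice(len(v_names), size=n, p=v_probs)
    l_idx = rng.choice(len(l_names), size=n, p=l_probs)

    b_lo, b_hi = config.bow_mm
    for i in range(n):
        dorsal_name = d_names[d_idx[i]]
        if to_ventral[i]:
            target_group = "ventral"
            target_name = v_names[v_idx[i]]
        else:
            target_group = "lateral_occipital"
            target_name = l_names[l_idx[i]]
        lab_a = name_to_label[dorsal_name]
        lab_b = name_to_label[target_name]
        vox_a = voxels[lab_a]
        vox_b = voxels[lab_b]
        p0 = vox_a[rng.integers(len(vox_a))]
        p3 = vox_b[rng.integers(len(vox_b))]
        bow = rng.uniform(b_lo, b_hi)
        offset = np.array([s * bow, 0.0, 0.0])
        p1 = p0 + (p3 - p0) / 3.0 + offset
        p2 = p0 + 2.0 * (p3 - p0) / 3.0 + offset
        pts = _resample(_bezier(np.array([p0, p1, p2, p3])), config.step_mm)
        pts = _smooth_jitter(pts, rng, config.jitter_mm, s)
        pts[0], pts[-1] = p0, p3
        frac = _axis_fractions(pts)
        if not (frac[2] > max(frac[0], frac[1]) and frac[2] > 0.5):
            raise AssertionError(
                f"VOF streamline {i} lost dominant-z orientation (fractions {frac})"
            )
        streamlines.append(pts)
        records.append(
            {"bundle": "vof", "hemisphere": hemisphere, "dorsal_parcel": dorsal_name,
             "target_parcel": target_name, "target_group": target_group}
        )
    return streamlines, pd.DataFrame(records)


def make_reference_bundles(
    config: PhantomConfig, rng: np.random.Generator, hemisphere: str
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """ILF-like (dominant-y, medial) and AF-like (arcing, anterior) bundles.

    Separation from the VOF corridor is asserted per streamline: every ILF
    point keeps ``|x| + ilf_margin_mm`` inside the corridor's medial wall,
    every AF point stays ``af_margin_mm`` anterior to the corridor's front.
    """
    s = _sign(hemisphere)
    ilf: list[np.ndarray] = []
    max_ilf_abs_x = _VOF_MIN_ABS_X - config.ilf_margin_mm
    if max_ilf_abs_x <= 8.0:
        raise ValueError("ilf_margin_mm leaves no medial corridor for the ILF")
    for _ in range(config.n_ilf):
        ax = rng.uniform(8.0, min(18.0, max_ilf_abs_x - 2.0))
        z0 = rng.uniform(-45.0, -10.0)
        y = np.arange(-85.0, 30.0 + config.step_mm, config.step_mm)
        pts = np.column_stack([np.full_like(y, s * ax), y, np.full_like(y, z0)])
        pts = _smooth_jitter(pts, rng, config.jitter_mm, s, taper_mm=1e-6)
        frac = _axis_fractions(pts)
        if frac[1] <= max(frac[0], frac[2]):
            raise AssertionError("ILF streamline lost dominant-y orientation")
        if np.abs(pts[:, 0]).max() + config.ilf_margin_mm > _VOF_MIN_ABS_X:
            raise AssertionError("ILF streamline violates the medial margin")
        ilf.append(pts)

    af: list[np.ndarray] = []
    y_floor = _VOF_MAX_Y + config.af_margin_mm
    for _ in range(config.n_af):
        ax = rng.uniform(32.0, 48.0)
        p0 = np.array([s * ax, 25.0 + rng.uniform(-4, 4), 32.0 + rng.uniform(-4, 4)])
        p3 = np.array([s * (ax + rng.uniform(-2, 2)), 18.0 + rng.uniform(-4, 4),
                       -32.0 + rng.uniform(-4, 4)])
        p1 = np.array([s * ax, -35.0 + rng.uniform(-3, 3), 24.0])
        p2 = np.array([s * ax, -35.0 + rng.uniform(-3, 3), -24.0])
        pts = _resample(_bezier(np.array([p0, p1, p2, p3])), config.step_mm)
        pts = _smooth_jitter(pts, rng, config.jitter_mm, s, taper_mm=1e-6)
        if pts[:, 1].min() < y_floor:
            raise AssertionError("AF streamline violates the anterior margin")
        af.append(pts)
    return ilf, af


def make_clutter(
    config: PhantomConfig,
    parcellation: ParcellationVolume,
    rng: np.random.Generator,
    hemisphere: str,
) -> list[np.ndarray]:
    """Random short arcs with random dominant axis.

    At least one terminal point of every clutter streamline is kept at
    least ``clutter_clearance_mm`` away from all labeled voxels, so clutter
    can never satisfy the two-ROI endpoint criterion.
    """
    s = _sign(hemisphere)
    dist_mm = ndimage.distance_transform_edt(
        parcellation.labels == 0, sampling=[config.voxel_mm] * 3
    )
    shape = np.array(parcellation.labels.shape)

    def clearance(p: np.ndarray) -> float:
        vox = world_to_voxel(p, parcellation.affine)[0]
        if np.any(vox < 0) or np.any(vox >= shape):
            return np.inf
        return float(dist_mm[tuple(vox)])

    half = (shape - 1) * config.voxel_mm / 2.0
    out: list[np.ndarray] = []
    for _ in range(config.n_clutter):
        for _attempt in range(200):
            m = rng.uniform(-5.0, 58.0)
            start = np.array([s * m, rng.uniform(-85.0, 35.0), rng.uniform(-70.0, 70.0)])
            direction = rng.normal(size=3)
            direction[0] *= s
            direction /= np.linalg.norm(direction)
            length = rng.uniform(20.0, 60.0)
            end = start + direction * length
            mid = (start + end) / 2.0 + rng.normal(0.0, 4.0, size=3) * np.array([s, 1, 1])
            if np.any(np.abs(end) > half - 2) or np.any(np.abs(mid) > half - 2):
                continue
            if clearance(start) <= config.clutter_clearance_mm and \
               clearance(end) <= config.clutter_clearance_mm:
                continue
            pts = _resample(_bezier(np.array([start, mid, end])), config.step_mm)
            pts = _smooth_jitter(pts, rng, config.jitter_mm, s, taper_mm=1e-6)
            out.append(pts)
            break
        else:
            raise RuntimeError("could not place a clutter streamline in 200 attempts")
    return out


# ---------------------------------------------------------------------------
# FA field
# ---------------------------------------------------------------------------

def make_fa(
    config: PhantomConfig,
    tractogram: Tractogram,
    rng: np.random.Generator,
    affine: np.ndarray | None = None,
) -> ScalarVolume:
    """Smooth FA field: ``bundle_fa`` on traversed voxels, ``background_fa``
    elsewhere, plus Gaussian-smoothed noise of s.d. ``fa_noise_sd``."""
    if affine is None:
        affine = default_affine(config.grid_shape, config.voxel_mm)
    values = np.full(config.grid_shape, config.background_fa, dtype=np.float64)
    shape = np.array(config.grid_shape)
    if len(tractogram) > 0:
        # same voxel support as the tract volume / mean FA metrics
        vox = streamline_voxels(list(tractogram), affine, config.step_mm)
        inside = np.all((vox >= 0) & (vox < shape), axis=1)
        vox = vox[inside]
        values[vox[:, 0], vox[:, 1], vox[:, 2]] = config.bundle_fa
    if config.fa_noise_sd > 0:
        noise = ndimage.gaussian_filter(rng.standard_normal(config.grid_shape), sigma=2.0)
        sd = noise.std()
        if sd > 0:
            values = values + noise * (config.fa_noise_sd / sd)
    return ScalarVolume(values=np.clip(values, 0.0, 1.0), affine=affine)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def make_phantom(config: PhantomConfig) -> Phantom:
    """Generate the full phantom under one RNG in a fixed draw order:
    per hemisphere — VOF, ILF, AF, clutter — then the FA noise field."""
    rng = np.random.default_rng(config.seed)
    parcellation = make_parcellation(config)
    streamlines: list[np.ndarray] = []
    frames: list[pd.DataFrame] = []
    for hemi in config.hemispheres():
        vof, truth_vof = make_vof_bundle(config, parcellation, rng, hemi)
        ilf, af = make_reference_bundles(config, rng, hemi)
        clutter = make_clutter(config, parcellation, rng, hemi)
        streamlines.extend(vof + ilf + af + clutter)
        frames.append(truth_vof)
        for bundle, group in (("ilf", ilf), ("af", af), ("clutter", clutter)):
            frames.append(
                pd.DataFrame(
                    {"bundle": bundle, "hemisphere": hemi,
                     "dorsal_parcel": pd.NA, "target_parcel": pd.NA, "target_group": pd.NA},
                    index=range(len(group)),
                )
            )
    truth = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["bundle", "hemisphere", "dorsal_parcel", "target_parcel", "target_group"]
    )
    tractogram = Tractogram(
        streamlines=streamlines,
        space_id=f"phantom:seed={config.seed}",
        voxel_size=(config.voxel_mm,) * 3,
    )
    fa = make_fa(config, tractogram, rng, parcellation.affine)
    return Phantom(parcellation=parcellation, tractogram=tractogram, fa=fa,
                   truth=truth, config=config)


def save_phantom(phantom: Phantom, out_dir: str | Path, tract_format: str = "tck") -> dict[str, Path]:
    """Write parcellation.nii.gz, fa.nii.gz, tracts.<fmt>, truth.tsv, labels.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "parcellation": out / "parcellation.nii.gz",
        "labels": out / "labels.tsv",
        "fa": out / "fa.nii.gz",
        "tracts": out / f"tracts.{tract_format}",
        "truth": out / "truth.tsv",
    }
    write_parcellation(phantom.parcellation, paths["parcellation"], paths["labels"])
    write_scalar_volume(phantom.fa, paths["fa"])
    write_tractogram(phantom.tractogram, paths["tracts"], tract_format,
                     affine=phantom.parcellation.affine,
                     dimensions=phantom.parcellation.labels.shape)
    phantom.truth.to_csv(paths["truth"], sep="\t", index_label="index")
    return paths


def mirror_config(config: PhantomConfig) -> PhantomConfig:
    """Twin config on the opposite hemisphere (same seed and conditions)."""
    if config.hemisphere == "both":
        raise ValueError("mirror_config is defined for single-hemisphere configs")
    return replace(config, hemisphere="R" if config.hemisphere == "L" else "L")
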