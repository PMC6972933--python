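"""Virtual-dissection filters, with brute-force oracles on small instances."""

import numpy as np
import pytest

from vofdissect import (
    PhantomConfig,
    SelectionCriteria,
    Tractogram,
    make_phantom,
    run_selection,
)
from vofdissect.selection import (
    assign_endpoint_parcel,
    classify_orientation,
    filter_orientation,
    filter_relative_position,
    filter_roa,
    select_two_roi,
)
from vofdissect.tract_io import ScalarVolume, is_more_lateral, world_to_voxel

from conftest import tiny_parcellation


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "points, axis, fractions",
    [
        ([(0, 0, 0), (0, 0, 10)], "SI", (0, 0, 1)),
        ([(0, 0, 0), (0, 10, 0)], "AP", (0, 1, 0)),
        ([(0, 0, 0), (10, 0, 0)], "LR", (1, 0, 0)),
        # segment displacements sum to (2, 4, 6) -> fractions (1/6, 1/3, 1/2)
        ([(0, 0, 0), (1, 2, 3), (2, 4, 6)], "SI", (2 / 12, 4 / 12, 6 / 12)),
        # non-monotone path: |dz| accumulates
        ([(0, 0, 0), (0, 0, 5), (0, 4, 2)], "SI", (0, 4 / 12, 8 / 12)),
    ],
)
def test_orientation_fractions(points, axis, fractions):
    r = classify_orientation(np.array(points, dtype=float))
    assert r.dominant_axis == axis
    np.testing.assert_allclose(r.fractions, fractions, atol=1e-12)
    assert abs(sum(r.fractions) - 1.0) < 1e-9


def test_orientation_tie_prefers_si_then_ap():
    r = classify_orientation(np.array([[0, 0, 0], [0, 5, 5]], dtype=float))
    assert r.dominant_axis == "SI"
    r = classify_orientation(np.array([[0, 0, 0], [5, 5, 0]], dtype=float))
    assert r.dominant_axis == "AP"


def test_orientation_scale_invariance():
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(20, 3)).cumsum(axis=0)
    a = classify_orientation(pts)
    b = classify_orientation(pts * 7.3)
    np.testing.assert_allclose(a.fractions, b.fractions)
    assert a.dominant_axis == b.dominant_axis


# ---------------------------------------------------------------------------
# endpoint -> parcel assignment vs brute force
# ---------------------------------------------------------------------------

def brute_force_assign(point, parc, radius_mm):
    """Independent oracle: scan every voxel, nearest labeled center within
    radius, ties -> smaller label id."""
    vox = world_to_voxel(np.asarray(point, float), parc.affine)[0]
    shape = parc.labels.shape
    if all(0 <= vox[k] < shape[k] for k in range(3)) and parc.labels[tuple(vox)] > 0:
        return int(parc.labels[tuple(vox)])
    best = None
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                lab = parc.labels[i, j, k]
                if lab == 0:
                    continue
                center = parc.affine[:3, :3] @ [i, j, k] + parc.affine[:3, 3]
                d = float(np.linalg.norm(center - point))
                if d > radius_mm + 1e-9:
                    continue
                if best is None or d < best[0] - 1e-9 or (abs(d - best[0]) <= 1e-9 and lab < best[1]):
                    best = (d, int(lab))
    return None if best is None else best[1]


def test_assign_endpoint_matches_brute_force(tiny_parc):
    rng = np.random.default_rng(4)
    pts = rng.uniform(-2, 16, size=(60, 3))
    for p in pts:
        for radius in (0.0, 2.0, 4.0):
            assert assign_endpoint_parcel(p, tiny_parc, radius) == brute_force_assign(
                p, tiny_parc, radius
            )


def test_assign_endpoint_basic_cases(tiny_parc):
    # center of a labeled voxel
    assert assign_endpoint_parcel(np.array([2.0, 2.0, 12.0]), tiny_parc, 2.0) == 1
    # background, nearest labeled voxel beyond the radius -> None
    assert assign_endpoint_parcel(np.array([7.0, 7.0, 7.0]), tiny_parc, 1.0) is None
    with pytest.raises(ValueError):
        assign_endpoint_parcel(np.array([np.nan, 0, 0]), tiny_parc, 2.0)


def test_assign_endpoint_tie_prefers_smaller_label():
    # two labels with voxel centers equidistant from the probe point
    parc = tiny_parcellation(
        shape=(5, 1, 1),
        labels_spec=[(3, (slice(0, 1), slice(0, 1), slice(0, 1))),
                     (9, (slice(2, 3), slice(0, 1), slice(0, 1)))],
    )
    # world x: label 3 voxel center at 0, label 9 at 4; probe at 2 (+-2 from both).
    # probe rounds to voxel 1 (background), equidistant -> smaller label id
    assert assign_endpoint_parcel(np.array([2.0, 0.0, 0.0]), parc, 2.5) == 3


# ---------------------------------------------------------------------------
# two-ROI
# ---------------------------------------------------------------------------

def test_two_roi_accepts_a_to_b_either_order(tiny_parc):
    a_pt, b_pt = [2.0, 2.0, 12.0], [12.0, 2.0, 2.0]   # inside P1 (dorsal), P2 (ventral)
    t = Tractogram([
        np.array([a_pt, [7, 2, 7], b_pt]),            # dorsal -> ventral
        np.array([b_pt, [7, 2, 7], a_pt]),            # reversed order
        np.array([a_pt, [4, 2, 10], [2.0, 4.0, 12.0]]),  # both ends dorsal
    ])
    crit = SelectionCriteria(group_a=("dorsal",), group_b=("ventral",), hemisphere="L")
    accepted, assignments = select_two_roi(t, tiny_parc, crit)
    assert accepted == [0, 1]
    assert assignments[0] == (1, 2) and assignments[1] == (1, 2)


def test_two_roi_explicit_parcel_names(tiny_parc):
    """Explicit parcel-name sets configure the gyrus-based ROI variant."""
    t = Tractogram([np.array([[2.0, 2, 12], [7, 2, 7], [12.0, 2, 2]])])
    crit = SelectionCriteria(group_a=("P1",), group_b=("P2",), hemisphere="L")
    accepted, _ = select_two_roi(t, tiny_parc, crit)
    assert accepted == [0]
    with pytest.raises(ValueError, match="unknown parcel"):
        crit_bad = SelectionCriteria(group_a=("NOPE",), group_b=("P2",), hemisphere="L")
        select_two_roi(t, tiny_parc, crit_bad)


def test_two_roi_overlapping_groups_rejected(tiny_parc):
    crit = SelectionCriteria(group_a=("P1",), group_b=("P1", "P2"), hemisphere="L")
    with pytest.raises(ValueError, match="overlap"):
        crit.resolve_labels(tiny_parc)


def test_two_roi_matches_truth_on_phantom(small_phantom):
    """Accepted set equals the generator's truth VOF set (endpoints are a
    generator contract), cross-checked by brute-force re-assignment."""
    ph = small_phantom
    crit = SelectionCriteria(hemisphere="L")
    accepted, assignments = select_two_roi(ph.tractogram, ph.parcellation, crit)
    assert set(accepted) == set(ph.bundle_indices("vof"))
    name_of = dict(zip(ph.parcellation.table["label_id"], ph.parcellation.table["name"]))
    for i in accepted[:50]:
        la, lb = assignments[i]
        row = ph.truth.loc[i]
        assert name_of[la] == row["dorsal_parcel"]
        assert name_of[lb] == row["target_parcel"]


# ---------------------------------------------------------------------------
# ROA
# ---------------------------------------------------------------------------

def _roa_like(parc, mask):
    return ScalarVolume(values=mask.astype(float), affine=parc.affine)


def test_filter_roa_empty_and_full(small_phantom):
    ph = small_phantom
    idx = list(range(len(ph.tractogram)))
    empty = _roa_like(ph.parcellation, np.zeros_like(ph.parcellation.labels))
    assert filter_roa(ph.tractogram, idx, empty) == idx
    full = _roa_like(ph.parcellation, np.ones_like(ph.parcellation.labels))
    assert filter_roa(ph.tractogram, idx, full) == []


def test_filter_roa_coronal_plane_matches_brute_force(small_phantom):
    """Coronal-slab ROA: removed set equals a point-in-mask scan."""
    ph = small_phantom
    mask = np.zeros_like(ph.parcellation.labels)
    mask[:, 10, :] = 1
    roa = _roa_like(ph.parcellation, mask)
    idx = list(range(len(ph.tractogram)))
    kept = filter_roa(ph.tractogram, idx, roa)
    shape = np.array(mask.shape)
    expected = []
    for i in idx:
        vox = world_to_voxel(ph.tractogram.streamlines[i], roa.affine)
        hit = False
        for v in vox:
            if np.all(v >= 0) and np.all(v < shape) and mask[tuple(v)]:
                hit = True
                break
        if not hit:
            expected.append(i)
    assert kept == expected
    assert len(kept) < len(idx)   # the slab actually intersects streamlines


# ---------------------------------------------------------------------------
# relative position
# ---------------------------------------------------------------------------

def test_lateral_filter_simple_geometry():
    # candidate at x=-40 over z 0..20; reference at x=-25 -> retained (left lateral)
    cand = Tractogram([np.column_stack([np.full(21, -40.0), np.zeros(21), np.arange(21.0)])])
    ref = Tractogram([np.column_stack([np.full(21, -25.0), np.zeros(21), np.arange(21.0)])])
    kept, _ = filter_relative_position(cand, [0], ref, "lateral", "L")
    assert kept == [0]
    # medial candidate rejected in every slab
    kept, _ = filter_relative_position(ref, [0], cand, "lateral", "L")
    assert kept == []


def test_relative_filter_inapplicable_when_no_shared_z():
    cand = Tractogram([np.column_stack([np.full(11, -40.0), np.zeros(11), np.arange(50.0, 61.0)])])
    ref = Tractogram([np.column_stack([np.full(11, -25.0), np.zeros(11), np.arange(11.0)])])
    kept, n_na = filter_relative_position(cand, [0], ref, "lateral", "L")
    assert kept == [0] and n_na == 1


def brute_force_relative(t, indices, reference, relation, hemisphere, slab_mm=5.0):
    """Plain-loop oracle: candidate slab median vs reference slab envelope
    (the reference's extreme point toward the relation direction)."""
    axis = 0 if relation == "lateral" else 1
    ref_pts = np.vstack(list(reference))
    ref_slabs = np.floor(ref_pts[:, 2] / slab_mm).astype(int)
    toward_smaller = relation == "posterior" or hemisphere == "L"
    kept = []
    for i in indices:
        pts = t.streamlines[i]
        slabs = np.floor(pts[:, 2] / slab_mm).astype(int)
        shared = sorted(set(slabs) & set(ref_slabs))
        if not shared:
            kept.append(i)
            continue
        ok = True
        for s in shared:
            c = float(np.median(pts[slabs == s, axis]))
            vals = ref_pts[ref_slabs == s, axis]
            r = float(vals.min()) if toward_smaller else float(vals.max())
            if relation == "lateral":
                good = is_more_lateral(c, r, hemisphere)
            else:
                good = c < r
            if not good:
                ok = False
                break
        if ok:
            kept.append(i)
    return kept


def test_relative_filters_match_brute_force(small_phantom):
    ph = small_phantom
    idx = list(range(len(ph.tractogram)))
    for relation, ref in (("lateral", ph.bundle("ilf")), ("posterior", ph.bundle("af"))):
        kept, _ = filter_relative_position(ph.tractogram, idx, ref, relation, "L")
        assert kept == brute_force_relative(ph.tractogram, idx, ref, relation, "L")


def test_lateral_filter_separates_vof_from_ilf(small_phantom):
    """All true VOF retained, all ILF rejected by the lateral-to-ILF filter."""
    ph = small_phantom
    ilf = ph.bundle("ilf")
    vof_idx = ph.bundle_indices("vof")
    kept, _ = filter_relative_position(ph.tractogram, vof_idx, ilf, "lateral", "L")
    assert kept == vof_idx
    ilf_idx = ph.bundle_indices("ilf")
    kept, _ = filter_relative_position(ph.tractogram, ilf_idx, ilf, "lateral", "L")
    assert kept == []


def test_posterior_filter_rejects_af_against_itself(small_phantom):
    ph = small_phantom
    af = ph.bundle("af")
    af_idx = ph.bundle_indices("af")
    kept, _ = filter_relative_position(ph.tractogram, af_idx, af, "posterior", "L")
    assert kept == []


# ---------------------------------------------------------------------------
# composed pipeline
# ---------------------------------------------------------------------------

def _default_criteria(ph):
    return SelectionCriteria(
        hemisphere="L",
        lateral_reference=ph.bundle("ilf"),
        posterior_reference=ph.bundle("af"),
    )


def test_run_selection_empty_tractogram(small_phantom):
    report = run_selection(
        Tractogram([]), small_phantom.parcellation, _default_criteria(small_phantom)
    )
    assert report.accepted == [] and report.n_input == 0
    assert all(v == 0 for v in report.rejections.values())


def test_run_selection_recovers_truth(small_phantom, small_report):
    """Precision = recall = 1.0 against generator truth on the
    well-separated phantom; bookkeeping conserves counts."""
    truth = set(small_phantom.bundle_indices("vof"))
    accepted = set(small_report.accepted)
    assert accepted == truth
    small_report.check_conservation()
    assert small_report.rejections["two_roi"] == len(small_phantom.tractogram) - len(truth)


def test_run_selection_order_invariance(small_phantom):
    """Permuting streamline order permutes, but does not change, the
    accepted set."""
    ph = small_phantom
    rng = np.random.default_rng(8)
    perm = rng.permutation(len(ph.tractogram))
    shuffled = Tractogram([ph.tractogram.streamlines[i] for i in perm])
    crit = _default_criteria(ph)
    rep = run_selection(shuffled, ph.parcellation, crit)
    accepted_original_ids = sorted(perm[i] for i in rep.accepted)
    assert accepted_original_ids == sorted(ph.bundle_indices("vof"))


def test_run_selection_idempotent(small_phantom, small_report):
    ph = small_phantom
    accepted_t = ph.tractogram.subset(small_report.accepted)
    rep2 = run_selection(accepted_t, ph.parcellation, _default_criteria(ph))
    assert rep2.accepted == list(range(len(accepted_t)))


def test_independent_filters_commute():
    """two-ROI, orientation and ROA are per-streamline predicates: any
    application order yields the same accepted set."""
    ph = make_phantom(PhantomConfig(n_vof=80, n_ilf=20, n_af=20, n_clutter=15, seed=13))
    mask = np.zeros_like(ph.parcellation.labels)
    mask[:, 9:11, :] = 1
    roa = ScalarVolume(values=mask.astype(float), affine=ph.parcellation.affine)
    crit = SelectionCriteria(hemisphere="L")
    idx = list(range(len(ph.tractogram)))

    def two_roi(ind):
        acc, _ = select_two_roi(ph.tractogram, ph.parcellation, crit, indices=ind)
        return acc

    def orient(ind):
        return filter_orientation(ph.tractogram, ind, "SI", 0.5)

    def avoid(ind):
        return filter_roa(ph.tractogram, ind, roa)

    import itertools

    results = []
    for order in itertools.permutations([two_roi, orient, avoid]):
        current = idx
        for f in order:
            current = f(current)
        results.append(set(current))
    assert all(r == results[0] for r in results)


def test_min_axis_fraction_threshold():
    # SI fraction 0.5 exactly passes the default >= 0.5; dominance tie -> SI
    t = Tractogram([np.array([[0, 0, 0], [0, 5.0, 5.0]])])
    assert filter_orientation(t, [0], "SI", 0.5) == [0]
    assert filter_orientation(t, [0], "SI", 0.6) == []
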