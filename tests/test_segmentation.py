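"""Segmentation chain: flat field, cells, DNA objects, K/N, nucleolus."""

import numpy as np
import pytest

from conftest import match_truth_cell
from nucleopart import (
    DnaDetectionParams,
    DnaObject,
    NucleusGeometry,
    SegmentationParams,
    assign_kn,
    assign_objects_to_cells,
    detect_dna_objects,
    fit_nucleus_geometry,
    flat_field_correct,
    locate_nucleolus,
    nucleolus_mask,
    preprocess_dna,
    segment_cells,
)
from nucleopart.segmentation import NucleolusNotFound


# ---------------------------------------------------------------- flat field

def test_flat_field_median_subtraction():
    imgs = [np.full((8, 8), v, dtype=float) for v in (10, 20, 30)]
    out = flat_field_correct(imgs)
    assert np.all(out[2] == 10)    # 30 - median 20
    assert np.all(out[1] == 0)     # the median image maps to zero
    assert np.all(out[0] == -10)   # negatives preserved, no clipping


def test_flat_field_shape_mismatch():
    with pytest.raises(ValueError, match="shape"):
        flat_field_correct([np.zeros((4, 4)), np.zeros((5, 5))])


# --------------------------------------------------------------- cell bodies

def test_segment_cells_recovers_phantom_cells(segmented_phantom):
    _spec, m, truth, _segs = segmented_phantom
    masks = segment_cells(m["phase"])
    assert len(masks) == truth.n_cells
    for mask in masks:
        lab = match_truth_cell(mask, truth)
        true_mask = truth.cell_mask(lab)
        iou = (mask & true_mask).sum() / (mask | true_mask).sum()
        assert iou >= 0.7


def test_segment_cells_blank_image():
    assert segment_cells(np.full((64, 64), 7.0)) == []


def test_segment_cells_size_filter():
    """Objects outside the 2000-7000 px^2 window are rejected."""
    rng = np.random.default_rng(0)
    img = rng.normal(100.0, 1.0, (300, 600))
    yy, xx = np.indices(img.shape)
    small = (yy - 80) ** 2 + (xx - 100) ** 2 <= 17 ** 2    # ~900 px^2
    good = (yy - 150) ** 2 + (xx - 400) ** 2 <= 36 ** 2    # ~4070 px^2
    img[small] = 50.0
    img[good] = 50.0
    masks = segment_cells(img)
    assert len(masks) == 1
    rr, cc = np.nonzero(masks[0])
    assert abs(rr.mean() - 150) < 3 and abs(cc.mean() - 400) < 3


def test_segment_cells_offset_invariant(segmented_phantom):
    """A constant intensity offset does not change the segmentation."""
    _spec, m, _truth, _segs = segmented_phantom
    a = segment_cells(m["phase"])
    b = segment_cells(m["phase"] + 137.0)
    assert len(a) == len(b)
    for ma, mb in zip(a, b):
        np.testing.assert_array_equal(ma, mb)


def test_params_validation():
    with pytest.raises(ValueError):
        SegmentationParams(unsharp_weight=1.2)
    with pytest.raises(ValueError):
        SegmentationParams(unsharp_radii_px=(5, 5, 10))
    with pytest.raises(ValueError):
        DnaDetectionParams(rel_threshold=0.0)


# --------------------------------------------------------------- DNA objects

def test_detect_dna_objects_on_phantom(segmented_phantom):
    """Every true nucleus and kinetoplast is found within 2 px."""
    _spec, m, truth, _segs = segmented_phantom
    objs = detect_dna_objects(m["dna"])
    n_true = len(truth.nucleus_cell) + len(truth.kinetoplast_cell)
    assert len(objs) == n_true
    true_centres = list(truth.nucleus_centres.values()) + list(
        truth.kinetoplast_centres.values())
    for obj in objs:
        d = min(np.hypot(obj.centroid[0] - tc[0], obj.centroid[1] - tc[1])
                for tc in true_centres)
        assert d <= 2.0


def test_detect_dna_objects_constant_image():
    assert detect_dna_objects(np.full((64, 64), 3.0)) == []


def test_detect_dna_objects_prominence_cut():
    """A blob only 1 s.d. above background is below the 1.5 s.d. cut."""
    img = np.zeros((200, 200))
    yy, xx = np.indices(img.shape)
    blob = np.exp(-(((yy - 100) ** 2 + (xx - 100) ** 2) / (2 * 16.0)))
    img += blob
    sd = preprocess_dna(img).std()
    scaled = img * (1.0 * sd / img.max())  # peak prominence ~1.0 x s.d.
    assert detect_dna_objects(scaled) == []


def test_detect_dna_objects_gain_invariant(segmented_phantom):
    """Multiplying the DNA channel by c > 0 keeps the object count."""
    _spec, m, _truth, _segs = segmented_phantom
    n0 = len(detect_dna_objects(m["dna"]))
    for c in (0.2, 5.0):
        assert len(detect_dna_objects(m["dna"] * c)) == n0


# ------------------------------------------------------------ K/N assignment

def _obj(label, area, intensity=0.0):
    return DnaObject(label=label, mask=None, area_px2=area,
                     centroid=(0.0, 0.0), total_intensity=intensity,
                     peak=(0, 0))


@pytest.mark.parametrize(
    "areas,expected",
    [
        ((60, 240), ["K", "N"]),
        ((40, 50, 180), ["K", "K", "N"]),
        ((50, 60, 200, 210), ["K", "K", "N", "N"]),
    ],
)
def test_assign_kn_rules(areas, expected):
    objs = [_obj(i + 1, a) for i, a in enumerate(areas)]
    assigned, excluded = assign_kn(objs)
    assert not excluded
    assert [o.klass for o in assigned] == expected


@pytest.mark.parametrize("n", [0, 1, 5, 6])
def test_assign_kn_excludes_other_counts(n):
    objs = [_obj(i + 1, 50 + i) for i in range(n)]
    _assigned, excluded = assign_kn(objs)
    assert excluded


def test_assign_kn_tie_breaks():
    """Area ties break by intensity, then by lower label."""
    objs = [_obj(1, 100, 5.0), _obj(2, 100, 9.0)]
    assigned, _ = assign_kn(objs)
    assert {o.label: o.klass for o in assigned} == {1: "K", 2: "N"}
    objs = [_obj(1, 100, 5.0), _obj(2, 100, 5.0)]
    assigned, _ = assign_kn(objs)
    assert {o.label: o.klass for o in assigned} == {1: "N", 2: "K"}


def test_assignment_to_cells_drops_orphans():
    cell = np.zeros((20, 20), dtype=bool)
    cell[2:10, 2:10] = True
    inside = _obj(1, 5)
    inside.centroid = (5.0, 5.0)
    outside = _obj(2, 5)
    outside.centroid = (15.0, 15.0)
    grouped = assign_objects_to_cells([inside, outside], [cell])
    assert [o.label for o in grouped[0]] == [1]


# ----------------------------------------------------------- nucleus geometry

def _filled_ellipse(a, b, shape=(80, 80), angle=0.0):
    yy, xx = np.indices(shape)
    cy, cx = shape[0] / 2, shape[1] / 2
    u = (xx - cx) * np.cos(angle) + (yy - cy) * np.sin(angle)
    v = -(xx - cx) * np.sin(angle) + (yy - cy) * np.cos(angle)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def test_fit_nucleus_geometry_ellipse():
    """Axes 30 x 20 -> r within 1 px of 25; r/8 and r/4 follow."""
    geom = fit_nucleus_geometry(_filled_ellipse(15, 10, angle=0.4))
    assert abs(geom.r_px - 25.0) <= 1.0
    assert geom.edge_margin_px == pytest.approx(geom.r_px / 8)
    assert geom.nucleolus_radius_px == pytest.approx(geom.r_px / 4)


def test_fit_nucleus_geometry_circle():
    d = 21
    geom = fit_nucleus_geometry(_filled_ellipse(d / 2, d / 2))
    assert abs(geom.r_px - d) <= 1.0


def test_fit_nucleus_geometry_phantom_scale(segmented_phantom):
    """Default 28 x 22 phantom nuclei give r near 25 px."""
    _spec, _m, _truth, segs = segmented_phantom
    rs = [g.r_px for s in segs for g in s.geometries]
    assert rs and all(23.0 <= r <= 27.5 for r in rs)


def test_fit_nucleus_geometry_degenerate():
    mask = np.zeros((10, 10), dtype=bool)
    mask[5, 5] = True
    with pytest.raises(ValueError, match="degenerate"):
        fit_nucleus_geometry(mask)


# ----------------------------------------------------------------- nucleolus

def test_locate_nucleolus_off_centre_dip():
    """A dimmed disc 3 px off the centroid is found within 2 px."""
    nucleus = _filled_ellipse(15, 12, shape=(80, 80))
    img = np.where(nucleus, 100.0, 0.0)
    yy, xx = np.indices(img.shape)
    true_c = (40 + 3, 40)
    d2 = (yy - true_c[0]) ** 2 + (xx - true_c[1]) ** 2
    dip = d2 <= 6 ** 2
    img[dip & nucleus] = 60.0 + 20.0 * d2[dip & nucleus] / 36.0
    geom = locate_nucleolus(img, nucleus, fit_nucleus_geometry(nucleus))
    err = np.hypot(geom.nucleolus_centre[0] - true_c[0],
                   geom.nucleolus_centre[1] - true_c[1])
    assert err <= 2.0
    disc = nucleolus_mask(geom, nucleus)
    assert disc.sum() <= np.pi * geom.nucleolus_radius_px ** 2 * 1.2
    assert not (disc & ~nucleus).any()


def test_locate_nucleolus_uniform_tie_breaks_to_centroid():
    nucleus = _filled_ellipse(14, 11, shape=(64, 64))
    img = np.where(nucleus, 50.0, 0.0)
    geom = locate_nucleolus(img, nucleus, fit_nucleus_geometry(nucleus))
    rr, cc = np.nonzero(nucleus)
    centroid = (rr.mean(), cc.mean())
    err = np.hypot(geom.nucleolus_centre[0] - centroid[0],
                   geom.nucleolus_centre[1] - centroid[1])
    assert err <= 1.0


def test_locate_nucleolus_respects_edge_margin():
    """A darker pixel closer than r/8 to the edge is ignored."""
    nucleus = _filled_ellipse(15, 12, shape=(80, 80))
    img = np.where(nucleus, 100.0, 0.0)
    geom0 = fit_nucleus_geometry(nucleus)
    # darkest pixel at ~r/16 from the edge, interior dip elsewhere
    img[40, 54] = 1.0  # within ~1 px of the edge at x = 55
    yy, xx = np.indices(img.shape)
    dip = (yy - 40) ** 2 + (xx - 38) ** 2 <= 4 ** 2
    img[dip] = 60.0
    geom = locate_nucleolus(img, nucleus, geom0)
    assert np.hypot(geom.nucleolus_centre[0] - 40,
                    geom.nucleolus_centre[1] - 38) <= 2.0


def test_locate_nucleolus_tiny_nucleus_excluded():
    nucleus = _filled_ellipse(3, 2, shape=(20, 20))
    geom = NucleusGeometry(r_px=100.0)  # margin r/8 larger than the mask
    with pytest.raises(NucleolusNotFound):
        locate_nucleolus(np.zeros((20, 20)), nucleus, geom)


def test_phantom_nucleolus_centres_recovered(segmented_phantom):
    _spec, _m, truth, segs = segmented_phantom
    errs = []
    for s in segs:
        if s.excluded:
            continue
        lab = match_truth_cell(s.cell_mask, truth)
        centres = [truth.nucleolus_centres[k]
                   for k, c in truth.nucleus_cell.items() if c == lab]
        for g in s.geometries:
            errs.append(min(
                np.hypot(g.nucleolus_centre[0] - tc[0],
                         g.nucleolus_centre[1] - tc[1]) for tc in centres))
    assert errs and max(errs) <= 2.0
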