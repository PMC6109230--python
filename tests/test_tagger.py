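"""Blinded crescent tagging: rotation protocol, detection, vectors."""

import numpy as np
import pytest

from polarleaf.fieldmap import MidlineFrame
from polarleaf.surfseg import CellSegment, SurfaceProjection
from polarleaf.tagger import (
    CrescentCall,
    RotatedCellView,
    TagParams,
    assign_vector,
    detect_crescent,
    import_manual_tags,
    randomize_orientation,
    restore_coordinates,
    tag_cells,
)


def make_view(marker, mask, rotation=0):
    return RotatedCellView(
        cell_id=1,
        outline=np.zeros_like(marker, dtype=float),
        marker=np.asarray(marker, dtype=float),
        mask=np.asarray(mask, dtype=bool),
        rotation_deg=rotation,
        origin_rc=(0, 0),
        crop_shape=marker.shape,
    )


def disk_mask(n=41, r=15):
    yy, xx = np.mgrid[:n, :n]
    return (yy - n // 2) ** 2 + (xx - n // 2) ** 2 <= r**2


# --- rotation protocol ------------------------------------------------------


def test_rotation_deterministic_per_cell(clean_leaf):
    proj = clean_leaf["projection"]
    cell = next(c for c in clean_leaf["segmentation"].cells if not c.touches_border)
    v1 = randomize_orientation(cell, proj, seed=42)
    v2 = randomize_orientation(cell, proj, seed=42)
    assert v1.rotation_deg == v2.rotation_deg
    assert np.array_equal(v1.marker, v2.marker)


def test_rotation_frequencies_uniform(clean_leaf):
    """Each right angle drawn ~25% of the time over many (seed, cell) keys."""
    proj = clean_leaf["projection"]
    cell = next(c for c in clean_leaf["segmentation"].cells if not c.touches_border)
    from scipy.stats import chisquare

    draws = []
    for seed in range(10_000):
        rng = np.random.default_rng([seed, cell.id])
        draws.append(int(rng.integers(0, 4)))
    counts = np.bincount(draws, minlength=4)
    assert np.all(np.abs(counts / 10_000 - 0.25) < 0.02)
    assert chisquare(counts).pvalue > 1e-4


@pytest.mark.parametrize("k", [0, 1, 2, 3])
def test_transform_round_trip(k):
    view = RotatedCellView(
        cell_id=1,
        outline=np.zeros((7, 5)),
        marker=np.zeros((7, 5)),
        mask=np.ones((7, 5), bool),
        rotation_deg=90 * k,
        origin_rc=(10, 20),
        crop_shape=(7, 5),
    )
    corners = np.array([[0.0, 0.0], [0.0, 4.0], [6.0, 0.0], [6.0, 4.0], [3.0, 2.0]])
    for p in corners:
        leaf = view.crop_to_leaf(view.leaf_to_crop(p + [10, 20]))
        assert np.allclose(leaf, p + [10, 20], atol=1e-9)


def test_transform_90_degrees_hand_case():
    """CCW 90° of a (2, 3) crop: array value tracking matches point mapping."""
    arr = np.arange(6, dtype=float).reshape(2, 3)
    rot = np.rot90(arr)
    view = RotatedCellView(
        cell_id=1, outline=rot, marker=rot, mask=np.ones_like(rot, bool),
        rotation_deg=90, origin_rc=(0, 0), crop_shape=(2, 3),
    )
    for i in range(rot.shape[0]):
        for j in range(rot.shape[1]):
            r, c = view.crop_to_leaf((i, j)).astype(int)
            assert arr[r, c] == rot[i, j]


# --- detection --------------------------------------------------------------


def test_detect_no_signal_skips():
    mask = disk_mask()
    call = detect_crescent(make_view(np.zeros(mask.shape), mask))
    assert call.status == "skipped" and call.skip_reason == "no signal"


def test_detect_uniform_coating_is_unpolarized():
    mask = disk_mask()
    from skimage.morphology import dilation, disk as disk_se

    marker = np.zeros(mask.shape)
    marker[dilation(~mask, disk_se(4)) & mask] = 100.0  # coat the entire inner rim
    call = detect_crescent(make_view(marker, mask))
    assert call.status == "skipped" and call.skip_reason == "unpolarized"


def test_detect_synthetic_crescent_midpoint(clean_leaf):
    """Detected midpoints sit within 2 px of the true arc midpoint."""
    geom = clean_leaf["geometry"]
    truth = clean_leaf["truth"].records.set_index("cell_id")
    proj = clean_leaf["projection"]
    seg = clean_leaf["segmentation"]
    tf = clean_leaf["transform"]
    errors = []
    for cell in seg.cells:
        if cell.touches_border:
            continue
        view = randomize_orientation(cell, proj, seed=9)
        call = detect_crescent(view)
        if call.status != "tagged":
            continue
        (call2,) = restore_coordinates([call], [view])
        # match segmented cell to the truth cell containing its centroid
        from shapely.geometry import Point

        xy = tf.to_leaf(np.array(call2.midpoint_rc))
        cen_xy = tf.to_leaf(np.array(cell.centroid_rc))
        owner = None
        for cid, poly in geom.cells.items():
            if poly.contains(Point(*cen_xy)):
                owner = cid
                break
        if owner is None:
            continue
        rec = truth.loc[owner]
        err = np.hypot(xy[0] - rec.crescent_mid_x, xy[1] - rec.crescent_mid_y)
        errors.append(err / geom.pixel_size)
    assert len(errors) > 100
    assert np.median(errors) <= 2.0


def test_detect_recovery_rate(clean_leaf):
    """Noise-free proximodistal leaf: ≥90% tagged, median |α| ≤ 5°."""
    vec, calls, views = tag_cells(
        clean_leaf["projection"], clean_leaf["segmentation"], clean_leaf["frame"], seed=1
    )
    tagged = vec[vec.status == "tagged"]
    assert len(tagged) / len(vec) >= 0.90
    assert np.median(np.abs(tagged.alpha_deg)) <= 5.0
    # skip accounting
    assert (vec.status == "tagged").sum() + (vec.status == "skipped").sum() == len(vec)


def test_blinding_soundness(clean_leaf):
    """Enabling random rotation leaves the α measurements unchanged.

    The detector is rotation-equivariant by construction up to boundary
    resampling, which is pixel-quantized: the midpoint can move by at
    most ~1 px, i.e. atan(1 px / midpoint-centroid distance) ≈ 4–5° for
    the smallest cells.  Per-cell deviations must stay inside that
    discretization bound and the α distribution must not shift at all.
    """
    kw = dict(seed=5)
    v_blind, _, _ = tag_cells(
        clean_leaf["projection"], clean_leaf["segmentation"], clean_leaf["frame"],
        blind=True, **kw,
    )
    v_plain, _, _ = tag_cells(
        clean_leaf["projection"], clean_leaf["segmentation"], clean_leaf["frame"],
        blind=False, **kw,
    )
    m = v_blind.merge(v_plain, on="cell_id", suffixes=("_b", "_p"))
    both = m[(m.status_b == "tagged") & (m.status_p == "tagged")]
    assert len(both) >= 0.95 * max((m.status_b == "tagged").sum(), 1)
    d = ((both.alpha_deg_b - both.alpha_deg_p) + 180) % 360 - 180
    assert np.abs(d).max() <= 5.0  # single-boundary-pixel bound
    assert np.abs(d).median() <= 0.5
    assert abs(d.mean()) <= 0.2  # no systematic rotation-induced bias
    from polarleaf.circular import circular_sd

    assert circular_sd(both.alpha_deg_b) == pytest.approx(
        circular_sd(both.alpha_deg_p), abs=0.5
    )


# --- vector assignment ------------------------------------------------------


FRAME = MidlineFrame(base=(0.0, 0.0), tip=(0.0, 10.0))


def _cell_with_centroid(rc):
    return CellSegment(
        id=1, bbox=(0, 0, 1, 1), mask=np.ones((1, 1), bool),
        centroid_rc=rc, boundary_rc=np.zeros((1, 2)), touches_border=False, area_px=1,
    )


def _tagged_call(mid_rc):
    return CrescentCall(cell_id=1, status="tagged", midpoint_rc=mid_rc)


def test_assign_vector_proximal_gives_zero():
    # image frame: midpoint directly below centroid (proximal, tip-up leaf)
    n_rows = 100
    vec = assign_vector(_tagged_call((60.0, 30.0)), _cell_with_centroid((50.0, 30.0)),
                        FRAME, 1.0, n_rows)
    assert vec.alpha_deg == pytest.approx(0.0, abs=1e-9)
    assert vec.magnitude_um == pytest.approx(10.0)


def test_assign_vector_distal_gives_180():
    vec = assign_vector(_tagged_call((40.0, 30.0)), _cell_with_centroid((50.0, 30.0)),
                        FRAME, 1.0, 100)
    assert abs(vec.alpha_deg) == pytest.approx(180.0, abs=1e-9)


def test_assign_vector_45_degrees():
    # leaf frame: origin (0,0), centroid (1,1) μm, midline +y ⇒ α = −45° (rightward)
    frame_x = MidlineFrame(base=(0.0, 0.0), tip=(1.0, 0.0))  # midline along +x
    n_rows = 10
    call = _tagged_call((9.0, 0.0))  # leaf (0, 0)
    cell = _cell_with_centroid((8.0, 1.0))  # leaf (1, 1)
    vec = assign_vector(call, cell, frame_x, 1.0, n_rows)
    assert vec.alpha_deg == pytest.approx(45.0, abs=1e-9)
    assert vec.magnitude_um == pytest.approx(np.sqrt(2.0))


def test_assign_vector_zero_length_fails():
    with pytest.raises(ValueError):
        assign_vector(_tagged_call((50.0, 30.0)), _cell_with_centroid((50.0, 30.0)),
                      FRAME, 1.0, 100)


def test_restore_requires_transform():
    call = CrescentCall(cell_id=99, status="tagged", midpoint_crop=(1.0, 1.0))
    with pytest.raises(ValueError, match="missing"):
        restore_coordinates([call], [])


# --- manual import ----------------------------------------------------------


def test_import_manual_tags_round_trip(clean_leaf):
    seg = clean_leaf["segmentation"]
    cell = next(c for c in seg.cells if not c.touches_border)
    bpt = cell.boundary_rc[0]
    records = [
        {"cell_id": cell.id, "status": "tagged", "midpoint_xy_leaf": [float(bpt[0]), float(bpt[1])]},
        {"cell_id": cell.id, "status": "skipped"},
        {"cell_id": cell.id, "status": "tagged",
         "midpoint_xy_leaf": [float(cell.centroid_rc[0]), float(cell.centroid_rc[1])]},
    ]
    calls, rejects = import_manual_tags(records, seg)
    assert len(calls) == 2  # tagged-on-boundary + skipped
    assert calls[0].status == "tagged" and calls[1].status == "skipped"
    assert len(rejects) == 1  # interior midpoint rejected
    assert "boundary" in rejects[0][1]
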