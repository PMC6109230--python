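"""Midline frame, grid downsampling, axial averaging, regions, colors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polarleaf.circular import circular_correlation, wrap_angle, wrap_axial
from polarleaf.fieldmap import (
    AxialField,
    DownsampleParams,
    MidlineFrame,
    angle_colormap,
    axial_average,
    build_frame,
    downsample,
    region_grid_average,
    triangular_grid,
)


# --- frame ------------------------------------------------------------------


def test_frame_vertical_midline_has_zero_rotation():
    f = build_frame((0, 0), (0, 10))
    assert f.rotation_to_vertical == pytest.approx(0.0)
    assert f.angle_to_midline((0, 1)) == pytest.approx(0.0)


def test_frame_horizontal_midline():
    f = build_frame((0, 0), (10, 0))
    assert f.angle_to_midline((1, 0)) == pytest.approx(0.0)
    rotated = f.to_frame((10, 0))
    assert rotated[0] == pytest.approx(0.0, abs=1e-9)
    assert rotated[1] == pytest.approx(10.0)


def test_frame_midline_and_antimidline():
    f = build_frame((3, -2), (7, 5))
    assert f.angle_to_midline(f.vector) == pytest.approx(0.0, abs=1e-9)
    assert abs(f.angle_to_midline(-f.vector)) == pytest.approx(180.0, abs=1e-9)


def test_frame_coincident_points_fail():
    with pytest.raises(ValueError):
        build_frame((1, 1), (1, 1))


# --- downsampling -----------------------------------------------------------


def test_downsample_identical_angles():
    rng = np.random.default_rng(0)
    pos = rng.uniform(0, 100, (50, 2))
    ds = downsample(pos, np.full(50, 30.0), DownsampleParams(20, 15, 1))
    assert len(ds.mean_angle) > 0
    assert np.allclose(ds.mean_angle, 30.0, atol=1e-9)
    assert np.all(ds.support >= 1)


def test_downsample_cancellation_guard():
    """Two antiparallel vectors equidistant from every vertex are dropped."""
    pos = np.array([[0.0, 0.0], [0.0, 0.0]])
    ds = downsample(pos, np.array([90.0, -90.0]), DownsampleParams(10, 5, 1))
    assert len(ds.mean_angle) == 0


def test_downsample_vertex_consistency():
    """Vectors placed exactly at vertices with tight maxdist: identity."""
    params = DownsampleParams(grid_spacing=20.0, maxdist=9.0, neighbor_threshold=1)
    grid = triangular_grid((0, 0, 100, 100), 20.0)
    angles = wrap_angle(np.linspace(-170, 170, len(grid)))
    ds = downsample(grid, angles, params, bounds=(0, 0, 100, 100))
    assert len(ds.mean_angle) == len(grid)
    order = np.lexsort((ds.vertices[:, 0], ds.vertices[:, 1]))
    order_in = np.lexsort((grid[:, 0], grid[:, 1]))
    assert np.allclose(ds.mean_angle[order], angles[order_in], atol=1e-9)


def test_downsample_rotation_equivariance():
    """Rotating positions, vectors and the frame together is a no-op on α."""
    rng = np.random.default_rng(1)
    pos = rng.uniform(0, 200, (120, 2))
    alpha = rng.uniform(-180, 180, 120)
    params = DownsampleParams(30, 25, 2)
    f0 = build_frame((0, 0), (0, 1))
    ds0 = downsample(f0.to_frame(pos), alpha, params)
    theta = np.radians(37.0)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    f1 = build_frame((0, 0), tuple(rot @ [0, 1]))
    ds1 = downsample(f1.to_frame(pos @ rot.T), alpha, params)
    assert len(ds0.mean_angle) == len(ds1.mean_angle)
    o0 = np.lexsort((ds0.vertices[:, 0], ds0.vertices[:, 1]))
    o1 = np.lexsort((ds1.vertices[:, 0], ds1.vertices[:, 1]))
    assert np.allclose(ds0.vertices[o0], ds1.vertices[o1], atol=1e-6)
    d = np.abs(wrap_angle(ds0.mean_angle[o0] - ds1.mean_angle[o1]))
    assert d.max() < 1e-6


def test_downsample_tracks_divergent_field():
    """Vertex means correlate with the generator's local field angle."""
    from polarleaf import synthleaf as sl

    g = sl.generate_leaf_geometry(300.0, n_cells=300, seed=21)
    truth = sl.generate_truth(g, sl.FieldSpec("divergent", 20.0, divergence_gain=45.0, seed=22))
    r = truth.records
    ds = downsample(
        r[["centroid_x", "centroid_y"]].to_numpy(),
        r["true_angle_deg"].to_numpy(),
        DownsampleParams(25, 20, 3),
    )
    spec = sl.FieldSpec("divergent", 0.0, divergence_gain=45.0)
    L = 1.6 * 300.0
    expected = []
    for x, y in ds.vertices:
        hw = sl._half_width_at(g.outline, y)
        expected.append(
            sl.true_field_angle(spec, float(np.clip(x / hw, -1, 1)), float(np.clip(y / L, 0, 1)))
        )
    assert len(ds.mean_angle) > 30
    assert circular_correlation(ds.mean_angle, expected) >= 0.8


def test_downsample_support_bookkeeping():
    rng = np.random.default_rng(3)
    pos = rng.uniform(0, 50, (40, 2))
    ds = downsample(pos, np.zeros(40), DownsampleParams(10, 12, 2))
    assert int(ds.support.sum()) >= 40 - 5  # nearly all vectors reach ≥1 vertex


# --- axial averaging --------------------------------------------------------


def doubled_angle_oracle(orientations_deg):
    a = 2.0 * np.radians(np.asarray(orientations_deg))
    return wrap_axial(0.5 * np.degrees(np.arctan2(np.sin(a).sum(), np.cos(a).sum())))


def test_axial_average_identical_orientations():
    pos = np.zeros((5, 2))
    field = axial_average(pos, [40.0] * 5, radius=1.0, grid_vertices=np.array([[0.0, 0.0]]),
                          neighbor_threshold=1)
    assert field.axis_angle[0] == pytest.approx(40.0, abs=1e-9)
    assert field.anisotropy[0] == pytest.approx(1.0)


def test_axial_average_flip_invariance():
    pos = np.zeros((4, 2))
    grid = np.array([[0.0, 0.0]])
    f1 = axial_average(pos, [40.0, 40.0, 40.0, 40.0], 1.0, grid, neighbor_threshold=1)
    f2 = axial_average(pos, [40.0, 220.0, 40.0, 220.0], 1.0, grid, neighbor_threshold=1)
    assert f1.axis_angle[0] == pytest.approx(f2.axis_angle[0], abs=1e-9)
    assert f1.anisotropy[0] == pytest.approx(f2.anisotropy[0], abs=1e-12)


def test_axial_average_isotropic_cloud():
    rng = np.random.default_rng(4)
    n = 1000
    pos = np.zeros((n, 2))
    ori = rng.uniform(-90, 90, n)
    field = axial_average(pos, ori, 1.0, np.array([[0.0, 0.0]]), neighbor_threshold=1)
    assert field.anisotropy[0] <= 0.55


@given(st.lists(st.floats(-90, 90), min_size=2, max_size=40))
@settings(deadline=None, max_examples=100)
def test_axial_pca_equals_doubled_angle_oracle(orientations):
    """PCA of superimposed ± unit segments ≡ doubled-angle circular mean."""
    pos = np.zeros((len(orientations), 2))
    field = axial_average(pos, orientations, 1.0, np.array([[0.0, 0.0]]), neighbor_threshold=1)
    if len(field.axis_angle) == 0:
        return
    oracle = doubled_angle_oracle(orientations)
    d = abs(wrap_axial(field.axis_angle[0] - oracle))
    d = min(d, 180 - d)
    # degenerate (isotropic) samples have no defined axis; skip those
    a2 = 2 * np.radians(np.asarray(orientations))
    r2 = np.hypot(np.cos(a2).sum(), np.sin(a2).sum()) / len(orientations)
    if r2 > 1e-6:
        assert d < 1e-6


# --- regions & colors -------------------------------------------------------


def test_region_average_uniform_field():
    rng = np.random.default_rng(5)
    pos = rng.uniform(0, 90, (200, 2))
    reg = region_grid_average(pos, np.zeros(200))
    assert len(reg) == 9
    assert np.allclose(reg.mean_angle_deg, 0.0, atol=1e-9)


def test_region_average_single_vector():
    reg = region_grid_average(np.array([[1.0, 2.0]]), np.array([33.0]))
    assert len(reg) == 1
    assert reg.mean_angle_deg.iloc[0] == pytest.approx(33.0)


def test_region_average_divergent_ordering():
    """Lateral-proximal regions splay more than the midline-proximal one."""
    from polarleaf import synthleaf as sl

    g = sl.generate_leaf_geometry(300.0, n_cells=300, seed=23)
    truth = sl.generate_truth(g, sl.FieldSpec("divergent", 10.0, divergence_gain=45.0, seed=24))
    r = truth.records
    reg = region_grid_average(
        r[["centroid_x", "centroid_y"]].to_numpy(), r["true_angle_deg"].to_numpy()
    ).set_index(["row", "col"])
    mid = abs(reg.loc[(0, 1), "mean_angle_deg"])
    assert abs(reg.loc[(0, 0), "mean_angle_deg"]) > mid
    assert abs(reg.loc[(0, 2), "mean_angle_deg"]) > mid


def test_angle_colormap_periodicity():
    assert np.allclose(angle_colormap(30.0), angle_colormap(390.0))
    assert np.allclose(angle_colormap(30.0, axial=True), angle_colormap(210.0, axial=True))
    assert not np.allclose(angle_colormap(0.0), angle_colormap(180.0))
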