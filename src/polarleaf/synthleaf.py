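"""Synthetic leaf-epidermis generator with known geometry and polarity.

Real confocal stacks for this assay are not publicly deposited, so this
module builds a stand-in with full ground truth: a leaf-shaped sheet of
Lloyd-relaxed Voronoi cells, a per-cell true polarity angle drawn from a
configurable field (proximodistal or divergent) with wrapped-normal
angular noise, and a renderer that turns geometry + truth into a
two-channel z-stack (membrane network and boundary crescents) with mild
surface-height variation and photon/detector noise.

The leaf frame is mathematical: μm units, midline along +y from base
(0, 0) to tip (0, L), angles measured counterclockwise from the midline
so that a proximally placed crescent gives a polarity angle of 0°.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import shapely
import shapely.affinity
from scipy.spatial import Voronoi
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import substring
from skimage.draw import polygon as draw_polygon
from skimage.morphology import dilation, disk
from skimage.segmentation import find_boundaries

from .circular import sample_wrapped_normal, wrap_angle
from .stack import ImageStack

LENGTH_TO_WIDTH = 1.6  # ovate outline aspect ratio (length : width)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class LeafGeometry:
    """Leaf outline tiled by cell polygons, with midline and pixel size."""

    outline: Polygon
    cells: dict  # cell id (int) -> shapely Polygon (μm)
    midline: tuple  # ((x, y) base, (x, y) tip) μm
    pixel_size: float  # μm per pixel

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        base, tip = self.midline
        if tuple(base) == tuple(tip):
            raise ValueError("midline base and tip coincide")

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class FieldSpec:
    """Ground-truth polarity field specification.

    field_type
        ``"proximodistal"`` — every true angle is 0° plus noise;
        ``"divergent"`` — angles deflect away from the midline toward the
        margin, maximally in the proximal lamina.
    noise_sigma_deg
        Circular SD of wrapped-normal angular noise (degrees, ≥ 0).
    divergence_gain
        Maximal lateral splay in degrees at the margin of the leaf base
        (only used by the divergent field); ≥ 0.
    """

    field_type: str = "proximodistal"
    noise_sigma_deg: float = 0.0
    divergence_gain: float = 45.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.field_type not in ("proximodistal", "divergent"):
            raise ValueError(f"unknown field_type {self.field_type!r}")
        if self.noise_sigma_deg < 0 or self.divergence_gain < 0:
            raise ValueError("noise_sigma_deg and divergence_gain must be ≥ 0")


@dataclass
class GroundTruthField:
    """Per-cell truth table plus the generating spec.

    ``records`` columns: cell_id, centroid_x, centroid_y, true_angle_deg
    (leaf frame, (−180°, 180°]), crescent_mid_x, crescent_mid_y,
    crescent_arc_pos (arc-length position of the crescent centre along the
    cell's exterior ring, μm).
    """

    records: pd.DataFrame
    spec: FieldSpec

    def to_csv(self, path) -> None:
        cols = [
            "cell_id",
            "centroid_x",
            "centroid_y",
            "true_angle_deg",
            "crescent_mid_x",
            "crescent_mid_y",
        ]
        self.records[cols].to_csv(path, index=False)


@dataclass
class RenderParams:
    """Rasterization parameters for :func:`render_stack`."""

    membrane_width_px: float = 2.0
    membrane_intensity: float = 200.0
    crescent_intensity: float = 255.0
    background_intensity: float = 5.0
    crescent_arc_fraction: float = 0.25
    crescent_inset_px: float = 1.5  # cytoplasmic offset off the wall, toward the cell interior
    z_slices: int = 5
    surface_amplitude_px: float = 1.0
    noise_model: str = "gaussian"  # none | gaussian | poisson
    noise_magnitude: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.crescent_arc_fraction < 1.0):
            raise ValueError("crescent_arc_fraction must be in (0, 1)")
        if self.z_slices < 1:
            raise ValueError("z_slices must be ≥ 1")
        if self.membrane_width_px <= 0:
            raise ValueError("membrane_width_px must be positive")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")


@dataclass
class RasterTransform:
    """Affine map between the leaf μm frame and raster pixel coords.

    col = (x − x0) / pixel_size ; row = (y0 − y) / pixel_size
    (the raster y-axis points down; the leaf tip renders at the top).
    """

    x0: float
    y0: float
    pixel_size: float
    shape: tuple  # (rows, cols)

    def to_pixel(self, points_xy) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
        col = (pts[:, 0] - self.x0) / self.pixel_size
        row = (self.y0 - pts[:, 1]) / self.pixel_size
        out = np.column_stack([row, col])
        return out[0] if np.asarray(points_xy).ndim == 1 else out

    def to_leaf(self, points_rc) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_rc, dtype=float))
        x = self.x0 + pts[:, 1] * self.pixel_size
        y = self.y0 - pts[:, 0] * self.pixel_size
        out = np.column_stack([x, y])
        return out[0] if np.asarray(points_rc).ndim == 1 else out


# ---------------------------------------------------------------------------
# geometry


def ovate_outline(width_um: float, n_vertices: int = 128) -> Polygon:
    """Symmetric ovate leaf outline: base at (0, 0), tip at (0, L)."""
    length = LENGTH_TO_WIDTH * width_um
    u = np.linspace(0.0, 1.0, n_vertices // 2)
    half_w = 0.5 * width_um * np.sin(np.pi * u) ** 0.7
    right = np.column_stack([half_w, u * length])
    left = np.column_stack([-half_w[::-1], u[::-1] * length])
    coords = np.vstack([right, left])[:-1]
    return Polygon(coords)


def _sample_in_polygon(poly: Polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    minx, miny, maxx, maxy = poly.bounds
    pts = []
    while len(pts) < n:
        cand = rng.uniform([minx, miny], [maxx, maxy], size=(4 * n, 2))
        inside = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        pts.extend(cand[inside][: n - len(pts)].tolist())
    return np.asarray(pts)


def _clipped_voronoi(points: np.ndarray, outline: Polygon):
    """Voronoi cells of ``points`` clipped to ``outline``.

    Far guard points around the domain make every interior region finite.
    """
    minx, miny, maxx, maxy = outline.bounds
    cx, cy = (minx + maxx) / 2, (miny + maxy) / 2
    r = 4.0 * max(maxx - minx, maxy - miny)
    theta = np.linspace(0, 2 * np.pi, 9)[:-1]
    guards = np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])
    vor = Voronoi(np.vstack([points, guards]))
    cells = []
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            cells.append(None)
            continue
        poly = Polygon(vor.vertices[region])
        clipped = poly.intersection(outline)
        if clipped.is_empty:
            cells.append(None)
            continue
        if clipped.geom_type == "MultiPolygon":
            clipped = max(clipped.geoms, key=lambda g: g.area)
        if clipped.geom_type != "Polygon" or clipped.area <= 0:
            cells.append(None)
            continue
        cells.append(clipped)
    return cells


def generate_leaf_geometry(
    width_um: float,
    n_cells: Optional[int] = None,
    cell_density: Optional[float] = None,
    anisotropy: float = 1.0,
    seed: int = 0,
    pixel_size: float = 0.5,
    lloyd_iterations: int = 4,
) -> LeafGeometry:
    """Tile an ovate leaf domain with Lloyd-relaxed Voronoi cells.

    Parameters
    ----------
    width_um
        Leaf blade width (the staging variable); length is 1.6 × width.
    n_cells, cell_density
        Target cell count, or cells per μm² (exactly one required).
    anisotropy
        Cell elongation ratio along the midline; 1 gives isotropic cells,
        2 stretches cells 2:1 proximodistally.  Implemented by relaxing
        the tessellation in a midline-compressed space and mapping back.
    seed
        Deterministic geometry for a fixed seed.
    """
    if width_um <= 0:
        raise ValueError("width_um must be positive")
    if anisotropy <= 0:
        raise ValueError("anisotropy must be positive")
    outline = ovate_outline(width_um)
    if (n_cells is None) == (cell_density is None):
        raise ValueError("specify exactly one of n_cells / cell_density")
    if n_cells is None:
        n_cells = int(round(cell_density * outline.area))
    if n_cells < 3:
        raise ValueError("degenerate domain: fewer than 3 interior cells")

    rng = np.random.default_rng(seed)
    squeezed = shapely.affinity.scale(outline, 1.0, 1.0 / anisotropy, origin=(0, 0))
    points = _sample_in_polygon(squeezed, n_cells, rng)
    cells = None
    for _ in range(lloyd_iterations):
        cells = _clipped_voronoi(points, squeezed)
        points = np.array(
            [(c.centroid.x, c.centroid.y) if c is not None else p for c, p in zip(cells, points)]
        )
    cells = _clipped_voronoi(points, squeezed)
    cell_map = {}
    next_id = 1
    for c in cells:
        if c is None:
            continue
        cell_map[next_id] = shapely.affinity.scale(c, 1.0, anisotropy, origin=(0, 0))
        next_id += 1
    if len(cell_map) < 3:
        raise ValueError("degenerate domain: fewer than 3 interior cells")
    midline = ((0.0, 0.0), (0.0, LENGTH_TO_WIDTH * width_um))
    return LeafGeometry(outline=outline, cells=cell_map, midline=midline, pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# ground truth


def _half_width_at(outline: Polygon, y: float) -> float:
    minx, _, maxx, _ = outline.bounds
    cut = LineString([(minx - 1.0, y), (maxx + 1.0, y)]).intersection(outline)
    if cut.is_empty:
        return 0.0
    xmin, _, xmax, _ = cut.bounds
    return max(xmax, -xmin, 1e-9)


def true_field_angle(spec: FieldSpec, lateral_norm: float, proximal_norm: float) -> float:
    """Noise-free field angle (degrees) at a normalized leaf position.

    ``lateral_norm`` is the signed offset from the midline as a fraction of
    the local half-width (positive to the right of a tip-up leaf);
    ``proximal_norm`` is the base→tip position in [0, 1].  The divergent
    field deflects vectors toward the nearer margin (rightward deflection
    is a clockwise, hence negative, angle), strongest at the proximal
    lamina and vanishing at the tip.
    """
    if spec.field_type == "proximodistal":
        return 0.0
    raw = -spec.divergence_gain * lateral_norm * (1.0 - proximal_norm)
    return float(np.clip(raw, -90.0, 90.0))


def _crescent_point(cell: Polygon, angle_deg: float):
    """Boundary point anti-parallel to the polarity vector, plus arc position.

    The polarity vector points crescent → centroid at ``angle_deg`` to the
    midline (+y), so the crescent sits where the ray from the centroid in
    the opposite direction crosses the cell boundary.
    """
    c = cell.centroid
    phi = np.radians(90.0 + angle_deg)  # vector direction from +x axis
    reach = 4.0 * max(cell.bounds[2] - cell.bounds[0], cell.bounds[3] - cell.bounds[1])
    ray = LineString(
        [(c.x, c.y), (c.x - reach * np.cos(phi), c.y - reach * np.sin(phi))]
    )
    ring = LineString(cell.exterior.coords)
    hit = ray.intersection(ring)
    if hit.is_empty:
        # centroid outside a highly non-convex clip; fall back to nearest vertex
        hit = Point(cell.exterior.coords[0])
    if hit.geom_type != "Point":
        pts = [g for g in getattr(hit, "geoms", [hit])]
        coords = []
        for g in pts:
            coords.extend(list(g.coords))
        d2 = [(px - c.x) ** 2 + (py - c.y) ** 2 for px, py in coords]
        hit = Point(coords[int(np.argmin(d2))])
    return (hit.x, hit.y), float(ring.project(hit))


def generate_truth(geometry: LeafGeometry, spec: FieldSpec) -> GroundTruthField:
    """Draw a per-cell true polarity angle and crescent placement."""
    rng = np.random.default_rng(spec.seed)
    base, tip = np.asarray(geometry.midline[0]), np.asarray(geometry.midline[1])
    length = float(np.linalg.norm(tip - base))
    rows = []
    ids = sorted(geometry.cells)
    noise = (
        sample_wrapped_normal(0.0, spec.noise_sigma_deg, len(ids), rng)
        if spec.noise_sigma_deg > 0
        else np.zeros(len(ids))
    )
    for cell_id, eps in zip(ids, noise):
        cell = geometry.cells[cell_id]
        c = cell.centroid
        proximal_norm = float(np.clip((c.y - base[1]) / length, 0.0, 1.0))
        half_w = _half_width_at(geometry.outline, c.y)
        lateral_norm = float(np.clip(c.x / half_w, -1.0, 1.0))
        angle = wrap_angle(true_field_angle(spec, lateral_norm, proximal_norm) + eps)
        (mx, my), arc_pos = _crescent_point(cell, angle)
        rows.append(
            {
                "cell_id": cell_id,
                "centroid_x": c.x,
                "centroid_y": c.y,
                "true_angle_deg": float(angle),
                "crescent_mid_x": mx,
                "crescent_mid_y": my,
                "crescent_arc_pos": arc_pos,
            }
        )
    return GroundTruthField(records=pd.DataFrame(rows), spec=spec)


# ---------------------------------------------------------------------------
# rendering


def _height_map(shape, z_slices: int, amplitude_px: float) -> np.ndarray:
    rows, cols = shape
    z0 = (z_slices - 1) / 2.0
    rr = np.arange(rows)[:, None] / max(rows, 1)
    cc = np.arange(cols)[None, :] / max(cols, 1)
    h = z0 + amplitude_px * np.sin(2 * np.pi * cc) * np.cos(2 * np.pi * rr)
    return np.clip(np.round(h), 0, z_slices - 1).astype(int)


def _rasterize_labels(geometry: LeafGeometry, tf: RasterTransform) -> np.ndarray:
    labels = np.zeros(tf.shape, dtype=np.int32)
    for cell_id in sorted(geometry.cells):
        coords = np.asarray(geometry.cells[cell_id].exterior.coords)
        rc = tf.to_pixel(coords)
        rr, cc = draw_polygon(rc[:, 0], rc[:, 1], shape=tf.shape)
        labels[rr, cc] = cell_id
    return labels


def _arc_mask(
    cell: Polygon, arc_pos: float, arc_len: float, tf: RasterTransform, inset_um: float = 0.0
) -> np.ndarray:
    """Rasterize the boundary arc of length ``arc_len`` centred at ``arc_pos``.

    ``inset_um`` moves arc points off the wall toward the cell centroid —
    the crescent is cytoplasmic, hugging the inner face of the membrane,
    which is what lets signal spanning a shared wall region be attributed
    to one cell.
    """
    ring = LineString(cell.exterior.coords)
    total = ring.length
    start, end = arc_pos - arc_len / 2.0, arc_pos + arc_len / 2.0
    pieces = []
    if start < 0:
        pieces.append(substring(ring, start + total, total))
        start = 0.0
    if end > total:
        pieces.append(substring(ring, 0.0, end - total))
        end = total
    pieces.append(substring(ring, start, end))
    mask = np.zeros(tf.shape, dtype=bool)
    step = 0.4 * tf.pixel_size
    for piece in pieces:
        if piece.is_empty or piece.length == 0:
            continue
        n = max(2, int(np.ceil(piece.length / step)))
        pts = np.asarray(
            [piece.interpolate(d).coords[0] for d in np.linspace(0, piece.length, n)]
        )
        if inset_um > 0:
            c = np.asarray(cell.centroid.coords[0])
            d = c - pts
            norms = np.linalg.norm(d, axis=1, keepdims=True)
            pts = pts + inset_um * d / np.maximum(norms, 1e-9)
        rc = np.round(tf.to_pixel(pts)).astype(int)
        keep = (
            (rc[:, 0] >= 0) & (rc[:, 0] < tf.shape[0]) & (rc[:, 1] >= 0) & (rc[:, 1] < tf.shape[1])
        )
        mask[rc[keep, 0], rc[keep, 1]] = True
    return mask


def render_stack(
    geometry: LeafGeometry,
    truth: GroundTruthField,
    params: RenderParams = None,
):
    """Rasterize geometry + truth into a two-channel z-stack.

    Returns ``(stack, transform)`` where ``transform`` maps the leaf μm
    frame onto raster pixels.  Channel 1 is the membrane network, channel
    2 the crescent signal; both ride on a smooth height map across
    ``z_slices`` slices, with noise applied last.
    """
    if params is None:
        params = RenderParams()
    ps = geometry.pixel_size
    margin_px = 5
    minx, miny, maxx, maxy = geometry.outline.bounds
    cols = int(np.ceil((maxx - minx) / ps)) + 2 * margin_px
    rows = int(np.ceil((maxy - miny) / ps)) + 2 * margin_px
    tf = RasterTransform(
        x0=minx - margin_px * ps, y0=maxy + margin_px * ps, pixel_size=ps, shape=(rows, cols)
    )

    areas = np.array([geometry.cells[i].area for i in sorted(geometry.cells)])
    min_diam_px = 2.0 * np.sqrt(areas.min() / np.pi) / ps
    if min_diam_px < 3.0 * params.membrane_width_px:
        raise ValueError(
            "raster too small to resolve membrane: smallest cell diameter "
            f"{min_diam_px:.1f}px < 3× membrane width"
        )

    labels = _rasterize_labels(geometry, tf)
    membrane = find_boundaries(labels, mode="thick")
    dil_r = max(0, int(round(params.membrane_width_px / 2)) - 1)
    if dil_r > 0:
        membrane = dilation(membrane, disk(dil_r))

    crescents = np.zeros(tf.shape, dtype=bool)
    inset_um = params.crescent_inset_px * ps
    for rec in truth.records.itertuples():
        cell = geometry.cells[rec.cell_id]
        arc_len = params.crescent_arc_fraction * cell.exterior.length
        crescents |= _arc_mask(cell, rec.crescent_arc_pos, arc_len, tf, inset_um=inset_um)
    if dil_r > 0:
        crescents = dilation(crescents, disk(dil_r))

    ch1_2d = np.where(membrane, params.membrane_intensity, 0.0).astype(np.float32)
    ch2_2d = np.where(crescents, params.crescent_intensity, 0.0).astype(np.float32)

    z = params.z_slices
    height = _height_map(tf.shape, z, params.surface_amplitude_px if z > 1 else 0.0)
    outline_vol = np.full((z, rows, cols), params.background_intensity, dtype=np.float32)
    marker_vol = np.zeros((z, rows, cols), dtype=np.float32)
    zz = np.arange(z)[:, None, None]
    on_surface = zz == height[None]
    outline_vol += np.where(on_surface, ch1_2d[None], 0.0)
    marker_vol += np.where(on_surface, ch2_2d[None], 0.0)

    rng = np.random.default_rng(params.seed)
    if params.noise_model == "gaussian" and params.noise_magnitude > 0:
        outline_vol += rng.normal(0, params.noise_magnitude, outline_vol.shape)
        marker_vol += rng.normal(0, params.noise_magnitude, marker_vol.shape)
    elif params.noise_model == "poisson":
        scale = max(params.noise_magnitude, 1e-6)
        outline_vol = rng.poisson(np.maximum(outline_vol, 0) / scale) * scale
        marker_vol = rng.poisson(np.maximum(marker_vol, 0) / scale) * scale
    outline_vol = np.clip(outline_vol, 0, None)
    marker_vol = np.clip(marker_vol, 0, None)

    stack = ImageStack(outline=outline_vol, marker=marker_vol, pixel_size=ps, z_step=1.0)
    return stack, tf


def write_config(path, **kv) -> None:
    """Plain-text key=value generator config."""
    lines = [f"{k} = {v}" for k, v in kv.items()]
    Path(path).write_text("\n".join(lines) + "\n")
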