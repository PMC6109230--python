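"""Tissue-scale vector-field construction and visualization.

Builds the midline reference frame, downsamples per-cell polarity vectors
onto a triangular (hexagonal-lattice) grid, averages 180°-periodic cell
orientations by PCA on superimposed unit segments, subdivides the leaf
into a coarse region grid, and maps angles to a cyclic color wheel.

All averaging is the unweighted circular mean of unit vectors: the
statistics of this assay are orientation-only, so vector magnitudes carry
no weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib import pyplot as plt
from scipy.spatial import cKDTree

from .circular import circular_mean, resultant_length, signed_angle, wrap_angle, wrap_axial

log = logging.getLogger(__name__)

RESULTANT_GUARD = 1e-6  # drop vertices whose mean vector cancels to ~zero


@dataclass
class MidlineFrame:
    """The user-specified base→tip leaf midline as a reference frame."""

    base: tuple  # (x, y) μm
    tip: tuple

    def __post_init__(self) -> None:
        if tuple(self.base) == tuple(self.tip):
            raise ValueError("midline base and tip coincide")

    @property
    def vector(self) -> np.ndarray:
        return np.asarray(self.tip, float) - np.asarray(self.base, float)

    @property
    def rotation_to_vertical(self) -> float:
        """Angle (deg, CCW) that maps the midline vector onto tip-up vertical."""
        m = self.vector
        return float(wrap_angle(90.0 - np.degrees(np.arctan2(m[1], m[0]))))

    def angle_to_midline(self, vector_xy) -> float:
        """Signed angle α (deg) from the midline to ``vector_xy``, (−180°, 180°]."""
        return signed_angle(self.vector, vector_xy)

    def to_frame(self, points_xy) -> np.ndarray:
        """Rotate points about the base so the midline is vertical (tip-up)."""
        pts = np.atleast_2d(np.asarray(points_xy, float)) - np.asarray(self.base, float)
        rho = np.radians(self.rotation_to_vertical)
        rot = np.array([[np.cos(rho), -np.sin(rho)], [np.sin(rho), np.cos(rho)]])
        out = pts @ rot.T
        return out[0] if np.asarray(points_xy).ndim == 1 else out


def build_frame(base, tip) -> MidlineFrame:
    return MidlineFrame(base=tuple(base), tip=tuple(tip))


def angle_to_midline(vector_xy, frame: MidlineFrame) -> float:
    return frame.angle_to_midline(vector_xy)


@dataclass
class DownsampleParams:
    grid_spacing: float = 25.0  # μm between triangular-grid vertices
    maxdist: float = 20.0  # μm gathering radius
    neighbor_threshold: int = 3  # minimum contributing vectors per vertex

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0 or self.maxdist <= 0:
            raise ValueError("grid_spacing and maxdist must be positive")
        if self.neighbor_threshold < 1:
            raise ValueError("neighbor_threshold must be ≥ 1")


@dataclass
class DownsampledField:
    vertices: np.ndarray  # (n, 2) μm
    mean_angle: np.ndarray  # degrees per retained vertex
    support: np.ndarray  # contributing-vector count per vertex


@dataclass
class AxialField:
    vertices: np.ndarray
    axis_angle: np.ndarray  # (−90°, 90°] orientation per vertex
    anisotropy: np.ndarray  # λ1/(λ1+λ2) ∈ [0.5, 1]
    support: np.ndarray


def triangular_grid(bounds, spacing: float) -> np.ndarray:
    """Hexagonal-lattice vertices covering ``bounds`` = (minx, miny, maxx, maxy)."""
    minx, miny, maxx, maxy = bounds
    dy = spacing * np.sqrt(3.0) / 2.0
    ys = np.arange(miny, maxy + dy, dy)
    verts = []
    for i, y in enumerate(ys):
        off = 0.5 * spacing if i % 2 else 0.0
        xs = np.arange(minx + off, maxx + spacing, spacing)
        verts.extend((x, y) for x in xs)
    return np.asarray(verts, dtype=float)


def downsample(
    positions_xy, angles_deg, params: DownsampleParams = None, bounds=None
) -> DownsampledField:
    """Average vectors onto a triangular grid.

    For each grid vertex, the unweighted circular mean of the angles of
    all vectors within ``maxdist`` is taken; a vertex is retained only if
    it gathers at least ``neighbor_threshold`` vectors and the vectors do
    not cancel (mean resultant length above a tiny guard).  Vectors that
    contribute to no retained vertex are counted and logged, never lost
    silently.
    """
    if params is None:
        params = DownsampleParams()
    pos = np.atleast_2d(np.asarray(positions_xy, float))
    ang = np.asarray(angles_deg, float)
    if pos.shape[0] == 0:
        raise ValueError("need at least one vector")
    if bounds is None:
        pad = params.maxdist
        bounds = (
            pos[:, 0].min() - pad,
            pos[:, 1].min() - pad,
            pos[:, 0].max() + pad,
            pos[:, 1].max() + pad,
        )
    grid = triangular_grid(bounds, params.grid_spacing)
    tree = cKDTree(pos)
    hits = tree.query_ball_point(grid, params.maxdist)
    verts, means, support = [], [], []
    used = np.zeros(pos.shape[0], dtype=bool)
    for vertex, idx in zip(grid, hits):
        if len(idx) < params.neighbor_threshold:
            continue
        if resultant_length(ang[idx]) <= RESULTANT_GUARD:
            continue
        verts.append(vertex)
        means.append(circular_mean(ang[idx]))
        support.append(len(idx))
        used[idx] = True
    n_dropped = int((~used).sum())
    if n_dropped:
        log.info("downsample: %d vectors contributed to no retained vertex", n_dropped)
    return DownsampledField(
        vertices=np.asarray(verts, float).reshape(-1, 2),
        mean_angle=np.asarray(means, float),
        support=np.asarray(support, int),
    )


def axial_average(
    positions_xy,
    orientations_deg,
    radius: float,
    grid_vertices=None,
    grid_spacing: float = 25.0,
    neighbor_threshold: int = 3,
) -> AxialField:
    """Local PCA averaging of 180°-periodic orientations.

    Each orientation within ``radius`` of a vertex contributes a unit
    segment — the endpoint pair ±(cos θ, sin θ) superimposed at the
    origin — and the first principal axis of that point cloud is the
    local mean axis.  Equivalent to the doubled-angle circular mean.
    Anisotropy is λ1/(λ1+λ2) of the PCA eigenvalues: 0.5 for an isotropic
    cloud, 1 for perfectly aligned orientations.
    """
    pos = np.atleast_2d(np.asarray(positions_xy, float))
    ori = np.radians(np.asarray(orientations_deg, float))
    if grid_vertices is None:
        pad = radius
        bounds = (
            pos[:, 0].min() - pad,
            pos[:, 1].min() - pad,
            pos[:, 0].max() + pad,
            pos[:, 1].max() + pad,
        )
        grid_vertices = triangular_grid(bounds, grid_spacing)
    tree = cKDTree(pos)
    hits = tree.query_ball_point(grid_vertices, radius)
    verts, axes, aniso, support = [], [], [], []
    for vertex, idx in zip(grid_vertices, hits):
        if len(idx) < neighbor_threshold:
            continue
        u = np.column_stack([np.cos(ori[idx]), np.sin(ori[idx])])
        cloud = np.vstack([u, -u])  # superimposed ± unit segments
        cov = cloud.T @ cloud
        evals, evecs = np.linalg.eigh(cov)
        lead = evecs[:, np.argmax(evals)]
        axes.append(float(wrap_axial(np.degrees(np.arctan2(lead[1], lead[0])))))
        lam2, lam1 = np.sort(evals)
        aniso.append(float(lam1 / (lam1 + lam2)) if (lam1 + lam2) > 0 else 0.5)
        verts.append(vertex)
        support.append(len(idx))
    return AxialField(
        vertices=np.asarray(verts, float).reshape(-1, 2),
        axis_angle=np.asarray(axes, float),
        anisotropy=np.asarray(aniso, float),
        support=np.asarray(support, int),
    )


def region_grid_average(
    positions_xy, angles_deg, bounds=None, rows: int = 3, cols: int = 3
) -> pd.DataFrame:
    """Circular mean of α per cell of a rows×cols subdivision of the leaf.

    ``bounds`` defaults to the bounding box of the vector origins.  Empty
    regions are absent from the output.  Region (0, 0) is the proximal
    (low-y) left corner in the tip-up frame.
    """
    pos = np.atleast_2d(np.asarray(positions_xy, float))
    ang = np.asarray(angles_deg, float)
    if pos.shape[0] == 0:
        raise ValueError("need at least one vector")
    if bounds is None:
        bounds = (pos[:, 0].min(), pos[:, 1].min(), pos[:, 0].max(), pos[:, 1].max())
    minx, miny, maxx, maxy = bounds
    eps = 1e-9
    ci = np.clip(((pos[:, 0] - minx) / max(maxx - minx, eps) * cols).astype(int), 0, cols - 1)
    ri = np.clip(((pos[:, 1] - miny) / max(maxy - miny, eps) * rows).astype(int), 0, rows - 1)
    out = []
    for r in range(rows):
        for c in range(cols):
            sel = (ri == r) & (ci == c)
            if not sel.any():
                continue
            out.append(
                {
                    "row": r,
                    "col": c,
                    "mean_angle_deg": circular_mean(ang[sel]),
                    "n": int(sel.sum()),
                }
            )
    return pd.DataFrame(out)


def angle_colormap(alpha_deg, axial: bool = False):
    """Cyclic hue for an angle: full wheel for vectors, half wheel for axes.

    α = 0° maps to the wheel's reference hue (red); axial orientations θ
    and θ + 180° share a color.
    """
    period = 180.0 if axial else 360.0
    hue = (np.asarray(alpha_deg, float) % period) / period
    return plt.get_cmap("hsv")(hue)


def plot_vector_field(positions_xy, angles_deg, path=None, ax=None, scale_um: float = 10.0):
    """Quiver of unit vectors colored by α on the full color wheel."""
    pos = np.atleast_2d(np.asarray(positions_xy, float))
    ang = np.radians(np.asarray(angles_deg, float) + 90.0)  # α=0 points tip-up
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 7))
    else:
        fig = ax.figure
    colors = angle_colormap(angles_deg)
    ax.quiver(
        pos[:, 0], pos[:, 1], scale_um * np.cos(ang), scale_um * np.sin(ang),
        color=colors, angles="xy", scale_units="xy", scale=1, width=0.004,
    )
    ax.set_aspect("equal")
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return ax


def plot_axial_field(field: AxialField, path=None, ax=None, scale_um: float = 10.0):
    """Axial (headless) segments colored on the half wheel."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 7))
    else:
        fig = ax.figure
    ang = np.radians(field.axis_angle + 90.0)
    dx, dy = scale_um * np.cos(ang) / 2, scale_um * np.sin(ang) / 2
    colors = angle_colormap(field.axis_angle, axial=True)
    for (x, y), ddx, ddy, col in zip(field.vertices, dx, dy, colors):
        ax.plot([x - ddx, x + ddx], [y - ddy, y + ddy], color=col, lw=1.5)
    ax.set_aspect("equal")
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return ax
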