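"""Surface projection and epidermal cell segmentation.

Projects the leaf surface out of a 3D two-channel stack (height map from
the outline channel, per-channel max projection in a band around the
surface) and segments individual cells by marker-controlled watershed on
the projected outline channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import find_contours, label as cc_label, regionprops
from skimage.morphology import closing, dilation, disk, h_minima
from skimage.segmentation import watershed

from .stack import ImageStack

log = logging.getLogger(__name__)


class NoSurfaceError(ValueError):
    """Raised when the outline channel carries no detectable surface."""


@dataclass
class SurfaceProjection:
    """Per-pixel surface height and band-projected channels."""

    height_map: np.ndarray  # int z index per (y, x)
    outline: np.ndarray  # projected outline channel (y, x)
    marker: np.ndarray  # projected marker channel (y, x)
    band_halfwidth: int
    pixel_size: float


@dataclass
class CellSegment:
    """A single segmented cell in full-image pixel coordinates."""

    id: int
    bbox: tuple  # (row0, col0, row1, col1)
    mask: np.ndarray  # bool, local to bbox
    centroid_rc: tuple  # (row, col), full-image frame
    boundary_rc: np.ndarray  # closed (N, 2) contour, full-image frame
    touches_border: bool
    area_px: int


@dataclass
class Segmentation:
    label_image: np.ndarray
    cells: list
    leaf_mask: np.ndarray
    params: dict = field(default_factory=dict)

    def cell(self, cell_id: int) -> CellSegment:
        for c in self.cells:
            if c.id == cell_id:
                return c
        raise KeyError(cell_id)


@dataclass
class SegmentationParams:
    """Leaf-specific tuning knobs for :func:`segment_cells`.

    ``seed_h_rel`` is the h-minima depth as a fraction of the blurred
    image's dynamic range; ``seed_h`` (absolute intensity) overrides it
    when given.
    """

    blur_sigma: float = 2.0
    seed_h_rel: float = 0.10
    seed_h: float = None
    min_cell_area_px: int = 50


def project_surface(
    stack: ImageStack, band_halfwidth: int = 2, smoothing: float = 1.0
) -> SurfaceProjection:
    """Detect the leaf surface and project both channels onto it.

    Height map: per-(y, x) argmax over z of the (z-wise smoothed) outline
    channel, median-filtered laterally; each channel is then max-projected
    over z within ±``band_halfwidth`` slices of the surface, so signal off
    the leaf surface is excluded.  Single-slice stacks pass through.
    """
    if not np.any(stack.outline > 0):
        raise NoSurfaceError("no surface detected: outline channel is all zero")
    z = stack.n_slices
    if z == 1:
        return SurfaceProjection(
            height_map=np.zeros(stack.shape_yx, dtype=int),
            outline=stack.outline[0].copy(),
            marker=stack.marker[0].copy(),
            band_halfwidth=band_halfwidth,
            pixel_size=stack.pixel_size,
        )
    smoothed = gaussian(stack.outline, sigma=(0, smoothing, smoothing), preserve_range=True)
    height = np.argmax(smoothed, axis=0)
    height = ndi.median_filter(height, size=5)
    zz = np.arange(z)[:, None, None]
    band = np.abs(zz - height[None]) <= band_halfwidth
    proj_outline = np.where(band, stack.outline, -np.inf).max(axis=0)
    proj_marker = np.where(band, stack.marker, -np.inf).max(axis=0)
    return SurfaceProjection(
        height_map=height,
        outline=np.maximum(proj_outline, 0).astype(np.float32),
        marker=np.maximum(proj_marker, 0).astype(np.float32),
        band_halfwidth=band_halfwidth,
        pixel_size=stack.pixel_size,
    )


def _leaf_mask(blurred: np.ndarray) -> np.ndarray:
    """Largest connected component of above-background signal, holes filled."""
    if blurred.max() <= blurred.min():
        return np.zeros(blurred.shape, dtype=bool)
    thr = threshold_otsu(blurred)
    fg = closing(blurred > thr, disk(3))
    fg = ndi.binary_fill_holes(fg)
    lab = cc_label(fg)
    if lab.max() == 0:
        return np.zeros(blurred.shape, dtype=bool)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == sizes.argmax()


def _merge_small_regions(labels: np.ndarray, min_area: int) -> np.ndarray:
    """Merge regions below ``min_area`` into the neighbor sharing the longest boundary."""
    labels = labels.copy()
    for _ in range(8):  # a few passes handle chained merges
        sizes = np.bincount(labels.ravel())
        small = [l for l in range(1, sizes.size) if 0 < sizes[l] < min_area]
        if not small:
            break
        for l in small:
            mask = labels == l
            if not mask.any():
                continue
            ring = dilation(mask, disk(1)) & ~mask
            neighbors = labels[ring]
            neighbors = neighbors[neighbors > 0]
            if neighbors.size == 0:
                labels[mask] = 0
                continue
            counts = np.bincount(neighbors)
            labels[mask] = counts.argmax()
    return labels


def _build_cells(labels: np.ndarray) -> list:
    cells = []
    nrows, ncols = labels.shape
    for prop in regionprops(labels):
        r0, c0, r1, c1 = prop.bbox
        mask = prop.image
        padded = np.pad(mask, 1)
        contours = find_contours(padded.astype(float), 0.5)
        if not contours:
            continue
        contour = max(contours, key=len) + np.array([r0 - 1, c0 - 1])
        touches = r0 == 0 or c0 == 0 or r1 == nrows or c1 == ncols
        cells.append(
            CellSegment(
                id=int(prop.label),
                bbox=(r0, c0, r1, c1),
                mask=mask,
                centroid_rc=(float(prop.centroid[0]), float(prop.centroid[1])),
                boundary_rc=contour,
                touches_border=bool(touches),
                area_px=int(prop.area),
            )
        )
    return cells


def segment_cells(
    projection: SurfaceProjection, params: SegmentationParams = None
) -> Segmentation:
    """Marker-controlled watershed segmentation of the projected outline.

    Seeds are h-minima (depth ``seed_h``) of the blurred outline channel
    inside the leaf mask; watershed floods the blurred image from them.
    Regions smaller than ``min_cell_area_px`` are merged into the neighbor
    with the longest shared boundary, and cells touching the image border
    are flagged (and excluded from downstream statistics).
    """
    if params is None:
        params = SegmentationParams()
    img = np.asarray(projection.outline, dtype=float)
    blurred = gaussian(img, sigma=params.blur_sigma, preserve_range=True)
    leaf = _leaf_mask(blurred)
    if not leaf.any():
        raise NoSurfaceError("no surface detected: empty leaf mask")

    h = params.seed_h
    if h is None:
        h = params.seed_h_rel * (blurred.max() - blurred.min())
    minima = h_minima(blurred, h) & leaf
    markers = cc_label(minima)
    if markers.max() == 0:
        raise ValueError("zero watershed seeds found; lower seed_h / seed_h_rel")
    labels = watershed(blurred, markers, mask=leaf)
    labels = _merge_small_regions(labels, params.min_cell_area_px)
    cells = _build_cells(labels)
    log.info("segmented %d cells (%d seeds)", len(cells), markers.max())
    return Segmentation(
        label_image=labels,
        cells=cells,
        leaf_mask=leaf,
        params={
            "blur_sigma": params.blur_sigma,
            "seed_h": float(h),
            "min_cell_area_px": params.min_cell_area_px,
        },
    )


def extract_marker_on_cells(
    projection: SurfaceProjection, segmentation: Segmentation, dilation_px: int = 2
) -> dict:
    """Per-cell marker images on dilated masks (full-image frame).

    Each cell's mask is dilated by the membrane width so that
    boundary-localized signal is captured; signal on a shared wall is
    credited to every adjacent cell.
    """
    out = {}
    marker = projection.marker
    nrows, ncols = marker.shape
    se = disk(dilation_px)
    for cell in segmentation.cells:
        r0, c0, r1, c1 = cell.bbox
        p = dilation_px + 1
        R0, C0 = max(0, r0 - p), max(0, c0 - p)
        R1, C1 = min(nrows, r1 + p), min(ncols, c1 + p)
        big = np.zeros((R1 - R0, C1 - C0), dtype=bool)
        big[r0 - R0 : r1 - R0, c0 - C0 : c1 - C0] = cell.mask
        dil = dilation(big, se)
        img = np.zeros_like(big, dtype=float)
        img[dil] = marker[R0:R1, C0:C1][dil]
        out[cell.id] = {"image": img, "origin_rc": (R0, C0)}
    return out


def write_segmentation(segmentation: Segmentation, out_dir, pixel_size: float) -> None:
    """Label image as 16-bit TIFF plus a per-cell CSV table."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "labels.tif", segmentation.label_image.astype(np.uint16))
    rows = [
        {
            "cell_id": c.id,
            "centroid_x": c.centroid_rc[1] * pixel_size,
            "centroid_y": c.centroid_rc[0] * pixel_size,
            "area_px": c.area_px,
            "touches_border": c.touches_border,
        }
        for c in segmentation.cells
    ]
    pd.DataFrame(rows).to_csv(out / "cells.csv", index=False)
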