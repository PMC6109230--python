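"""Blinded per-cell crescent tagging and polarity-vector assignment.

Each segmented cell is presented in isolation, randomly rotated by one of
the four right angles so no positional cue can bias the call.  An
automated detector samples marker intensity along the cell boundary and
places the crescent midpoint (the original protocol's manual click can be
imported instead).  Calls are mapped back to the whole-leaf frame and a
polarity vector is drawn from crescent midpoint to cell centroid; its
angle α to the leaf midline is the quantity all downstream statistics
use.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter
from skimage.measure import find_contours

from .coords import pixel_to_leaf
from .fieldmap import MidlineFrame
from .surfseg import CellSegment, Segmentation, SurfaceProjection

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class RotatedCellView:
    """A cell's cropped image pair under a random right-angle rotation."""

    cell_id: int
    outline: np.ndarray  # rotated crop
    marker: np.ndarray
    mask: np.ndarray
    rotation_deg: int  # 0 / 90 / 180 / 270 (counterclockwise)
    origin_rc: tuple  # crop origin in the full image (before rotation)
    crop_shape: tuple  # unrotated crop shape (rows, cols)

    def crop_to_leaf(self, points_rc) -> np.ndarray:
        """Map rotated-crop (row, col) points to full-image pixel coords."""
        pts = np.atleast_2d(np.asarray(points_rc, dtype=float))
        k = (self.rotation_deg // 90) % 4
        shape = self.crop_shape
        # forward single CCW rot90 on points: (r, c) -> (W-1-c, r); invert k times
        shapes = [shape]
        for _ in range(k):
            shapes.append((shapes[-1][1], shapes[-1][0]))
        for step in range(k):
            h, w = shapes[k - 1 - step]  # shape before that rotation step
            r, c = pts[:, 0].copy(), pts[:, 1].copy()
            pts = np.column_stack([c, (w - 1) - r])
        out = pts + np.asarray(self.origin_rc, dtype=float)
        return out[0] if np.asarray(points_rc).ndim == 1 else out

    def leaf_to_crop(self, points_rc) -> np.ndarray:
        """Inverse of :meth:`crop_to_leaf`."""
        pts = np.atleast_2d(np.asarray(points_rc, dtype=float)) - np.asarray(
            self.origin_rc, dtype=float
        )
        k = (self.rotation_deg // 90) % 4
        shape = self.crop_shape
        for _ in range(k):
            h, w = shape
            r, c = pts[:, 0].copy(), pts[:, 1].copy()
            pts = np.column_stack([(w - 1) - c, r])
            shape = (w, h)
        return pts[0] if np.asarray(points_rc).ndim == 1 else pts


@dataclass
class CrescentCall:
    cell_id: int
    status: str  # "tagged" | "skipped"
    midpoint_crop: tuple = None  # (row, col) in the rotated crop
    midpoint_rc: tuple = None  # (row, col) in the full image (after restore)
    arc_crop: np.ndarray = None  # (N, 2) boundary run in the rotated crop
    arc_rc: np.ndarray = None
    basis: str = "automated"  # automated | three_way_junction | concavity
    skip_reason: str = ""
    arc_len_px: float = 0.0
    perimeter_px: float = 0.0
    rotation_deg: int = 0


@dataclass
class BaslVector:
    """Polarity vector from crescent midpoint to cell centroid (μm)."""

    cell_id: int
    origin_xy: tuple  # crescent midpoint, leaf frame μm
    tip_xy: tuple  # cell centroid, leaf frame μm
    alpha_deg: float  # signed angle to the midline vector, (−180°, 180°]
    magnitude_um: float


@dataclass
class TagParams:
    snr_min: float = 5.0
    min_arc_px: float = 4.0
    max_arc_fraction: float = 0.6
    ambiguity_ratio: float = 0.8  # second run ≥ this × longest → ambiguous
    merge_gap_px: int = 2
    sample_radius_px: int = 1
    sample_inset_px: float = 1.5  # read intensity this far inside the boundary
    crop_pad_px: int = 3


# ---------------------------------------------------------------------------
# operations


def randomize_orientation(
    cell: CellSegment, projection: SurfaceProjection, seed: int, pad: int = 3
) -> RotatedCellView:
    """Crop a cell and rotate it by a seed-deterministic right angle.

    The rotation is drawn uniformly from {0°, 90°, 180°, 270°} using a
    generator keyed on (seed, cell id), so it is reproducible regardless
    of iteration order.
    """
    rng = np.random.default_rng([int(seed), int(cell.id)])
    k = int(rng.integers(0, 4))
    r0, c0, r1, c1 = cell.bbox
    nrows, ncols = projection.outline.shape
    R0, C0 = max(0, r0 - pad), max(0, c0 - pad)
    R1, C1 = min(nrows, r1 + pad), min(ncols, c1 + pad)
    mask = np.zeros((R1 - R0, C1 - C0), dtype=bool)
    mask[r0 - R0 : r1 - R0, c0 - C0 : c1 - C0] = cell.mask
    outline = projection.outline[R0:R1, C0:C1]
    marker = projection.marker[R0:R1, C0:C1]
    return RotatedCellView(
        cell_id=cell.id,
        outline=np.rot90(outline, k).copy(),
        marker=np.rot90(marker, k).copy(),
        mask=np.rot90(mask, k).copy(),
        rotation_deg=90 * k,
        origin_rc=(R0, C0),
        crop_shape=(R1 - R0, C1 - C0),
    )


def _boundary_samples(view: RotatedCellView, sample_radius_px: int, sample_inset_px: float = 1.5):
    """Resample the cell contour at ~1 px spacing and read marker intensity.

    Intensity is read slightly *inside* the boundary (the crescent hugs
    the cytoplasmic face of the membrane) as the local maximum of the
    marker in a small window — so signal is attributed to the cell that
    owns it and not to the neighbor across a shared wall.
    """
    padded = np.pad(view.mask, 1).astype(float)
    contours = find_contours(padded, 0.5)
    if not contours:
        raise ValueError(f"cell {view.cell_id}: no boundary contour")
    contour = max(contours, key=len) - 1.0  # back to crop coords
    seg = np.diff(contour, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]
    n = max(8, int(np.floor(total)))
    pos = np.linspace(0.0, total, n, endpoint=False)
    rr = np.interp(pos, cum, contour[:, 0])
    cc = np.interp(pos, cum, contour[:, 1])
    if sample_inset_px > 0:
        mr, mc = np.nonzero(view.mask)
        centre = np.array([mr.mean(), mc.mean()]) if mr.size else np.zeros(2)
        dr, dc = centre[0] - rr, centre[1] - cc
        norm = np.maximum(np.hypot(dr, dc), 1e-9)
        rr = rr + sample_inset_px * dr / norm
        cc = cc + sample_inset_px * dc / norm
    size = 2 * sample_radius_px + 1
    filt = maximum_filter(view.marker, size=size, mode="nearest")
    ri = np.clip(np.round(rr).astype(int), 0, view.marker.shape[0] - 1)
    ci = np.clip(np.round(cc).astype(int), 0, view.marker.shape[1] - 1)
    samples = filt[ri, ci]
    contour_pts = np.interp(pos, cum, contour[:, 0]), np.interp(pos, cum, contour[:, 1])
    return np.column_stack(contour_pts), samples, total


def _circular_runs(mask: np.ndarray, merge_gap: int) -> list:
    """Index runs of True in a circular boolean array, gaps ≤ merge_gap merged."""
    n = mask.size
    if mask.all():
        return [np.arange(n)]
    if not mask.any():
        return []
    # rotate so position 0 is False, runs never wrap the array seam
    start = int(np.flatnonzero(~mask)[0])
    rolled = np.roll(mask, -start)
    edges = np.flatnonzero(np.diff(rolled.astype(int)))
    starts = edges[::2] + 1
    ends = edges[1::2] + 1 if edges.size % 2 == 0 else np.append(edges[1::2] + 1, n)
    runs = [np.arange(s, e) for s, e in zip(starts, ends)]
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][-1] - 1 <= merge_gap:
            merged[-1] = np.concatenate([merged[-1], np.arange(merged[-1][-1] + 1, run[0]), run])
        else:
            merged.append(run)
    # merge across the (rotated) seam
    if len(merged) > 1 and (n - merged[-1][-1] - 1) + merged[0][0] <= merge_gap:
        bridge = np.concatenate(
            [merged[-1], np.arange(merged[-1][-1] + 1, n), np.arange(0, merged[0][0]), merged[0]]
        )
        merged = [bridge % n] + merged[1:-1]
    return [(run + start) % n for run in merged]


def detect_crescent(view: RotatedCellView, params: TagParams = None) -> CrescentCall:
    """Automated crescent call on a (rotated) cell view.

    Boundary positions whose marker intensity exceeds background median +
    ``snr_min`` × scaled MAD form candidate runs; the longest run is the
    crescent and its intensity-weighted centre the midpoint.  Failure
    modes are skips with a reason, never errors: no/short signal,
    unpolarized (run longer than ``max_arc_fraction`` of the perimeter),
    or ambiguous (two runs of comparable length).
    """
    if params is None:
        params = TagParams()
    contour, samples, perimeter = _boundary_samples(
        view, params.sample_radius_px, params.sample_inset_px
    )
    k = view.rotation_deg

    def skip(reason):
        return CrescentCall(
            cell_id=view.cell_id,
            status="skipped",
            skip_reason=reason,
            perimeter_px=perimeter,
            rotation_deg=k,
        )

    if samples.max() <= 0:
        return skip("no signal")
    med = float(np.median(samples))
    mad = float(np.median(np.abs(samples - med)))
    thr = med + params.snr_min * 1.4826 * mad
    candidate = samples > thr
    if not candidate.any():
        if np.allclose(samples, samples[0]):
            return skip("unpolarized")
        return skip("no signal")
    runs = _circular_runs(candidate, params.merge_gap_px)
    runs.sort(key=len, reverse=True)
    longest = runs[0]
    if len(longest) < params.min_arc_px:
        return skip("no signal")
    if len(longest) > params.max_arc_fraction * samples.size:
        return skip("unpolarized")
    if len(runs) > 1 and len(runs[1]) >= params.ambiguity_ratio * len(longest):
        return skip("ambiguous")

    # refine arc extent to the half-maximum of the run, then take the
    # intensity-weighted centre (positions are contiguous along the run)
    vals = samples[longest]
    keep = vals >= 0.5 * vals.max()
    run = longest[keep]
    vals = vals[keep]
    if run.size == 0:
        return skip("no signal")
    # unwrap indices so the run is monotone even if it crosses the seam
    idx = run.astype(float)
    jumps = np.where(np.diff(idx) < 0)[0]
    if jumps.size:
        idx[jumps[0] + 1 :] += samples.size
    centre = float(np.average(idx, weights=vals)) % samples.size
    lo = int(np.floor(centre)) % samples.size
    hi = (lo + 1) % samples.size
    frac = centre - np.floor(centre)
    midpoint = (1 - frac) * contour[lo] + frac * contour[hi]
    return CrescentCall(
        cell_id=view.cell_id,
        status="tagged",
        midpoint_crop=(float(midpoint[0]), float(midpoint[1])),
        arc_crop=contour[run % samples.size],
        basis="automated",
        arc_len_px=float(run.size),
        perimeter_px=perimeter,
        rotation_deg=k,
    )


def restore_coordinates(calls, views) -> list:
    """Map crescent calls from their rotated crops back to the leaf frame."""
    view_by_id = {v.cell_id: v for v in views}
    out = []
    for call in calls:
        if call.cell_id not in view_by_id:
            raise ValueError(f"cell {call.cell_id}: missing rotated view/transform")
        v = view_by_id[call.cell_id]
        if call.status == "tagged":
            call.midpoint_rc = tuple(v.crop_to_leaf(call.midpoint_crop))
            if call.arc_crop is not None:
                call.arc_rc = v.crop_to_leaf(call.arc_crop)
        out.append(call)
    return out


def assign_vector(
    call: CrescentCall,
    cell: CellSegment,
    frame: MidlineFrame,
    pixel_size: float,
    n_rows: int,
) -> BaslVector:
    """Polarity vector from crescent midpoint to centroid, α to midline."""
    if call.status != "tagged" or call.midpoint_rc is None:
        raise ValueError(f"cell {call.cell_id}: cannot assign a vector to a skipped call")
    origin = pixel_to_leaf(call.midpoint_rc, n_rows, pixel_size)
    tip = pixel_to_leaf(cell.centroid_rc, n_rows, pixel_size)
    v = tip - origin
    mag = float(np.hypot(*v))
    if mag == 0:
        raise ValueError(f"cell {call.cell_id}: zero-length polarity vector")
    alpha = frame.angle_to_midline(v)
    return BaslVector(
        cell_id=call.cell_id,
        origin_xy=tuple(origin),
        tip_xy=tuple(tip),
        alpha_deg=alpha,
        magnitude_um=mag,
    )


# ---------------------------------------------------------------------------
# driver and I/O


def tag_cells(
    projection: SurfaceProjection,
    segmentation: Segmentation,
    frame: MidlineFrame,
    seed: int = 0,
    params: TagParams = None,
    blind: bool = True,
):
    """Run the blinded tagging protocol over all non-border cells.

    Returns ``(vectors_df, calls, views)``.  Border-touching cells are
    excluded before presentation; tagged + skipped equals the number of
    cells presented.
    """
    if params is None:
        params = TagParams()
    n_rows = projection.outline.shape[0]
    ps = projection.pixel_size
    views, calls = [], []
    for cell in segmentation.cells:
        if cell.touches_border:
            continue
        view = randomize_orientation(cell, projection, seed, pad=params.crop_pad_px)
        if not blind:
            view = RotatedCellView(
                cell_id=view.cell_id,
                outline=np.rot90(view.outline, -view.rotation_deg // 90).copy(),
                marker=np.rot90(view.marker, -view.rotation_deg // 90).copy(),
                mask=np.rot90(view.mask, -view.rotation_deg // 90).copy(),
                rotation_deg=0,
                origin_rc=view.origin_rc,
                crop_shape=view.crop_shape,
            )
        views.append(view)
        calls.append(detect_crescent(view, params))
    calls = restore_coordinates(calls, views)
    rows = []
    for call in calls:
        rec = {
            "cell_id": call.cell_id,
            "status": call.status,
            "skip_reason": call.skip_reason,
            "alpha_deg": np.nan,
            "magnitude_um": np.nan,
            "centroid_x_um": np.nan,
            "centroid_y_um": np.nan,
            "mid_x_um": np.nan,
            "mid_y_um": np.nan,
        }
        if call.status == "tagged":
            cell = segmentation.cell(call.cell_id)
            try:
                vec = assign_vector(call, cell, frame, ps, n_rows)
            except ValueError:
                call.status = "skipped"
                call.skip_reason = "zero-length vector"
                rec["status"] = call.status
                rec["skip_reason"] = call.skip_reason
                rows.append(rec)
                continue
            rec.update(
                alpha_deg=vec.alpha_deg,
                magnitude_um=vec.magnitude_um,
                centroid_x_um=vec.tip_xy[0],
                centroid_y_um=vec.tip_xy[1],
                mid_x_um=vec.origin_xy[0],
                mid_y_um=vec.origin_xy[1],
            )
        rows.append(rec)
    df = pd.DataFrame(rows)
    n_tag = int((df["status"] == "tagged").sum())
    log.info("tagged %d / %d presented cells", n_tag, len(df))
    return df, calls, views


def write_cell_records(calls, views, out_dir, write_images: bool = False) -> None:
    """One JSON record per cell (optionally with a PNG of the crop)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    view_by_id = {v.cell_id: v for v in views}
    for call in calls:
        rec = {
            "cell_id": call.cell_id,
            "status": call.status,
            "rotation_deg": call.rotation_deg,
            "basis": call.basis,
            "skip_reason": call.skip_reason,
            "midpoint_xy_crop": list(call.midpoint_crop) if call.midpoint_crop else None,
            "midpoint_xy_leaf": list(call.midpoint_rc) if call.midpoint_rc else None,
        }
        (out / f"cell_{call.cell_id:05d}.json").write_text(json.dumps(rec, indent=1))
        if write_images and call.cell_id in view_by_id:
            import imageio.v3 as iio

            v = view_by_id[call.cell_id]
            img = np.stack(
                [
                    v.outline / max(v.outline.max(), 1e-9),
                    v.marker / max(v.marker.max(), 1e-9),
                    np.zeros_like(v.outline),
                ],
                axis=-1,
            )
            iio.imwrite(out / f"cell_{call.cell_id:05d}.png", (255 * img).astype(np.uint8))


def import_manual_tags(
    records, segmentation: Segmentation, boundary_tolerance_px: float = 3.0
):
    """Validate externally produced per-cell calls (manual protocol).

    ``records`` is an iterable of dicts (or a directory of JSON files)
    with fields cell_id, status, midpoint_xy_leaf (full-image pixel
    row/col) and optionally basis.  A tagged record whose midpoint lies
    farther than ``boundary_tolerance_px`` from its cell's boundary is
    rejected.  Returns ``(calls, rejects)``.
    """
    if isinstance(records, (str, Path)):
        records = [json.loads(p.read_text()) for p in sorted(Path(records).glob("cell_*.json"))]
    calls, rejects = [], []
    for rec in records:
        cid = int(rec["cell_id"])
        status = rec.get("status", "tagged")
        basis = rec.get("basis", "three_way_junction")
        if status == "skipped":
            calls.append(
                CrescentCall(cell_id=cid, status="skipped", basis=basis,
                             skip_reason=rec.get("skip_reason", "manual skip"))
            )
            continue
        try:
            cell = segmentation.cell(cid)
        except KeyError:
            rejects.append((rec, "unknown cell id"))
            continue
        mp = rec.get("midpoint_xy_leaf")
        if mp is None:
            rejects.append((rec, "tagged record without midpoint"))
            continue
        d = np.hypot(cell.boundary_rc[:, 0] - mp[0], cell.boundary_rc[:, 1] - mp[1]).min()
        if d > boundary_tolerance_px:
            rejects.append((rec, f"midpoint {d:.1f}px from cell boundary"))
            continue
        calls.append(
            CrescentCall(
                cell_id=cid, status="tagged", midpoint_rc=(float(mp[0]), float(mp[1])),
                basis=basis, rotation_deg=int(rec.get("rotation_deg", 0)),
            )
        )
    return calls, rejects
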