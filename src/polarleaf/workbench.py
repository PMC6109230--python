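"""End-to-end pipeline runner: simulate → segment → tag → fieldmap → stats.

A single :class:`RunConfig` holds every stage's parameter block and one
global seed; the seed is fanned out to the stages through stable
``SeedSequence`` hashing so reruns are byte-identical.  Every segmented
cell is accounted for in the manifest as tagged, skipped (with a reason)
or border-excluded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coords import pixel_to_leaf
from .fieldmap import (
    DownsampleParams,
    MidlineFrame,
    axial_average,
    downsample,
    plot_vector_field,
    region_grid_average,
)
from .shape_stats import (
    angle_triple,
    crescent_length,
    fit_cell_shape,
    summarize,
)
from .stack import ImageStack
from .surfseg import SegmentationParams, project_surface, segment_cells, write_segmentation
from .synthleaf import (
    FieldSpec,
    RenderParams,
    generate_leaf_geometry,
    generate_truth,
    render_stack,
    write_config,
)
from .tagger import TagParams, tag_cells, write_cell_records

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class SimulateConfig:
    width_um: float = 300.0
    n_cells: int = 300
    anisotropy: float = 1.0
    field_type: str = "proximodistal"
    noise_sigma_deg: float = 40.0
    divergence_gain: float = 45.0
    pixel_size: float = 0.5


@dataclass
class ProjectionConfig:
    band_halfwidth: int = 2
    smoothing: float = 1.0


@dataclass
class RunConfig:
    seed: int = 0
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    render: RenderParams = field(default_factory=RenderParams)
    projection: ProjectionConfig = field(default_factory=ProjectionConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    tagging: TagParams = field(default_factory=TagParams)
    downsampling: DownsampleParams = field(default_factory=DownsampleParams)
    ecc_max: float = 0.6
    range_lo: float = -80.0
    range_hi: float = 80.0
    hist_bin_width: float = 20.0
    make_plots: bool = True

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            seed=raw.get("seed", 0),
            simulate=SimulateConfig(**raw.get("simulate", {})),
            render=RenderParams(**raw.get("render", {})),
            projection=ProjectionConfig(**raw.get("projection", {})),
            segmentation=SegmentationParams(**raw.get("segmentation", {})),
            tagging=TagParams(**raw.get("tagging", {})),
            downsampling=DownsampleParams(**raw.get("downsampling", {})),
            **{
                k: raw[k]
                for k in ("ecc_max", "range_lo", "range_hi", "hist_bin_width", "make_plots")
                if k in raw
            },
        )

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    files: dict
    counts: dict

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def stage_seeds(global_seed: int, n: int = 4) -> list:
    """Fan one global seed out to per-stage integer seeds (< 2³¹)."""
    ss = np.random.SeedSequence(int(global_seed))
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_pipeline(config: RunConfig, out_dir) -> RunManifest:
    """Execute the full pipeline and write all artifacts under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    logging.getLogger("polarleaf").addHandler(handler)
    seed_geom, seed_field, seed_render, seed_tag = stage_seeds(config.seed)
    files = {}
    try:
        # --- simulate -----------------------------------------------------
        try:
            sim = config.simulate
            geom = generate_leaf_geometry(
                sim.width_um,
                n_cells=sim.n_cells,
                anisotropy=sim.anisotropy,
                seed=seed_geom,
                pixel_size=sim.pixel_size,
            )
            spec = FieldSpec(
                field_type=sim.field_type,
                noise_sigma_deg=sim.noise_sigma_deg,
                divergence_gain=sim.divergence_gain,
                seed=seed_field,
            )
            truth = generate_truth(geom, spec)
            render = dataclasses.replace(config.render, seed=seed_render)
            stack, tf = render_stack(geom, truth, render)
            stack.write(out / "stack.tif")
            truth.to_csv(out / "truth.csv")
            config.to_yaml(out / "config.yaml")
            write_config(
                out / "generator.cfg",
                width_um=sim.width_um,
                n_cells=geom.n_cells,
                field_type=sim.field_type,
                noise_sigma_deg=sim.noise_sigma_deg,
                seed=config.seed,
            )
            files["simulate"] = ["stack.tif", "truth.csv", "config.yaml", "generator.cfg"]
        except Exception as exc:
            raise StageError(f"simulate: {exc}") from exc

        # --- segment ------------------------------------------------------
        try:
            proj = project_surface(
                stack, config.projection.band_halfwidth, config.projection.smoothing
            )
            seg = segment_cells(proj, config.segmentation)
            write_segmentation(seg, out, stack.pixel_size)
            files["segment"] = ["labels.tif", "cells.csv"]
        except Exception as exc:
            raise StageError(f"segment: {exc}") from exc

        # --- tag ----------------------------------------------------------
        try:
            n_rows = proj.outline.shape[0]
            mid_px = tf.to_pixel(np.asarray(geom.midline))
            base_um = pixel_to_leaf(mid_px[0], n_rows, stack.pixel_size)
            tip_um = pixel_to_leaf(mid_px[1], n_rows, stack.pixel_size)
            frame = MidlineFrame(base=tuple(base_um), tip=tuple(tip_um))
            vectors, calls, views = tag_cells(
                proj, seg, frame, seed=seed_tag, params=config.tagging
            )
            write_cell_records(calls, views, out / "tags")
            vectors.to_csv(out / "vectors.csv", index=False)
            files["tag"] = ["vectors.csv", "tags/"]
        except Exception as exc:
            raise StageError(f"tag: {exc}") from exc

        # --- fieldmap + stats ----------------------------------------------
        try:
            tagged = vectors[vectors["status"] == "tagged"]
            if len(tagged) == 0:
                raise ValueError("no tagged cells")
            pos = frame.to_frame(tagged[["mid_x_um", "mid_y_um"]].to_numpy())
            alpha = tagged["alpha_deg"].to_numpy()
            ds = downsample(pos, alpha, config.downsampling)
            pd.DataFrame(
                {
                    "x_um": ds.vertices[:, 0],
                    "y_um": ds.vertices[:, 1],
                    "mean_angle_deg": ds.mean_angle,
                    "support": ds.support,
                }
            ).to_csv(out / "field_vertices.csv", index=False)

            shapes = {}
            for cid in tagged["cell_id"]:
                cell = seg.cell(int(cid))
                shapes[int(cid)] = fit_cell_shape(
                    cell.mask, stack.pixel_size, frame, cell_id=int(cid)
                )
            triples = [
                angle_triple(a, shapes[int(cid)])
                for cid, a in zip(tagged["cell_id"], alpha)
            ]
            pd.DataFrame(
                [
                    {
                        "cell_id": t.cell_id,
                        "alpha_midline_deg": t.alpha_midline,
                        "alpha_axis_deg": t.alpha_axis,
                        "axis_midline_deg": t.axis_midline,
                        "eccentricity": shapes[t.cell_id].eccentricity,
                        "area_um2": shapes[t.cell_id].area,
                        "perimeter_um": shapes[t.cell_id].perimeter,
                    }
                    for t in triples
                ]
            ).to_csv(out / "angle_triples.csv", index=False)

            ax_field = axial_average(
                pos,
                [shapes[int(c)].long_axis_angle for c in tagged["cell_id"]],
                radius=config.downsampling.maxdist,
                grid_spacing=config.downsampling.grid_spacing,
                neighbor_threshold=config.downsampling.neighbor_threshold,
            )
            pd.DataFrame(
                {
                    "x_um": ax_field.vertices[:, 0],
                    "y_um": ax_field.vertices[:, 1],
                    "axis_angle_deg": ax_field.axis_angle,
                    "anisotropy": ax_field.anisotropy,
                    "support": ax_field.support,
                }
            ).to_csv(out / "axial.csv", index=False)

            region_grid_average(pos, alpha).to_csv(out / "regions.csv", index=False)

            cres = []
            for call in calls:
                if call.status == "tagged" and call.arc_rc is not None:
                    m = crescent_length(call, stack.pixel_size)
                    cres.append(
                        {
                            "cell_id": m.cell_id,
                            "crescent_length_um": m.crescent_length,
                            "perimeter_um": m.perimeter,
                            "proportion": m.proportion,
                        }
                    )
            pd.DataFrame(cres).to_csv(out / "crescents.csv", index=False)

            fs = summarize(
                alpha,
                n_leaves=1,
                lo=config.range_lo,
                hi=config.range_hi,
                bin_width=config.hist_bin_width,
            )
            fs.to_frame().to_csv(out / "stats.csv", index=False)
            fs.histogram.to_csv(out / "histogram.csv", index=False)
            if config.make_plots:
                plot_vector_field(pos, alpha, path=out / "field.png")
            files["stats"] = [
                "field_vertices.csv",
                "angle_triples.csv",
                "axial.csv",
                "regions.csv",
                "crescents.csv",
                "stats.csv",
                "histogram.csv",
            ]
        except Exception as exc:
            raise StageError(f"stats: {exc}") from exc

        n_border = sum(1 for c in seg.cells if c.touches_border)
        counts = {
            "cells_segmented": len(seg.cells),
            "border_excluded": n_border,
            "presented": len(vectors),
            "tagged": int((vectors["status"] == "tagged").sum()),
            "skipped": int((vectors["status"] == "skipped").sum()),
            "skip_reasons": vectors.loc[vectors["status"] == "skipped", "skip_reason"]
            .value_counts()
            .to_dict(),
        }
        assert counts["tagged"] + counts["skipped"] == counts["presented"]
        manifest = RunManifest(
            config_hash=config.hash(), version=__version__, files=files, counts=counts
        )
        manifest.write(out / "manifest.json")
        return manifest
    finally:
        logging.getLogger("polarleaf").removeHandler(handler)


# ---------------------------------------------------------------------------
# format validation


REQUIRED_VECTOR_COLUMNS = {
    "cell_id",
    "status",
    "alpha_deg",
    "centroid_x_um",
    "centroid_y_um",
    "mid_x_um",
    "mid_y_um",
    "magnitude_um",
}


@dataclass
class FormatReport:
    violations: list

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_formats(run_dir) -> FormatReport:
    """Schema checks over a run directory's artifacts."""
    run = Path(run_dir)
    if not run.exists():
        raise FileNotFoundError(run)
    violations = []

    tif = run / "stack.tif"
    if tif.exists():
        try:
            ImageStack.read(tif)
        except Exception as exc:
            violations.append(f"stack.tif: {exc}")

    vec = run / "vectors.csv"
    if vec.exists():
        df = pd.read_csv(vec)
        missing = REQUIRED_VECTOR_COLUMNS - set(df.columns)
        if missing:
            violations.append(f"vectors.csv: missing columns {sorted(missing)}")
        elif "alpha_deg" in df.columns:
            a = df.loc[df["status"] == "tagged", "alpha_deg"]
            bad = a[(a <= -180) | (a > 180)]
            if len(bad):
                violations.append(f"vectors.csv: {len(bad)} alpha_deg outside (-180, 180]")

    tru = run / "truth.csv"
    if tru.exists():
        df = pd.read_csv(tru)
        need = {"cell_id", "centroid_x", "centroid_y", "true_angle_deg"}
        missing = need - set(df.columns)
        if missing:
            violations.append(f"truth.csv: missing columns {sorted(missing)}")
        else:
            a = df["true_angle_deg"]
            bad = a[(a <= -180) | (a > 180)]
            if len(bad):
                violations.append(f"truth.csv: {len(bad)} true_angle_deg outside (-180, 180]")

    tags = run / "tags"
    if tags.exists():
        for p in sorted(tags.glob("cell_*.json")):
            rec = json.loads(p.read_text())
            for key in ("cell_id", "status", "rotation_deg"):
                if key not in rec:
                    violations.append(f"{p.name}: missing field {key!r}")
    return FormatReport(violations=violations)
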