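"""Shared synthetic fixtures.

Everything is generated at test time from seeds; the heavier pipeline
artifacts are session-scoped so multiple tests can reuse one rendering.
"""

import numpy as np
import pytest

from polarleaf import synthleaf as sl
from polarleaf.coords import pixel_to_leaf
from polarleaf.fieldmap import MidlineFrame
from polarleaf.surfseg import project_surface, segment_cells


@pytest.fixture(scope="session")
def clean_leaf():
    """Noise-free 150-cell proximodistal leaf, rendered and segmented."""
    geom = sl.generate_leaf_geometry(220.0, n_cells=150, seed=101)
    truth = sl.generate_truth(geom, sl.FieldSpec("proximodistal", 0.0, seed=102))
    stack, tf = sl.render_stack(geom, truth, sl.RenderParams(noise_model="none", seed=103))
    proj = project_surface(stack)
    seg = segment_cells(proj)
    n_rows = proj.outline.shape[0]
    mid_px = tf.to_pixel(np.asarray(geom.midline))
    frame = MidlineFrame(
        base=tuple(pixel_to_leaf(mid_px[0], n_rows, stack.pixel_size)),
        tip=tuple(pixel_to_leaf(mid_px[1], n_rows, stack.pixel_size)),
    )
    return {
        "geometry": geom,
        "truth": truth,
        "stack": stack,
        "transform": tf,
        "projection": proj,
        "segmentation": seg,
        "frame": frame,
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
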