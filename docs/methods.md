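# Methods

## The measurement model

A leaf epidermis is treated as a planar tissue in which each cell *i*
carries one polarity vector: the unit vector from the midpoint of its
marker crescent to its centroid, reported as the signed angle αᵢ to the
user-defined base→tip midline (degrees, (−180°, 180°], counterclockwise
positive in a tip-up leaf; α = 0° means the crescent sits at the proximal
end). All tissue-level statistics are functions of the αᵢ only — vector
magnitudes are computed and stored but never weighted into any average,
because the underlying biology question is orientation coordination, not
signal displacement.

Angle frames are handled in exactly one place
(`polarleaf.coords`): images are 0-based (row, col) with y down; all angle
arithmetic happens in a mathematical μm frame (y up). Angles are stored in
degrees in every file; radians exist only inside computations.

## Synthetic data: what it emulates and what it does not

No raw image stacks are publicly deposited for this assay, so the
`synthleaf` module generates the study conditions with known truth:

- **Domain** — a symmetric ovate polygon of chosen blade width with a
  fixed length:width ratio of 1.6, matching the staging convention in
  which leaves are classed by width (50–200, 200–400, 400–800 μm).
  The exact silhouette is immaterial to the statistics.
- **Cells** — Lloyd-relaxed (4 iterations) clipped Voronoi tessellation of
  uniformly sampled seed points; cell shape anisotropy is imposed by
  relaxing in a midline-compressed space and mapping back, so a stretch of
  2 yields a mean fitted-ellipse eccentricity near √(1 − 1/4) ≈ 0.87.
- **Field** — `proximodistal`: every true angle is 0° plus noise.
  `divergent`: angle = −gain · lateral_offset · (1 − proximal_position),
  clipped to ±90°, so vectors splay toward the nearer margin, most
  strongly in the proximal lamina and not at all at the tip. Angular noise
  is i.i.d. wrapped normal; for the wrapped normal the parameter σ *is*
  the circular SD √(−2 ln R), which makes estimator-recovery tests exact
  in expectation.
- **Crescent truth** — the crescent centre is the intersection of the ray
  from the centroid opposite the polarity vector with the cell boundary
  (the boundary point most anti-parallel to the vector), so the
  midpoint→centroid construction reproduces the true angle up to
  discretization. The rendered arc covers `crescent_arc_fraction` of the
  perimeter (default 0.25, in the range observed for crescent
  length/perimeter proportions) as one contiguous run that may span cell
  vertices.
- **Rendering** — membranes are the rasterized tessellation boundaries
  (~2 px wide); crescents are drawn **inset ~1.5 px toward the cell
  interior**, reflecting that the marker is cytoplasmic and hugs the inner
  face of the membrane. This inset is what makes signal on a shared wall
  attributable to the owning cell; without it, a cell's distal wall would
  carry its neighbor's crescent indistinguishably. Both channels ride on a
  low-frequency sinusoidal height map across `z_slices` slices (default 5,
  amplitude 1 px) — enough to exercise surface projection without
  modelling real leaf curvature, whose magnitude is not quantified
  anywhere we could calibrate against. Gaussian detector noise (SD 2 on a
  0–255 intensity scale) is applied last; Poisson shot noise is available.

Not emulated: point-spread-function blur, bleaching, spectral crosstalk,
stomatal-lineage divisions, lobed pavement-cell outlines (cells are
convex-ish polygons) and time-lapse growth. Passing tests therefore show
that the measurement chain is correct and unbiased on well-resolved,
convex-celled tissue; they do not certify segmentation robustness on
heavily lobed cells or low-SNR stacks.

## Surface projection and segmentation

The height map is the per-(y, x) argmax over z of the laterally smoothed
outline channel, median-filtered (5 px); each channel is then
max-projected within ±`band_halfwidth` slices (default 2) of the surface,
excluding off-surface signal. A band rather than a single surface voxel
was chosen so that signal a slice off the detected surface survives
noise in the height estimate.

Cells are segmented by marker-controlled watershed on the blurred
(σ = 2 px) projected outline channel. Seeds are h-minima with depth 10% of
the dynamic range (absolute override available); the leaf mask is the
largest connected component of above-Otsu signal with holes filled;
regions below `min_cell_area_px` (50) are merged into the neighbor
sharing the longest boundary. These defaults stand in for the original
tool's per-leaf parameters, and all are overridable per image.
Border-touching cells are flagged and excluded from all downstream
statistics: truncated masks bias both centroids and ellipse fits.

## Blinded tagging

To remove observer bias from crescent calls, each cell is cropped and
rotated by one of {0°, 90°, 180°, 270°}, drawn from a generator keyed on
(seed, cell id) so results are independent of iteration order. The
automated detector resamples the cell contour at ~1 px spacing, reads the
marker intensity 1.5 px inside the boundary (local 3×3 maximum), and
thresholds at background median + 5 × scaled MAD. Candidate runs are
circularly merged across ≤2 px gaps; the longest run is the crescent, its
intensity-weighted centre (refined to the run's half-maximum extent) is
projected back to the boundary as the midpoint. Cells are *skipped*, never
errored, when there is no run ≥ 4 px ("no signal"), the run exceeds 60% of
the perimeter ("unpolarized"), or a second run reaches 80% of the longest
("ambiguous" — typically a shared-wall conflict). Manual calls made on
exported blinded crops can be imported instead; records whose midpoint
lies > 3 px from the cell boundary are rejected.

The detector is rotation-equivariant by construction, up to boundary
resampling, which is pixel-quantized: a rotation can move the detected
midpoint by at most about one boundary pixel, i.e. ≲5° of α for the
smallest cells, with zero mean. The blinding-soundness test pins both the
per-cell bound and the absence of any distribution-level shift.

## Field maps

Downsampling places a hexagonal (triangular-grid) lattice, aligned to the
rotated tip-up frame, over the leaf (spacing 25 μm); each vertex averages
the unit vectors of all α within `maxdist` (20 μm) and is retained only
with ≥ `neighbor_threshold` (3) contributors and a mean resultant length
above 10⁻⁶ (antiparallel cancellation guard). The original tool's values
for these knobs are not recorded; the defaults give a readable field on a
~400 μm leaf and are fully configurable. Vectors contributing to no
retained vertex are counted and logged.

Cell long axes are 180°-periodic, so local averaging superimposes each
orientation as a ±unit endpoint pair at the origin and takes the first
principal axis of the cloud; this equals the doubled-angle circular mean
(a property test holds them to 10⁻⁶ degrees) and yields an anisotropy
λ₁/(λ₁+λ₂) ∈ [0.5, 1]. Region summaries split the bounding box of the
vector origins into equal thirds (3×3) and report circular means.

## Statistics

- **Dispersion** — σ = √(−2 ln R̄) in degrees; σ = 0 exactly for identical
  angles and capped at 180° as R̄ → 0. Which circular-SD estimator the
  original analysis used is not recorded; this one is the standard choice,
  is self-consistent with the wrapped-normal noise model, and accommodates
  reported values above 80°.
- **Coordination** — the fraction of α strictly inside (−80°, 80°). The
  endpoints are treated as an open interval; the boundary has measure zero
  in practice and the choice is documented for bit-exactness.
- **Comparisons** — Pearson chi-square on the 2×2 (dataset × in/out)
  table, df = 1, no continuity correction; an empty in/out margin is an
  error and expected counts below 5 raise a warning.
- **Shape** — ellipse fits by second central moments;
  eccentricity √(1 − (b/a)²) (equivalently focus distance over semi-major
  axis); cells with e < 0.6 (strict) are "near-isotropic". Perimeters are
  polygonal lengths of the traced boundary contour after a 5-point
  circular moving average, which removes the ~6% staircase bias of raw
  marching-squares contours (≲0.3% residual on a rasterized circle).
- **Histograms** — 20° bins over (−180°, 180°], matching the visual
  granularity of the published orientation histograms; configurable.
- **Pooling** across leaves is plain concatenation of per-cell α with no
  per-leaf weighting.

## Determinism and problem sizes

One global seed is fanned out to the simulate/field/render/tag stages via
`numpy.random.SeedSequence`, making reruns byte-identical (the manifest
records a config hash and full cell accounting: tagged + skipped =
presented, presented + border-excluded = segmented). Tests and the
acceptance script use leaves of 80–300 cells at 0.5 μm/px — large enough
that circular statistics stabilize (±2° at n ≈ 300) while a full pipeline
run takes a few seconds.

## Known limitations

- The divergent-field functional form is a single-knob phenomenological
  model, not a growth simulation.
- Crescent attribution relies on the cytoplasmic inset; markers imaged
  with no resolvable offset from the membrane would need the manual-import
  path and vertex-based judgement.
- Isotropic-cell subsets inherit the discreteness of the e < 0.6 cut; near
  the threshold, rasterization noise of ±0.01 in e can move cells across
  it.
- The 3×3 region grid uses the bounding box, not the leaf outline, so
  corner regions mix margin and lamina cells.
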