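# Methods

This note records the models implemented in `cellsoc`, the parameters that
matter, the numerical conventions, and what the synthetic-data generators do
and do not emulate.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Spectral model and unmixing

Transmitted-light imaging of chromogen-stained tissue is modeled as
Beer–Lambert absorption: with per-band blank intensity `blank(b)` and
recorded intensity `I(p, b)`, the optical density
`OD(p, b) = log10(blank(b)/I(p, b))` is a linear mix of the stains'
absorbance spectra weighted by their local concentrations, plus error:
`OD = C·S + E`.  Conventions:

- **Intensity floor** — intensities are clamped to 1 count before the log
  (the clamped-pixel count is recorded and logged); OD is floored at 0 where
  intensity exceeds the blank, since negative chromogen absorbance is
  unphysical.
- **Spectrum normalization** — each spectrum is scaled to unit maximum
  absorbance at construction.  The bilinear model `C·S` has a per-stain
  scale indeterminacy; anchoring `max(S_k) = 1` pushes the full scale into
  the concentrations, which is what downstream thresholding consumes.
- **Solver** — with fixed spectra the problem separates into one small NNLS
  per pixel.  The unconstrained least-squares solution is accepted where
  already non-negative (then identical to NNLS); remaining pixels use an
  active-set solve.  Deterministic, no iteration, `converged = True` by
  construction.
- **Alternating refinement** (optional) — when the supplied spectra are only
  approximate, `refine_spectra=True` alternates NNLS for `C` given `S` and
  for `S` given `C` (rows re-normalized to unit max each pass, scale folded
  back into `C`), stopping when the relative residual change drops below
  `tol` (default 1e-6) or the residual itself is negligible, up to
  `max_iter` (50) passes.  Initialization is the supplied spectra; no
  randomness.  Concentrations are never renormalized: per-pixel sums are
  deliberately unconstrained (no additivity/closure).
- **Rank checks** — a rank-deficient spectra matrix aborts with an error
  naming the most collinear pair (largest pairwise cosine).
- Flat-field / dark-field handling is reduced to the blank-reference
  division; fixed-pattern-noise modeling is out of scope.
- An artifact channel (e.g. pigment or debris absorbing across the band
  range) can be supplied as an additional "stain" spectrum; it is unmixed
  like any other and simply ignored downstream.

## Nuclei segmentation

Input is the hematoxylin concentration map, default pixel pitch 0.33 µm.
The size rules are expressed in pixels at that pitch:

| parameter | default | role |
|---|---|---|
| `min_size` | 50 px | components smaller than this are debris |
| `split_size` | 1000 px | components larger than this get re-thresholded |
| `fragment_size` | 150 px | re-threshold fragments this big become new objects |
| `max_iter` | 3 | total thresholding passes |
| `h` | 2 px | h-maxima depth for watershed seeding |

Procedure: global Otsu → drop `< min_size` → watershed split → up to two
further passes in which each `> split_size` component is re-thresholded by
Otsu *restricted to its own pixels* (necessarily a higher threshold, which
realizes "increasing intensity thresholds" without a magic constant),
followed by another watershed pass.

Numerical choices:

- **Connectivity** is 8-connected throughout.
- **Otsu** uses 256 bins over the data's own min–max range, making the whole
  pipeline invariant under positive rescaling of the map.  Ties in the
  between-class variance (plateaus from empty histogram gaps) are broken at
  the plateau midpoint so the threshold falls mid-gap rather than hugging
  the lower mode.
- **Watershed** runs per component on the negated Euclidean distance
  transform, seeded at h-maxima (`h = 2 px` suppresses shallow secondary
  peaks so roughly convex nuclei are not over-split); pieces below
  `min_size` are merged into the sibling they touch most.
- **Oversized-component splitting**: when the inner re-threshold yields ≥ 2
  fragments of `fragment_size` or more, the parent's *entire* pixel set is
  repartitioned among those fragments by a fragment-seeded watershed —
  sub-threshold pixels and small fragments rejoin the nearest large
  fragment, conserving area.  With fewer than two large fragments the parent
  is left intact.  The `split_size` test is applied to post-watershed
  objects.
- **Boundary refinement**: each nucleus's boundary pixels are returned to
  background where the map falls below 50% of that component's Otsu level;
  a removal that would empty or disconnect a nucleus is reverted.  This is
  the package's own refinement rule — a deliberately simple, testable
  substitute for edge-relocation methods from the nuclear-morphometry
  literature, not a reimplementation of any of them.

## Phenotyping

Marker intensities are integrated over the nucleus mask expanded by a 2-px
ring (`expand_labels`, territories never overlap), because CD3/CD8/CD79a are
membranous; the nuclear counterstain integrates over the nucleus only.  Both
behaviours are configurable (`membrane_ring_px=0` for nucleus-only).

Positivity is one threshold per stain per slide, applied to every region
from that slide.  The package standardizes on "larger integrated
concentration = more positive"; legacy 0–255 inverted scales (positive
*below* threshold) are supported via `scale_direction="below"`.  When no
thresholds are supplied, a per-slide Otsu on each stain's integrated-
intensity histogram stands in for interactive visual thresholding;
interactivity itself is out of scope, and the automatic default is only
sensible when the slide actually contains both positive and negative cells
for the stain.

The 2³ sign patterns map onto phenotypes as described in
`cellsoc.phenotyping`; two rules need justification:

- **CD3−CD8+ (with or without CD79a)** — biologically rare (possibly NK
  cells or staining artifacts); assigned to the unstained pool rather than
  dropped so that the tissue architecture (the Voronoi tessellation) is
  preserved.
- **CD3+CD79a+ conflicts** — T and B lineage markers are incompatible in one
  cell; the usual cause is two overlapping nuclei the segmentation merged.
  The package replaces manual review with a geometric rule: the conflict is
  deemed an overlap when the CD3- and CD79a-intensity-weighted centroids
  (within the nucleus) lie ≥ `overlap_min_offset_px` (2 px) apart.  If so,
  the cell is split: the majority stain keeps the original nucleus, the
  minority stain gets a new cell at its own weighted centroid
  (`origin = split_added`, carrying `parent_id`); a CD8+ parent keeps its
  cytotoxic identity.  Without offset evidence the cell is excluded.
  Excluded cells stay in the tessellation — they shape their neighbors'
  polygons — but enter no frequency numerator or denominator and no density.

## Neighbor graph and sociology statistics

Neighbors are cells whose Voronoi polygons share a boundary segment of
positive length.  Implementation: scipy's Voronoi diagram of all in-ROI
centroids; every ridge (unbounded ridges extended well past the ROI) is
clipped to the ROI polygon with shapely, and an edge is kept iff the clipped
length exceeds 1e-9 px.  Consequences of these choices:

- **ROI clipping** removes the spurious hull-spanning adjacencies of
  unbounded Voronoi cells without introducing any distance cutoff — the
  neighborhood definition stays parameter-free.
- **Cocircular degeneracies** (4+ points on a circle) produce zero-length
  ridges / point contacts, which the `> 1e-9 px` rule rejects: corner
  touching is not neighborhood.
- **Duplicate centroids** are jittered by 1e-6 px (deterministically, with a
  logged warning); fewer than 3 cells or all-collinear cells raise a
  degenerate-geometry error.
- Cells outside the ROI polygon are ignored; cells whose polygon touches the
  ROI boundary remain valid nodes.

For focal cell *i*: `f_i(N) = #{neighbors of phenotype N} / #{non-excluded
neighbors}`.  Per region and ordered pair (F, N), the mean and SD (sample,
ddof = 1; 0 for a single focal cell) are taken over all F-cells with at
least one eligible neighbor; focal cells with none are *skipped*, not
counted as zeros (they carry no neighborhood information; the choice is
logged and only matters in near-degenerate regions).  Frequencies over all
phenotypes sum to 1 per focal cell.  `f(F, N)` is not forced to equal
`f(N, F)`; both orders are reported.  Densities divide phenotype counts by
the ROI polygon area converted via `pixel_spacing_um²` (default 0.33 µm).
Density and neighbor frequency are deliberately decoupled: two rare
phenotypes clustered together show low densities but cross-frequencies near
1.

## Permutation test

Null hypothesis: given the positions and the per-phenotype counts, labels
are exchangeable.  Labels of non-excluded cells are permuted uniformly
(sampling *without* replacement — counts are preserved exactly; excluded
cells keep label and position), the graph is never rebuilt, and the mean
neighbor frequency of each requested pair is recomputed per replicate.
Default 500 replicates; `z = (observed − mean)/sd` with the sample SD
(ddof = 1); `sd = 0` yields a degenerate flag instead of a z.  |z| > 3 is
the non-randomness call; negative z means the pair neighbors less than
random (avoidance), positive more (colocalization).  Permutation is per
region — positions and counts are region-specific, so pooling across a
slide would mix incompatible geometries.  All pairs requested in one call
share one replicate stream (coherent joint null, reproducible by seed).

## Cohort comparison and benefit score

Group comparison is a two-sided Mann–Whitney U on per-patient values
(ROI rows are first averaged per patient; configurable off): the exact
distribution when both groups have ≤ 20 values and no ties, the normal
approximation with tie correction otherwise.

The ROI benefit score formalizes "does sociology classify this patient
better than density?".  Per metric and outcome group g, an interval
`I_g = [μ_g − σ_g, μ_g + σ_g]` is computed over ROI-level values pooled
across the group's patients.  An ROI value is **informative** when it lies
in exactly one group's interval (that group is its call); in both or
neither, it is uninformative.  Per ROI: **+1** if density is uninformative
and sociology calls the true outcome; **−1** if sociology calls the wrong
outcome; **0** otherwise.  Patient verdicts: improved (Σ > 0), no change
(Σ = 0), misclassified (Σ < 0).  Published descriptions of this style of
scoring are ambiguous about what "within the range" means when intervals
overlap; the exactly-one-interval formalization was chosen because it
reproduces the +1/0/−1 trichotomy with no additional parameters.  By
default the evaluated patient's own ROIs are excluded from the interval
statistics (leave-one-patient-out) to avoid self-classification; this is
configurable off, and falls back to the full group when a patient is its
group's only member.  A zero-variance group collapses its interval to a
point (logged).

## Synthetic data

`generate_tissue` emulates labeled point patterns in an ROI.  The tumor
background is a hexagonal lattice (default spacing 30 px ≈ 10 µm, matching
epithelial packing at 0.33 µm/px, i.e. densities of a few thousand
cells/mm²) with Gaussian jitter of SD 15% of the spacing — hexagonal
packing approximates epithelial sheets and the jitter guarantees
non-degenerate Voronoi cells.  Immune placement regimes span the
null-to-structured continuum:

- `uniform` — labels assigned at random positions (multinomial counts);
- `clustered` — Neyman–Scott: Poisson-sized Gaussian clusters
  (default mean 15 cells, offspring SD 18 px) around uniform parents;
- `segregated` — tumor and immune cells in disjoint vertical blocks;
- `infiltrated` — a fraction `mixing_fraction` of immune cells dispersed
  among the lattice, the remainder clustered.

`render_cube` forward-models the stained slide: Gaussian hematoxylin blobs
(SD 3 px) per nucleus plus wider marker blobs (SD 4.5 px, amplitude 0.8)
per phenotype, mixed to OD through the spectra, optional Gaussian noise on
the OD scale, `I = blank·10^(−OD)` with blank 4000 counts.  The default
spectra are synthetic Gaussian absorbance bumps with distinct peaks for
hematoxylin / Ferangi Blue (CD3) / DAB (CD8) / Warp Red (CD79a) — linearly
independent, which is all the model requires, but *not* measured chromogen
spectra.

`generate_cohort` simulates 11 recurrent vs 8 non-recurrent patients × 5
ROIs (95 rows, the cohort geometry the method targets) with ~250 cells and
~10% immune fraction per ROI.  The group effect is injected purely through
the infiltration mixing fraction (recurrent 0.15 vs non-recurrent 0.60,
patient-level SD 0.08); each ROI's immune count is the same
Binomial(n_cells, 0.10) draw in both groups, so densities are matched in
distribution and only the spatial arrangement separates the groups.
Problem sizes (250 cells/ROI, 500 permutation replicates, 200 replicate
cohorts in the acceptance suite) were chosen as the smallest at which the
spatial statistics are stable.

What passing tests on these fixtures does **not** show: real tissue has
segmentation errors correlated with staining, stromal/epithelial
compartments, anisotropic cell shapes, sectioning artifacts and
slide-to-slide staining variability, none of which the generators emulate.
The fixtures validate the *computations*; they say nothing about antibody
panels or clinical effect sizes.

## Determinism and I/O conventions

Every stochastic operation takes an explicit seed (generators, permutation
test, noise); identical config + seed reproduces byte-identical CSVs.
Coordinates are pixel units, origin top-left, x = column, y = row, 0-based.
CSVs are UTF-8, comma-separated, with floats at 9 significant digits; cubes
and maps are multi-page TIFF; ROIs are GeoJSON polygons in pixel
coordinates; configuration is schema-validated JSON that rejects unknown
keys with a JSON-pointer path.  Output directories carry a provenance
sidecar (package version, timestamp, input SHA-256 hashes, seeds,
parameters).

## Known limitations

- The NNLS fast path solves all pixels unconstrained first; for very large
  cubes the per-pixel fallback loop dominates when many pixels are truly
  mixed. No tiling/streaming is implemented.
- The boundary-refinement rule is intensity-only; it cannot recover
  boundaries the initial threshold merged.
- Auto-thresholds (per-slide Otsu) misbehave on slides where a marker has
  no true positives; supply config thresholds for such panels.
- The conflict-overlap heuristic assumes exactly two overlapping cells; a
  triple overlap would be split into at most two.
- Whole-slide pyramid formats (SVS/NDPI), stage control, stitching and
  autofocus are out of scope; inputs are in-memory arrays or plain TIFFs.
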