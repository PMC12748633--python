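# Methods

This note records the model behind `phasedig`, the parameters that matter,
the numerical choices made where the design was open, and what the
synthetic-data tests do and do not demonstrate about real scanned diagrams.

## The soft-labeling model

A digitized diagram is a partition of the temperature–composition rectangle
into labeled domains separated by one-pixel boundary lines. For a grid
point mapped to test pixel *p*, the minimum distance *dᵢ* from *p* to each
phase domain *i* is computed, and the phase probability is the normalized
truncated exponential kernel

    Pᵢ ∝ exp(−dᵢ / 2),   with raw weights < 10⁻³ set to exactly 0.

The kernel expresses measurement uncertainty near phase boundaries: a point
well inside a domain is certain (dᵢ = 0 for its own phase, every other
phase beyond the cutoff), while points near a boundary split their
probability smoothly across the adjacent phases — exactly 0.5/0.5 on the
boundary pixel itself. The cutoff distance is −2 ln 10⁻³ ≈ 13.8155 data
units: phases farther than that contribute exactly zero, which keeps the
output sparse and prevents far-away domains from bleeding probability
across a large diagram.

**Distance units.** Distances are measured in data units with a 1 °C step
treated as equal in length to a 1 wt% step, not in raw pixels, so results
are independent of scan resolution. The pixel→unit conversion is isolated
in `AxisCalibration.units_per_pixel()`; an anisotropic weighting could be
swapped in there without touching anything else (a deliberate hook, not an
implemented feature). For a log-scaled axis the conversion is defined in
the log10-transformed span, so "distance" on that axis is in decades scaled
by the axis range; log axes are rare in this domain and the choice is
documented rather than load-bearing.

**Exactness of the fast path.** Per-phase distance fields use
`scipy.ndimage.distance_transform_edt` with anisotropic sampling, but only
to find the *nearest pixel indices*; the distance itself is recomputed from
the row/column offsets with the same
`sqrt((Δr·uₜ)² + (Δc·u_w)²)` expression a brute-force scan uses, so the
fast path equals exhaustive search bitwise, not approximately.

**Degenerate rows.** If thresholding zeroes every phase the row cannot be
normalized; this can only happen for a point farther than ~13.8 units from
every domain, which is impossible for a point inside an enclosed diagram.
It raises an error rather than emitting an unnormalizable row.

## Image processing

- **Digital topology.** Phase domains are 4-connected, boundary ink is
  8-connected. This prevents a domain from leaking diagonally through a
  line whose pixels touch only at corners.
- **Binarization.** Normalized darkness ≥ 0.5 by default; configurable for
  poor scans. Deterministic, no adaptive thresholding.
- **Frame detection.** Among 8-connected ink components, the one enclosing
  the largest interior (computed by hole-filling) is the plot frame; its
  four extreme corners (min/max of r±c) define the quadrilateral. An image
  with no closed contour is rejected: the workflow requires diagrams
  enclosed on all four sides.
- **Rectification.** A projective transform maps the four corners onto the
  output rectangle; binary images are resampled nearest-neighbor so the
  result stays binary. Collinear corners are a geometry error.
- **Cleaning.** `keep_largest(mask, n)` ranks 8-connected ink components by
  pixel count (ties: earliest raster-scan pixel) and erases all but the
  largest *n*. Dashed-to-solid conversion, parallel-line midlines and the
  like are deliberately *manual*, expressed as edit primitives (draw/erase
  segment, isotherm at a temperature, extend-along-slope); automatic dash
  detection is out of scope.
- **Extension slope.** An open boundary is continued from its endpoint
  along the direction from the centroid of the last k = 5 curve pixels to
  the endpoint, marching in half-pixel steps until it meets other ink or
  the frame.
- **Thinning.** Ink pixels are removed in order of decreasing
  white-8-neighbor count, raster order among ties, and a pixel is removed
  only if its white 4-neighbors all belong to a single area — i.e. only if
  the number of areas (counted exactly as the labeling step counts them)
  stays unchanged. An incremental union-find makes each test O(α): areas
  only ever grow and can never merge, so the invariant is enforced, not
  merely checked afterwards. Image-border pixels are never removed: after
  cropping/rectification the border carries the enclosing frame, which must
  stay boundary ink so that curve tips keep their anchors and outer domains
  stay closed. Consequences worth knowing: interior separating lines end up
  exactly one pixel wide; interior ink that separates nothing (solid blobs,
  spurs) erodes away entirely; thinning is idempotent.
- **Labeling.** 4-connected white areas get labels 1..n (`scipy.ndimage.label`);
  ink keeps 0; n is the region count. The region→state mapping is a curated
  user input — region numbering is an artifact of the labeling pass.

## Curve tracing

Guide points snap to the nearest ink pixel (Euclidean, raster order on
ties); a snapped pixel within 2 px of the image border that has an
8-connected ink neighbor *on* the border snaps to that border pixel
instead, so curves attach to the frame. Consecutive points in the same
8-connected line component are joined by breadth-first search over
4-connected moves restricted to that component (fixed neighbor order up,
down, left, right — any fewest-steps path is acceptable, and the traced
path is by construction a subset of the original curve). Points in
different components are joined by a Bresenham segment. Note a genuinely
diagonal 1-px curve admits no 4-connected path; this is reported as a
routing error rather than silently bridged, and in practice thinned scan
lines are traced piecewise with guide points on 4-connected stretches or
reconnected by straight segments.

## Synthetic diagrams and what the tests show

The generator rasterizes polygonal regions that tile the axis rectangle,
plus isotherm lines and nuisance ink (text-like blobs, dashed segments,
optional grid lines, optional frame shear for skewed book scans), at a
default 401×401 px for a 0–100 °C × 0–100 wt% diagram (4 px per data unit,
typical of a decent figure scan) with a default 3-px line width (thick
enough that thinning is exercised). Everything is deterministic given the
seed.

Because the vector geometry is known, expected probabilities come from
exact shapely point-to-polygon distances through the same kernel — an
oracle independent of every raster code path. Rasterization displaces each
measured distance by at most about 1.5 px when boundaries are drawn at one
pixel width with vertices on exact pixels (Bresenham deviation ≤ 0.5 px
plus the one-pixel offset between a boundary line and the first interior
pixel); the pipeline-vs-oracle tests therefore check that every sampled
probability lies inside the band obtained by sliding all exact distances
through ±1.5 px. The agreement tests use 1-px lines and pixel-exact
vertices (`knot_quantum=0.25` wt% at 4 px/unit) so that this bound is a
theorem about the geometry, not an empirical tolerance.

What passing does *not* show: robustness to real scan artifacts (JPEG
noise, paper-fold shading, moiré, broken lines, typography overlapping
curves). Those require the manual cleaning and editing stages; the
synthetic nuisance ink only exercises the automatic component-size
cleaning.

## Record format and vocabulary

Records store probabilities as percentages at full float precision; the
0.33/0.33/0.33-style values seen in presentation tables are treated as
rounding for display, not storage, since they cannot sum to exactly one.
The validator checks normalization (default tolerance 10⁻⁶ of the 100 %
sum — the writer's own output passes exactly), composition within
[0, 100] wt%, vocabulary-valid state columns, equal-length value lists,
method codes within A–F, and that a `U` (unknown) column appears only in
diagrams marked incomplete. SMILES strings are stored verbatim and are not
assumed unique — one compound may have several source diagrams.

The packaged vocabulary carries 35 single-phase labels with their common
literature aliases (lamellar reported as D, G or L_α all resolve to `La`;
resolution is case- and subscript-insensitive and never guesses: unknown
labels return an explicit `unmapped` sentinel) and the canonical list of
118 observed one- and two-phase states, alphabetically canonicalized
(`W+X1`, never `X1+W`). One state in the packaged list, `V2i+W`, is
reconstructed from a corrupted cell of the source table; the data file's
provenance note records the reasoning. X1–X6/Xa/Xb are opaque distinct
solid labels — no hydration-state semantics are modeled. The vocabulary is
a plain JSON data file and can be overridden (`--vocab FILE`) for future
extension.

## Parameter summary

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| grid spacing | 1 × 1 | °C, wt% | the corpus' common resolution; ~10k points per full-range diagram |
| kernel length scale | 2 | data units | fixed by the model, `exp(−d/2)` |
| probability cutoff | 10⁻³ | — | sparsifies output; reach ≈ 13.8155 units |
| binarize threshold | 0.5 | fraction of darkness | clean scans; configurable |
| snap border margin | 2 | px | "near the border" quantified conservatively |
| extend slope window | 5 | px | local slope from the last few curve pixels |
| raster resolution (synth) | 401×401 | px | 4 px per data unit, scan-like |
| line width (synth) | 3 | px | exercises thinning; 1 for exact-geometry tests |

## Known limitations

- No OCR: axis numbers and in-figure phase labels are user-supplied
  (calibration file, region→state map).
- Dashed lines, tie lines and annotation arrows are removed or replaced via
  manual edit primitives, not detected automatically.
- Fewest-steps tracing requires 4-connected stretches of curve; diagonal
  pixel chains raise a routing error.
- Log-axis distance semantics are a documented convention (log10 units),
  exercised far less than the linear path.
- The categorical sampling mode (nearest phase, ties to the lowest region
  label) exists for cross-validation against manually digitized grids, not
  as the primary output.
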