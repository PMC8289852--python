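# Methods

## Model and assumptions

`tubeunroll` operates slice-wise in 2D: each image slice of the stack is
assumed to show one cross section of a single, roughly vertically
aligned tube, bounded by a simple closed inner contour strictly inside a
simple closed outer contour. The method does not segment these
boundaries — they are inputs, drawn by the user on a subset of slices
(the *key slices*). Between the boundaries the wall is assumed to be a
topological annulus on every slice (no self-intersections, no branches)
and to vary smoothly from slice to slice, smoothly enough that natural
cubic splines through contours spaced *m* slices apart describe the
intervening shape.

The central construction treats the two boundaries as oppositely
charged conductors. An exact electrostatic field between two closed
conductors has field lines that never cross, never loop, and meet both
boundaries perpendicularly — ideal trajectories along which to measure
local wall thickness and to place internal contours at fixed fractions
of that thickness. The implementation approximates those lines: the
field is summed over a finite sliding window of point charges, lines
advance in straight segments of finite length δ, and the approximation
is allowed to fail on difficult geometry. Failures are detected (stray
and collapsed lines) and the affected lines removed rather than
repaired; the internal contours interpolate across the gaps.

Coordinates are image coordinates throughout: x = column (right),
y = row (down), origin at the top-left of each slice, 0-based,
continuous. "Counter-clockwise" means positive shoelace signed area in
this frame; for star-shaped contours this equals increasing azimuth
`atan2(y−o_y, x−o_x)` about an interior point.

## Parameters

| name | meaning | unit | default |
| --- | --- | --- | --- |
| `I` (`n_points`) | points per boundary contour = charges per boundary = points per internal contour | – | 200 |
| `w` (`window`) | half-width of the sliding charge window; 2w+1 ≤ I | – | 15 |
| `δ` (`delta`) | field-line segment size; keep well below the thinnest wall | px | 2 |
| `rigidity` | outer/inner charge-magnitude ratio; larger values straighten lines, smaller ones let them follow the outer boundary's curvature | – | 1 |
| `K_max` (`k_max`) | maximum segments per line; lines exceeding it are *stray* | – | 75 |
| `V_min` (`v_min`) | minimum point-scatter variance; lines below it are *collapsed* | px² | 50 |
| `C` (`depth_levels`) | relative depth levels, 0 % … 100 % inclusive | – | 30 |
| `m` (`interp_interval`) | key-slice spacing for field-line tracing | slices | 20 |
| `O` (`origin`) | rotation axis for opening contours; constant across slices and depths | px | inner-boundary centroid of the first slice |

The defaults are the parameter set documented for micro-CT murine-colon
stacks (walls on the order of 10² px thick). Two of them scale with the
geometry and must be adapted to thin-walled data:

* **V_min** — a straight line of length *d* sampled every δ has point
  scatter ≈ d²/12, so `V_min = 50 px²` silently rejects *every* line in
  a wall thinner than ≈ 25 px. The analytic 20-px annulus used by the
  verification bench therefore runs with `V_min = 1`. The filter is a
  pure threshold applied to all lines after tracing, complete or not.
* **δ** — must stay below the local thickness or the very first step
  overshoots the wall (such lines are treated as collapsed-at-start).

## What the phantom generator does and does not emulate

`tubeunroll.phantom` renders tubes with analytically known geometry:
constant or linearly tapered radii, sinusoidal boundary deformation
`r(θ) = R(1 + a·cos(kθ + φ(h)))` with a linear twist φ(h), and disc
markers embedded at exact (azimuth, relative depth) positions. Boundary
contours are emitted analytically rather than re-segmented from the
raster, so meshing tests are not confounded by segmentation error.
Noise is additive Gaussian, seeded, and defaults to zero.

The phantom deliberately does **not** simulate CT physics (phase
contrast, beam hardening, ring artifacts), anisotropic voxels,
non-simply-connected walls, or hand-drawn contour wobble. Passing the
bench therefore demonstrates the correctness of the geometry pipeline —
tracing, contouring, interpolation, mapping, inversion — on smooth
walls with exact boundaries; it does not bound the error contributed by
manual contouring or imaging artifacts on real data.

## Numerical choices

* **Explicit stepping.** Each segment follows the field evaluated at
  the tip of the previous segment (an explicit Euler update of the
  field-direction ODE). The first step bypasses the field entirely — it
  would be singular at the start charge — and follows the boundary
  normal into the wall, with the sign chosen by an
  inside-the-annulus test.
* **Termination and clipping.** A line is complete as soon as a point
  is no longer strictly inside the outer polygon (boundary points count
  as outside the annulus, giving a clean termination test). The final
  segment is clipped at its exact intersection with the outer polygon,
  removing up to δ of quantisation from `d_i`; `clip_final=False`
  restores the K·δ convention.
* **Variance filter.** `V_i` is the trace-form scatter
  `(1/K) Σ_k ‖p_k − p̄‖²` over all K+1 points about their centroid.
  (Normalising the *mean* by K instead of K+1 would make the statistic
  depend on absolute coordinates; the centroid is used.)
* **Splines.** In-plane closed contours use periodic cubic splines;
  field lines and vertical interpolation use natural cubic splines.
  End conditions are not dictated by the construction; periodic is the
  only consistent choice for closed curves, and natural avoids
  extrapolation artifacts at the open tube ends. The last slice is
  always added to the key-slice set so vertical splines never
  extrapolate. Depth along a line is measured by arc length along its
  fitted spline (dense subdivision, 10 samples per segment), not by
  step count.
* **Equidistant resampling.** Closed-contour resampling iterates to a
  fixed point (≤ 20 passes, 1e-9 px tolerance) so that spacing is
  uniform on the *output* polygon, making normalisation idempotent.
* **Contour length.** `L_{h,c}` is the polygonal perimeter rounded to
  whole pixels — a property of the curve, not of the sampling density.
* **Opening and stretch.** The opening point is the dense sample with
  azimuth closest to π (ties to the lowest index); columns follow
  increasing azimuth (`--reverse` flips). The stretch resamples the
  closed loop to L equidistant points from the opening point; since
  L ≥ L_{h,c}, spacing only dilates, which preserves adjacency.
* **Probing.** Bilinear in-plane interpolation by default (nearest
  neighbour offered for label volumes); slice index is integral by
  construction. Out-of-bounds positions receive the fill value and are
  counted in the log. Bilinear probing of a constant volume is constant
  to float round-off (≈ 1e-16), exactly constant in nearest mode.
* **Inversion.** Source coordinates are stored at full float precision
  per panorama cell; the inverse maps each cell to
  `(h, round(y), round(x))`, optionally dilated to an axis-aligned cube
  clipped at the stack border. The non-injective stretch needs no
  global inversion.
* **Singularity guard.** Field evaluation within 1e-9 px of a charge
  raises; during tracing this marks the line stray.

## Open design points, resolved

* The start points of the inner and outer contour must be paired for
  the mapping to stay aligned; the rule used is nearest-Euclidean: the
  outer contour is rotated so its first point is the one closest to the
  inner contour's first point.
* How gaps from removed lines are bridged is under-determined; the
  per-level spline is fitted through the surviving points in cyclic
  order of original index, closing the loop across gaps.
* The variance filter's scope (all lines vs. stalled lines only) is
  under-determined; it is applied to every line after the K_max test.
* The charge-sign convention fixes line direction: inner boundary
  positive, so lines run inner → outer.
* Whether a line that wanders back into the lumen should be killed is
  under-determined; for closed annuli it keeps stepping (the field
  pushes it back out), while for open sheets leaving the region is
  terminal.

## Verification bench sizes

The acceptance bench runs, on one CPU in about a minute: the analytic
annulus at I = 200 (windowed w = 15 and near-full window w = 99 — the
2w+1 ≤ I constraint makes w = 99 the widest window for even I); the
deformed phantom at 512×512×61 with C = 6, m = 20; the marker phantom
at 400×400×61 with C = 5 and twelve markers; and the straight cylinder
at 256×256×31 with C = 5, m = 10.

## Known limitations

* The mapping is a proof-of-concept linear stretch: scale is not
  preserved, pixel sizes are anisotropic and non-uniform, so distances
  must not be measured on panoramas. Topology, however, is preserved.
  The per-column source spacing is exported as a diagnostic
  (`CycloramaVolume.column_spacing`).
* Isometric or moving-least-squares surface mappings would trade these
  deformations differently; they are extension points, not implemented.
* The method is slice-wise 2D by construction; strongly oblique tubes
  violate the per-slice annulus assumption.
* Open-sheet (C-shaped) support is experimental: tracing works on the
  sheet interior, but the panorama mapping assumes closed contours.
* With very few surviving lines (≥ 4 required) the internal contours
  degrade gracefully but are no longer locally accurate near the gaps.
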