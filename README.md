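# tubeunroll

Digital unrolling of deformed tubes of non-uniform thickness, imaged as
3D grey-value stacks (micro-CT, confocal, MRI, ...).

Many biological structures are roughly tubular — colonic mucosa with its
crypt pattern, tooth roots with annual cementum layers, the cortical
shaft of long bones — and the features of interest extend radially
through the wall. Physically flattening such samples (e.g. the
histological "Swiss roll") is destructive and distorts the very shapes
under study. `tubeunroll` instead unrolls the imaged volume digitally:
it reforms the tube wall into a family of nested, onion-like re-slicing
surfaces and maps each surface onto a planar panorama, producing a stack
of equal-sized images that sweep the wall from its inner to its outer
boundary, together with an exact cell-wise inverse mapping back to voxel
space (e.g. to seed a 3D segmentation in the original stack).

## Method

On every *m*-th slice the user-drawn inner and outer boundary contours
are resampled to *I* equidistant points. The wall is treated as a 2D
capacitor: unit positive point charges sit at the inner boundary points
`p_i`, charges of magnitude *rigidity* and negative sign at the outer
points `p'_i`. From each inner point a virtual electric field line is
grown in segments of length δ,

    p_{i,1} = p_{i,0} + δ · v_{i,1}/‖v_{i,1}‖                (boundary normal)
    p_{i,k} = p_{i,k-1} + δ · E(p_{i,k-1})/‖E(p_{i,k-1})‖    (k ≥ 2)

where the field sums the Coulomb kernels `q_j (p − p_j)/‖p − p_j‖³` of
the 2w+1 charge pairs in a sliding window centred on index *i*. Field
lines of a true electrostatic field never cross and meet both boundaries
perpendicularly, which makes the traced line a natural definition of the
local wall thickness `d_i` (its arc length, final segment clipped at the
outer boundary). Lines that fail to reach the outer boundary within
`K_max` steps (stray) or stall near their start with point-scatter
variance below `V_min` (collapsed) are discarded.

Each surviving line is re-represented as a cubic spline and sampled at
the absolute depths `c/(C−1) · d_i` for *C* relative depth levels
`c/(C−1) · 100 %` (0 % = inner boundary, 100 % = outer). A closed
periodic cubic spline through the samples of each level, resampled to
*I* points, gives the internal contours; vertical natural cubic splines
through corresponding points fill in the slices between key slices. The
contours of one level across all slices form one re-slicing surface.

Each contour is then opened at the point whose azimuth about a fixed
rotation axis *O* is closest to π, densely resampled to its own length
`L_{h,c}` in pixels, and linearly stretched to the reference length
`L = max L_{h,c}`. Probing the stack at all stretched positions yields
one L×H panorama per depth level; the C panoramas stack into the
unrolled volume. Every panorama cell retains the (x, y) position it
probed, so points marked on panoramas map back to voxels exactly to
rounding.

## Worked example

Generate a synthetic straight tube (inner radius 45 px, outer 105 px,
31 slices of 256×256) with its analytic boundary contours, unroll it,
then map a panorama seed point back into the stack:

```
$ tubeunroll phantom --preset concentric --out demo
wrote demo/stack.tif, contours.json, markers.csv

$ tubeunroll unroll --stack demo/stack.tif --contours demo/contours.json \
    --points 200 --window 15 --delta 2 --vmin 5 --interp-interval 10 \
    --depth-levels 5 --kmax 75 --out demo/cyclo.tif
INFO tubeunroll: slice 0: 200 complete, 0 stray, 0 collapsed field lines
INFO tubeunroll: slice 10: 200 complete, 0 stray, 0 collapsed field lines
INFO tubeunroll: slice 20: 200 complete, 0 stray, 0 collapsed field lines
INFO tubeunroll: slice 30: 200 complete, 0 stray, 0 collapsed field lines
INFO tubeunroll: wrote demo/cyclo.tif (+ sidecar, params)

$ echo '{"points": [[40, 15, 2]]}' > demo/seeds.json
$ tubeunroll invmap --sidecar demo/cyclo.map.npz --points demo/seeds.json \
    --cube 5 --out demo/mask.tif
```

All 200 field lines on each of the four key slices reach the outer
boundary (none stray or collapsed — the annulus is analytic and the
wall, 60 px, is far thicker than δ = 2 px). The resulting panorama stack
`cyclo.tif` has 5 pages of 31×660 pixels: 660 px is the rounded
perimeter 2π·105 of the outer boundary, the longest contour, and the 5
pages sample the wall at relative depths 0 %, 25 %, 50 %, 75 % and
100 %. The seed point at column 40, slice 15 on the 50 %-depth panorama
comes back as a 5×5×5-voxel cube (125 voxels) in `mask.tif`, which has
the input stack's dimensions and can initialise region growing in any
segmentation tool.

The same flags accept the parameter set documented for real micro-CT
colon data (`--points 200 --window 15 --delta 2 --vmin 50 --rigidity 1
--interp-interval 20 --depth-levels 30 --kmax 75 --origin 1080,780`).

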