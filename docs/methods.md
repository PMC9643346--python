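# Methods

`rcmorph` quantifies Rosenthal's canal (RC) — the helical bony channel in the
cochlear modiolus that houses the spiral-ganglion neuron somata — from
labelled 3-D volumes, and plans surgical access to it through the
round-window (RW) membrane.  Because the synchrotron phase-contrast volumes
that motivate this kind of analysis are not publicly available, the package
ships a parametric synthetic-anatomy generator with exact ground truth, so
every measurement stage is validated against known values.

## Synthetic anatomy

**Canal model.** The canal centerline is a conical helix about the modiolar
axis (+z by convention, millimetres throughout, right-handed frame, basal
end at cochlear angle 0°): radius interpolates linearly from
`helix_base_radius` to `helix_apical_radius` over `n_turns` turns, and the
pitch is recalibrated per specimen (Brent root-finding on the numerically
integrated arc length) so the centerline length equals the sampled
`target_length` to within 0.1 %.  Target lengths below the planar spiral arc
length are geometrically unattainable and rejected.

**Radius profile.** The canal radius along the centerline is a monotone
(PCHIP) interpolant through the half-diameters at the 0°/45°/90°/apex
cochlear-angle stations.  Station diameters are sampled from normals with the
published cohort's means and SDs (0.109/0.427/0.502 mm at base/45°/90°),
with monotone ordering enforced by rejection.  A consequence worth knowing:
a monotone profile through those station values implies a canal volume near
2.8 mm³, noticeably above the published per-bone volumes (mean 1.617 mm³) —
the printed diameters and volumes are not mutually consistent under any
monotone profile.  Volume recovery in this package is therefore validated
against the generator's exact voxel count, not against the printed volumes.

**Cohort distributions** (defaults; all configurable in
`GeneratorConfig` / YAML): canal length ~ Normal(14.568, 0.36058) truncated
to [13.5, 16] mm; bony cover thickness ~ Uniform(28, 56) µm; RW
membrane-to-canal depth ~ Uniform(3, 4) mm; dehiscent shell fraction ~
Uniform(0, 0.1); helix radii 1.6 → 0.7 mm and 1.8 turns (literature-typical
values — the source study reports none of these three); RW semi-axes
0.9 × 0.65 mm (also literature-typical, not from the study).

**Placement of the surgical scene.**  The RW membrane disc sits
`rw_depth_to_canal + r_base` from the basal canal point along an outward
in-plane normal, its center ~0.2 mm inferior to the basal canal, so the
canal lies deep to the superior-middle grid cells.  The vestibulocochlear
artery is a 0.1 mm-radius vessel crossing the B1/C1 trajectory corridor
1.0–1.8 mm below the membrane (present in a configurable fraction of
specimens, default all).  A stapedius blob occludes cell D1.  The scala
tympani is a 1.3 mm-radius fluid tube from the membrane to the basal canal,
clipped to the deep side of the membrane plane.  The central CSF nerve-exit
space is a cylinder about the modiolar axis sized to ≈15 mm³ before overlap
resolution.

**Voxelization.** Labels are assigned by signed-distance tests in a fixed
priority (canal > artery > membrane > perilymph > bony shell > bone >
background; the stapedius, absent from that order, sits above plain bone).
The canal distance field is computed coarse-to-fine: a stride-3
nearest-sample query upsampled everywhere, with exact polyline distances
recomputed in a band around the tube surface and the outer shell boundary,
where label decisions happen.  The bony shell is at least one voxel thick
regardless of spacing (a 28 µm shell cannot be thinner than an 18 µm voxel);
dehiscences are carved where a Gaussian-smoothed random field on the shell
exceeds the quantile matching `dehiscence_fraction`, so the carved fraction
is exact by construction.  Anatomy tubes end in hemispherical caps (the
ground-truth length is then exactly the curve length); debug phantoms use
flat end faces so that closed-form cylinder volumes hold.  Default spacing
is 18 µm for desk-scale memory; 9 µm matches the source detector pixel and
is available within the voxel budget guard.

Determinism: identical (seed, config, spacing) reproduce bit-identical
volumes; the dehiscence field derives from the specimen seed alone.

## Morphometry

**Centerline.** Largest 26-connected canal component, 1-voxel morphological
closing, 3-D thinning (Lee), conversion to a 26-adjacency graph, and the
longest geodesic path between endpoint nodes (side branches are
rasterization artifacts and get pruned).  Two corrections matter at tube
ends: thinning retracts the curve skeleton by about one radius at a *flat*
end face but not at a ball cap; the cap is classified by the mask
cross-section area just inside the end (a full disc means a flat face), and
flat ends are extended along the end tangent to the mask boundary while
ball-capped ends are extended only by any erosion beyond the cap center
(walk-to-exit distance minus the inscribed radius, usually zero).  The path
is then smoothed by a
moving average spanning a fixed 0.1 mm (at least 5 points) and resampled at
one voxel per step.  A point-count window was tried first and rejected: it
shrinks physically as spacing decreases, so finer grids did not converge.
The basal end is the end nearer the RW-membrane centroid (label 4), falling
back to the lower-z end.

**Modiolar axis.** The line minimizing the variance of point-to-axis radial
distance, initialized from the mean tangent (helix tangents lie on a cone
about the axis) and refined by Levenberg–Marquardt; requires ≥180° of total
turning.  Angular stations are unwrapped azimuths about this axis, zeroed at
the basal end.

**Diameter.** Twice the Euclidean distance transform at the voxel nearest
the centerline point (maximal inscribed sphere), averaged over a ±3-point
window, minus half a voxel: the transform measures to background voxel
*centers* (overshoot up to one voxel) while the discrete centerline sits up
to half a voxel off-axis (undershoot); the half-voxel diameter correction
was calibrated on the cylinder oracle and is within one voxel of truth
there.  At the tapering basal end the forward-only window biases the base
diameter up by 1–2 voxels; this is the least accurate station.

**Volumes** are exact voxel counts × spacing³.  **Shell assessment**: for
canal surface voxels, the distance through bone to the nearest exterior
voxel minus one voxel of center-to-center offset, minimized over the
surface; dehiscence is any canal voxel 6-adjacent to perilymph.

## Access planning

The membrane plane is the least-squares (PCA) plane through label-4 voxels,
normal oriented away from the perilymph centroid; the in-plane frame takes
superior as the projection of +z and anterior as `e_sup × n_out`.  The 4×4
dynamic grid divides the in-plane bounding box of the projected membrane
into equal cells, rows A–D superior→inferior, columns 1–4
anterior→posterior (a convention — the source figure only identifies A2/A3
as the superior mid-region).

Each cell center launches a capsule (trephine radius 0.2 mm default, depth
limit 4 mm from the reported 3–4 mm depth; both configurable) along the
inward plane normal, optionally tilted by polar/azimuth offsets.  The sweep
is sampled at half-voxel steps against linearly interpolated distance
fields; first contact with canal tissue within the limit is a hit at that
arc depth, artery contact at or before the stopping depth is a collision
(beyond-target collisions are ignored — drilling stops at target), and
cells whose centers lie within half a cell size of stapedius tissue are not
evaluable.  Cohort frequencies are hits over evaluable specimens; cells
never evaluable report "not applicable", never 0 %.  Selected cells must be
evaluable in every specimen, artery-safe, and at or above the threshold
(default 80 %).

## What the synthetic study does and does not show

Passing tests demonstrate that the measurement and planning pipeline
recovers known truth on geometry *like* the published cohort: right scale,
right taper, right membrane-canal relationship, one artery, one occluded
cell.  They do not validate against real segmentation noise, real membrane
shapes, per-specimen insertion angles, or the unpublished per-specimen hit
table — the published per-cell percentages (90 % at A2, etc.) depend on
those and are deliberately not targets; only the qualitative heat-map
structure (superior-half selection, anterior-column artery risk, D1 not
evaluable) and the 3–4 mm depth interval are.

## Problem sizes and tolerances

Defaults used by the test suite and the acceptance script: 10-specimen
cohorts at 18 µm spacing (about 30–60 M voxels per specimen), phantom
oracles at 20 µm.  Length oracles hold to 2 %, volumes to 3 %, diameters to
one voxel; cohort length recovery is within 2 % per specimen and station
diameters within two voxels at the median.  Degenerate inputs raise typed
errors: empty labels, cyclic skeletons, straight centerlines (no axis),
angles beyond the canal span, trajectory origins outside the volume,
inconsistent generator distributions (bounded rejection sampling).
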