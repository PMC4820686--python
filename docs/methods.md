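# Methods

`kidneyseg` implements a coarse-to-fine segmentation of the kidney from an
abdominal CT slice sequence. The difficulty it addresses is that kidney
parenchyma has nearly the same attenuation as adjacent organs (liver,
spleen), so purely intensity-based segmentation leaks across organ
boundaries. The method combines two stages: a per-slice *rough* pass based
on spatially constrained kernel fuzzy c-means (SKFCM) clustering inside a
propagated crop rectangle, and a *refined* pass that corrects
poorly-segmented slices with a GrowCut cellular automaton whose seed labels
are generated automatically from the contour of an adjacent,
well-segmented slice. The only manual input is one rectangle drawn around
the kidney on the slice with its largest cross-section; everything else —
crop propagation, quality gating, seed generation — is automatic.

## Preprocessing and intensity convention

All slices are rescaled once at load time to [0, 1] over the whole volume
(DICOM rescale slope/intercept applied first when present). Volume-wide
(not per-slice) normalization keeps SKFCM centroids and GrowCut feature
distances comparable across slices. Each slice is denoised with a 3×3
median filter (reflect-padded borders) before clustering; the median
preserves edges better than a mean filter at this window size.

## Rough segmentation (SKFCM)

SKFCM replaces the Euclidean distance of fuzzy c-means with the
kernel-induced distance `1 − K(x, v)`, `K(x, v) = exp(−(x−v)²/2σ²)`, and
adds a spatial penalty coupling each pixel to the mean intensity `x̄` of
its 8 neighbors:

    J_m = Σ_i Σ_k u_ik^m (1 − K(x_k, v_i)) + α Σ_i Σ_k u_ik^m (1 − K(x̄_k, v_i))

minimized by alternating the membership update

    u_ik ∝ [(1 − K(x_k, v_i)) + α (1 − K(x̄_k, v_i))]^(−1/(m−1))

(normalized over clusters `j = 1..c`; the denominator's summation index
runs over all clusters) and the centroid update

    v_i = Σ_k u_ik^m [K(x_k,v_i) x_k + α K(x̄_k,v_i) x̄_k] / Σ_k u_ik^m [K(x_k,v_i) + α K(x̄_k,v_i)]

with the kernel weights evaluated at the previous iterate. Iteration stops
when the infinity-norm centroid change drops below `eps`.

Parameter defaults and why:

| parameter | default | rationale |
|---|---|---|
| `c` (clusters) | 4 | a kidney crop contains four tissue modes: kidney, similar-intensity neighbor organ, muscle, background |
| `m` (fuzziness) | 2.0 | the standard FCM choice |
| `α` (spatial weight) | 1.0 | equal weight to intensity and neighborhood terms, the usual convention for this family |
| `σ` (kernel bandwidth) | 0.2 | of the order of inter-tissue contrast after [0,1] rescaling |
| `eps` | 1e-4 | centroid changes below 1e-4 are far below tissue contrast |
| `max_iter` | 200 | convergence is typically reached in 5–30 iterations |

Numerical choices: initialization is deterministic — `c` evenly spaced
intensity quantiles `(i+0.5)/c` of the crop — so runs are bit-reproducible
with no dependence on a random state. Membership ratios are computed as
`(D_min/D_i)^p`, which cannot overflow for tiny distances. A pixel whose
distance to some centroid is exactly zero gets crisp membership on that
centroid (split equally over ties). An emptied cluster (zero centroid
denominator) is re-seeded from the pixel with the lowest maximum
membership. Centroids are sorted ascending on return so cluster indices
are reproducible; hard labels are argmax memberships with ties going to
the lowest index.

The rough pass per slice is: median filter → crop → SKFCM → keep the
modal (maximum-pixel) cluster, count ties broken toward the brighter
centroid → keep its largest connected component (8-connectivity; area
ties go to the component whose top-left-most pixel comes first) → fill
interior holes (background regions not 4-connected to the border — these
are vessels the clustering rejects) → smooth the contour by morphological
opening then closing with a disk of radius 2 → compute the mask's minimum
bounding rectangle extended by 10 px, clamped to the frame. The extended
rectangle crops the adjacent slice. Propagation runs in both directions
from the seed slice, since the largest cross-section sits mid-kidney; a
slice whose candidate is empty after smoothing is a flagged failure that
reuses the previous rectangle, and a direction stops after 2 consecutive
failures.

A caveat inherited from the modal-cluster rule: it assumes the kidney
dominates its crop. The initial rectangle should therefore be as tight as
possible; a loose crop can make background the modal cluster.

## Quality gate

Roughly half of real slices need no refinement, so refinement is gated. A
slice is flagged when, compared with its neighbor toward the seed slice,
its mask area changes by more than 10%, or when its solidity (area /
convex-hull area) drops below 0.85 — both symptoms of leakage into a
neighboring organ or a lost pole. The seed slice itself (manual rectangle)
is never flagged unless its rough pass failed outright.

## Refined segmentation (auto-seeded GrowCut)

GrowCut treats the crop as a cellular automaton. Each cell carries a label
`l ∈ {−1, 0, +1}` (background / unlabeled / foreground), a strength
`θ ∈ [0, 1]`, and a feature `C` (the intensity). Seeded cells start at
`θ = 1`, all others at `(l, θ) = (0, 0)`. At each synchronous step every
neighbor `q` attacks cell `p` with force

    g(‖C_p − C_q‖) · θ_q,   g(d) = 1 − d / max‖C‖

and `p` adopts `q`'s label and the attack force as its new strength when
the force strictly exceeds `θ_p`. `max‖C‖ = 1` because intensities are
normalized to [0, 1]. Updates are synchronous (all reads from the time-t
grid); among winning attackers the strongest wins, with exact ties broken
by a fixed row-major neighbor scan order — both choices are required for
determinism and for exact agreement with a naive reference implementation.
The Moore (8-connected) neighborhood is the default. Iteration stops when
no cell changes; every change strictly raises a strength in a bounded
lattice, and termination within the 500-step cap holds on all fixtures.

Seeds are generated from the template mask (the rough mask of the nearest
unflagged slice, searching toward the seed slice first) as follows. The
template's outer boundary is traced (Moore-neighbor tracing, clockwise
from the top-left-most pixel). For each contour point the local altitude
difference `d_y = |row(i+step) − row(i−step)|` (cyclic indexing) measures
whether the contour runs horizontally there. If `d_y < T_h` the
foreground seed is placed `T_1` px vertically on the interior side and the
background seed `T_2` px vertically on the exterior side; otherwise the
offsets are horizontal. The interior side is decided by testing which
candidate lies inside the template — robust to concave contours — and
candidates that are out of bounds or on the wrong side are discarded
(foreground wins pixel collisions in thin sections). Defaults
`T_h = 1, T_1 = T_2 = 3` px: the offsets must exceed the contour drift
between 0.5–1 mm-spaced slices yet stay inside thin kidney sections.

A geometric note: because offsets are axis-aligned, seeds near contour
angles where the rasterized chain switches staircase direction can land
closer to the boundary than `T_1` (the offset is nearly tangential there).
The guaranteed invariants are strict interior/exterior placement and a
typical depth near the offset distance, and these are what the tests
assert.

The CA runs on the template's extended bounding rectangle, not the full
512×512 slice, mirroring the crop propagation and bounding runtime. If the
template itself has satellite fragments (contour smoothing can split a
mask), its largest component is used as the kidney contour.

## Post-processing

Final masks are smoothed by morphological closing with a disk of radius 1.
Closing is extensive (never erodes thin kidney poles) and idempotent. The
underlying operations named for this stage are dilation and erosion; the
extensive composite is this package's choice.

## Evaluation metrics

From pixel confusion counts against a manual mask:
`accuracy = (TP+TN)/total`, `overlap = TP/(TP+FP+FN)` (Jaccard),
`sensitivity = TP/(TP+FN)`, `specificity = TN/(TN+FP)`. Conventions for
empty denominators: sensitivity 1 when the truth is empty, specificity 1
when the truth covers everything, overlap 1 when both masks are empty.
Both pooled (counts summed over slices) and per-slice-averaged
aggregations are reported, since they differ when slice areas vary.

## The synthetic phantom

No patient data ships with the package; every test runs on a generated
phantom. Each of the 20 slices (128×128, spacing metadata 0.68/0.68/0.5 mm)
contains a bright convex kidney ellipse (intensity 0.62) abutting a larger
neighbor organ at 0.58 — within-soft-tissue contrast, the kidney/liver
confound — plus a darker muscle-like structure at 0.45 (the psoas, in real
anatomy) and background at 0.25, corrupted by additive Gaussian noise
(sd 0.03) and a low-frequency multiplicative field (amplitude 0.03; CT
bias fields are mild). Four tissue intensities appear in a kidney crop by
construction, matching the four-cluster operating point: with only three
tissues, c = 4 clustering necessarily splits the kidney mode and the
modal-cluster rule fails — real crops always contain a fourth class. The
kidney cross-section peaks mid-stack and shrinks by 5% toward the stack
ends: 20 slices at 0.5 mm spacing span about 1 cm around the equator of a
~10 cm kidney, over which the area genuinely changes only a few percent.
The center drifts by well under a pixel per slice, so adjacent ground-truth
masks overlap with Jaccard ≥ 0.8 — the spatial continuity the automatic
seeding relies on.

What the phantom does **not** emulate: anatomical shape (kidneys are not
ellipses), internal texture (collecting system, vessels), ribs and bowel
gas, Hounsfield calibration, partial-volume effects, or streak artifacts.
Passing the phantom tests therefore demonstrates the algorithmic contracts
(convergence, determinism, seed validity, recovery of a known target under
the stated noise), not clinical-grade performance on patient CT.

## Problem sizes

The test suite and the reproduction script run at desk scale: 20-slice
128×128 phantoms for end-to-end checks, 8×8–12×12 instances for the exact
CA-versus-reference comparisons (50 random instances), 100 random blob
templates for seed-validity checks, and 10 random restarts of the
four-component intensity-mixture recovery. A full phantom pipeline run
takes well under a minute on one CPU.

## Known limitations

* The modal-cluster assumption fails for loose crops (documented above).
* The quality gate's thresholds (10% area change, 0.85 solidity) are
  heuristics; on real data they would deserve tuning against a labeled set.
* Refinement inherits template errors: if every neighbor of a flagged
  slice is itself flagged, the slice keeps its rough mask.
* Only binary (kidney / not-kidney) labeling; no multi-organ CA.
* The stack is processed slice-wise; no 3-D regularization across slices
  beyond crop propagation and template seeding.
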