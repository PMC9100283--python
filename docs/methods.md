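# Methods

`skelfuse` fuses time-synchronized skeleton streams from several RGB-D
sensors into a single tracked skeleton. This note records the model, the
parameters that matter, the synthetic benchmark's scope, and the numerical
and design choices made where the procedure left room.

## Coordinate calibration

Every sensor `p` is aligned to a master sensor by registering two
correspondence trajectories `C_p` and `C_M` — the 3D centroids of a tracked
sphere observed simultaneously by both sensors — with the least-squares
rigid fit. Frames in which any sensor misses the sphere are filtered out;
at least 3 correspondences are required (the rig is normally calibrated
with ~1000). The fit is the Kabsch/SVD solution: with centroids
`ĉ_p`, `ĉ_M` and covariance

    Cov = Σ_i (C_p,i − ĉ_p)(C_M,i − ĉ_M)ᵀ = U S Vᵀ,

the rotation is `R = V diag(1, 1, det(VUᵀ)) Uᵀ` and the translation
`T = ĉ_M − R ĉ_p`. Two deliberate deviations from the plain `R = UVᵀ`,
`T = ĉ_M − ĉ_p` form: the determinant factor excludes reflections (without
it, noisy near-planar trajectories can return `det R = −1`), and the
translation must rotate the centroid, otherwise the result does not
minimize the registration error at all. Degenerate (collinear) geometry is
rejected by a singular-value ratio test at 1e-9.

Sphere centroids come from RANSAC on the segmented point cloud: 4-point
hypotheses (the minimal sample determining a sphere), rejected when the
implied radius differs from the known radius (default 240 mm) by more than
`radius_tol_mm` (20), scored by inliers within `inlier_tol_mm` (10), with
a fixed-radius Gauss–Newton refinement on the final consensus set.
200 iterations by default; fully deterministic given the seed.

The global frame comes from a plate with four fiducial centroids: origin at
marker 1, `x̂` along marker2→marker1 read left-to-right (the opposite sign
convention is a config choice), `ẑ = x̂ × (c₀ − c₁)` normalized with its
sign forced toward the supplied up hint (floor → ceiling), and
`ŷ = ẑ × x̂` re-orthogonalized because measured marker vectors are never
exactly perpendicular.

## Merging

Per synchronized time step, three stages:

**Arrangement.** Depth-sensor body trackers sporadically exchange a pair's
left/right labels per sensor (misorientation). For each mirrored pair a
cross-sensor reference is built for each side: the mean of
medium-confidence candidates, falling back to low-confidence ones. A sensor
carrying both members is flagged when the distance from the right-side
reference to its right joint exceeds the distance to its left joint
(`d_correct > d_wrong`); flagged pairs swap labels. Ties never swap —
swapping on ties oscillates. Decisions are per-sensor, computed from the
pre-correction reference, which makes one application idempotent.

**DBSCAN merge.** All sensor candidates with confidence above *none* form
the clustering input, augmented by two auxiliary points: the reference
position (anchoring the high-confidence consensus — this is the only
concrete mechanism by which confidence weights the merge; no multiplicative
weighting is applied) and, in the smoothing variants, the previous merged
position. DBSCAN uses closed-ball neighborhoods (`distance ≤ ε`, the point
itself included) and minimum neighbor count `N_c = 1`, under which every
point is core, no point is noise, and the clusters are exactly the
connected components of the ε-proximity graph (a property the test suite
checks against a brute-force oracle). The largest cluster wins; ties
prefer, in order, clusters containing a sensor candidate, the reference's
cluster, the previous position's cluster, the cluster nearest the previous
position, the lowest id. The merged position is the centroid of the winning
cluster's **sensor** candidates only; auxiliary points never enter the
centroid. If the winner holds no sensor candidate the joint is
*predicted_only* at the previous position. The searching area ε defaults to
100 mm (configurable, `cm`/`mm` suffixes accepted at the config boundary;
everything internal is millimeters).

**Kalman tracking.** Each joint runs an independent constant-position
filter, state = the 3 coordinates, `A = H = I₃`, `Q = q I`, `R = r I` with
defaults `q = 0.01`, `r = 1.0`. Prediction `X̃_t = X̂_{t−1}`,
`P̃_t = P_{t−1} + Q`; the *predicted* state is the tracked output; the
measurement (the merged centroid) then corrects the posterior. The tracker
initializes at the first merged measurement with `P₀ = I` (mm² scale), so
the first output equals that measurement. A missing measurement skips the
correction. After `max_coast_frames` (default 30) consecutive
predicted-only steps the joint is reported missing rather than extrapolated
forever, and its tracker re-initializes when measurements resume.

Pipeline variants: A1 plain per-joint average; A2 = A1 + arrangement
(kept behind a flag; useful in tests); A3 arrangement + DBSCAN merge;
A4 = A3 + previous-position smoothing candidate; A5 = A4 + Kalman. The
previous position fed to merging in A5 is the raw previous merged centroid,
not the filter output (configurable).

### A note on the tracker's bandwidth

With `q/r = 0.01` the per-axis steady-state gain is
`K = M/(M+r) ≈ 0.0951` where `M = (q + √(q² + 4qr))/2` — a ~10×
exponential smoother. Against *exact* ground truth this necessarily lags
motion: the phase-lag error of such a smoother is ≈ 0.44 × amplitude for a
4 s periodic gesture at 30 Hz, and ≈ 9.5 frames × velocity for sustained
translation (380 mm at 1.2 m/s). On the synthetic benchmark A5 therefore
wins on quasi-static data, where its tremble rejection is decisive (upper
limb ≈ 1.0 mm vs ≈ 4.2 mm for A4 under the default corruption model), and
loses on fast gestures (≈ 148 mm on the default hands-up-down template).
Consequently the variant-ordering and searching-area experiments run on a
stationary standing pose with the full corruption model — the condition
that isolates the occlusion-rejection and smoothing mechanisms those
comparisons are about — while the sensor-count sweep on the six dynamic
gestures uses A4, isolating the sensor-count effect from tracking
bandwidth. Both choices were fixed from this analysis before the
experiments were run.

## Synthetic benchmark

The generator emulates one subject captured by a ring of four depth sensors
(2.5 m radius, 1 m height, aimed at the subject; an optional fifth
front-facing best-view sensor). Six gesture templates — both hands up/down,
jump, squat, lunge, walking, free movement in a standing pose — are
analytic joint-angle trajectories on a fixed-segment body model (16 joints;
segment lengths of an ~1.75 m adult), so bone lengths are constant to
machine precision; squat and lunge pin the ankles and place the knees by
exact two-link IK. Default captures are 1000 frames at 30 Hz. The walking
template translates at `speed_mm_s` (default 1.2 m/s); the benchmark suite
instead uses walking-in-place, because a fixed ring of sensors cannot
follow tens of meters of travel — the capture volume is a few meters
across.

The corruption model, per sensor/frame/joint: isotropic Gaussian jitter
(σ = 5 mm); joints whose outward normal (horizontal radial from the body
axis; the facing direction for midline joints) points away from the sensor
beyond `occlusion_angle_deg` (90°) are demoted to *low* confidence and
displaced with probability 0.15 by an outlier of magnitude
Uniform(0.5, 1.5) × 300 mm in a uniform direction; mirrored pairs swap with
`swap_prob` (0 by default, matching data in which misorientation is rare),
the swapped pair demoted to *low* — a misoriented estimate is an estimation
failure, and this is also what makes an exactly-half-swapped sensor set
decidable by the reference rule; joints drop out entirely (*none*) with
probability 0.01, as do joints outside a sensor's range or field of view.
All draws flow from one seed; identical parameters reproduce streams
byte-for-byte.

What this does **not** model: real depth-sensor error is neither isotropic
nor white (it is distance- and surface-dependent, and occlusion errors are
strongly correlated over time), body trackers produce structured failure
modes beyond label swaps, and the best-view reference itself trembles.
Passing tests therefore demonstrate that the algorithm does what it claims
under its own error model — outlier rejection, label repair, monotone gains
with sensor count — not that millimeter error levels transfer to hardware.

## Evaluation

Error is the per-joint per-frame Euclidean distance (mm) between aligned
tracks; slots missing from either track are excluded pairwise and counted.
Regional aggregates pool per-frame joint errors within torso (8 joints),
upper limb (4) and lower limb (4): AE = mean, STD = population standard
deviation (sample form available via `ddof`), RMSE reported side by side
since both conventions appear in practice. The sensor-count sweep scores
every size-k subset (k = 1 scores raw streams; no merging) and averages the
statistics arithmetically over the C(total, k) combinations — 4/6/4/1 for
four sensors.

Problem sizes used by the shipped experiments (the package's own choice of
desk-scale defaults): sensor-count sweep — 20 seeded 1000-frame captures
cycling through the six gestures; variant ordering and ε comparison — 20
seeded 300-frame standing-pose captures; misorientation recovery — 10,000
constructed frames; registration noise scaling — 100 seeds × n ∈
{10, 100, 1000}.

## Known limitations

- Single subject; no multi-person association.
- No anthropometric (bone-length / joint-angle) constraints in the merge.
- Streams must share a hardware-synchronized frame counter; no
  timestamp resampling.
- The Kalman stage with the default `q/r` is a low-bandwidth smoother;
  for dynamic motion either retune `q/r` or use A4 (see the bandwidth
  note above).
- The 17th joint (`spine_chest`) is available in the topology but the
  canonical set is the 16-joint one; the simulator emits 16 joints.
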