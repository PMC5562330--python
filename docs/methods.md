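# Methods

## Input model and conventions

The detector operates on a stack of 2D frames of instantaneous [Ca] in the
submembrane voxel layer of a pacemaker cell: μM per voxel, cubic voxels
(default edge 100 nm), fixed frame interval (default 5 ms). Coordinates are
0-based (row, col) with row 0 at the top; frame *k* lies at time *k*·Δt from
the start of the stack. Loaders never rescale or auto-detect units; the
calibration (Δt, voxel edge) only scales derived metrics, never stored
intensities. Because the cell perimeter is topologically a ring, the column
dimension can optionally wrap (`periodic_x`); the default is off, since a
recording need not span the full perimeter.

## Segmentation

Each frame is thresholded adaptively. With mean *m* and maximum *M* over the
frame, the increment is Δ = (M − m)/n_bins and bin *i* (0-based) is the
Boolean mask [Ca] > m + Δ·i. The inequality is strict at every level,
including the mean level, so voxels exactly at the mean belong to
background. Masks are nested by construction. LCR images are the connected
components of the lowest mask; peaks are local maxima of [Ca] restricted to
the component.

Numerical choices:

* **Cluster connectivity is 4** (edge-sharing): a shared border is an edge,
  not a corner. **Peak neighbourhood is 8**, so diagonal neighbours suppress
  spurious twin peaks on discrete grids. Both are configurable.
* **Plateaus.** A connected set of equal-valued voxels none of whose
  in-region neighbours is higher counts as a single peak, represented by its
  smallest (row, col) voxel. This prevents double-counting on quantized
  data and guarantees ≥ 1 peak per non-empty region.
* **Degenerate frames.** A uniform frame has M = m, hence Δ = 0 and no
  supra-mean voxels; it yields zero LCR images rather than an error. In
  floating point, the mean of thousands of identical values can differ from
  the value by an ULP, which would otherwise turn a blank frame into one
  frame-sized "release"; a frame whose span M − m is below 10⁻¹² of the
  frame scale is therefore treated as exactly degenerate (empty masks). Any
  real contrast is many orders of magnitude above this.
* **Per-frame adaptivity.** Mean and Δ are recomputed each frame, so
  segmentation levels drift with the global Ca transient. This is a
  property of the method and is documented, not corrected: during a fast
  transient decay the background falls and small events become separable.
* No smoothing, denoising or detrending is applied; the intended input is
  noise-free reaction–diffusion simulation output. On noisy experimental
  data a pre-filtering step would be the user's responsibility.

Signal mass of an image is Σ [Ca]·10³ (μM → nmol/L) × V_voxel, with
V_voxel = (edge·10⁻⁹ m)³·10³ L/m³; 100 nm gives 10⁻¹⁸ L, so one voxel at
1 μM holds 10⁻¹⁵ nmol.

## Tracking

Images of consecutive frames pair when their lowest-bin footprints
intersect. Per frame, events are resolved in a fixed order: collisions,
then assignments/separations, then attrition. Decisions a practitioner
should know about:

* **Collision comparator.** When one current image is claimed by several
  tracks, the survivor is the track whose *previous-frame image* has the
  largest signal mass — not cumulative track mass. Ties go to the older
  track (smaller id), keeping the algorithm deterministic. Multi-way
  collisions (≥ 3 tracks) keep a single survivor by the same rule.
* **Collision priority.** A terminated track's pairs are deleted before
  separation processing. Consequently, if a track would simultaneously
  separate and lose a collision, no separation is recorded and any current
  image orphaned by the deletion starts a new track.
* **Threads.** A separation keeps all current images in the same track and
  opens new threads; the thread whose tip was the separating image
  continues with the smallest-id current image. A track dies only when all
  threads have ended. Two threads of the *same* track converging on one
  image is an intra-track merge (thread count decreases), not a collision —
  the collision rule concerns distinct LCRs.
* **Window-start births.** Images in the first analyzed frame start tracks
  with birth time 0; they are pre-existing releases adopted as new, and the
  summary can exclude them from birth-time statistics (default on).
* Tracking is exactly the overlap rule: no gap closing, no cost-matrix
  assignment, no randomness. Identical input and configuration give
  identical event logs, which the tests assert byte-for-byte through the
  CLI.

## Metrics

Duration counts frames inclusively: (last − birth + 1)·Δt, so a
single-frame event lasts one frame interval rather than 0 ms — ensemble
mean durations of short-lived simple events would otherwise collapse to 0.
Path area uses the union (not the sum) of per-frame footprints, so a static
event's area is duration-independent. "Total complex collisions" counts
collision events whose *surviving* track is classified complex at
finalization; a variant counting either participant is available
(`complex_collision_rule="either"`), since the definition is genuinely
ambiguous. Histogram defaults: birth-time bin width 25 ms; signal-mass bins
log-spaced at four per decade. Both are configurable; no canonical binning
exists for these distributions.

## Window selection

The MDP is located as the minimum Vm within the selected cycle (ties → the
earliest sample); in multi-cycle traces, cycles are delimited by
action-potential peaks (local maxima above 0 mV) and the caller picks a
cycle index. The window end is the first upward crossing of the threshold
(default −50 mV) after the MDP, linearly interpolated between samples and
rounded to the frame grid. A trace that never crosses the threshold after
the MDP is an error, as is a window that falls outside the stack.

## Synthetic scenarios

The generator renders isotropic Gaussian blobs, frame(t) = B(t) +
Σ A·exp(−d²/2σ²) (+ optional Gaussian noise), over a uniform background
B(t) = B_rest + (B₀ − B_rest)·e^(−t/τ) emulating the tail of the
action-potential-induced Ca transient. Defaults: B_rest = 0.09 μM (resting
Ca below 0.1 μM), B₀ = 0.5 μM, τ = 150 ms — a plausible diastolic decay; a
faster pump corresponds to a smaller τ. Population events default to
amplitudes 2–5 μM, widths σ = 1.5–3 voxels, durations 4–12 frames
(20–60 ms), spanning the small-simple to moderate-complex range of release
events. Noise defaults to zero because the target data (simulation output)
is noise-free.

The generator reproduces the *statistical appearance* of local releases —
blob-like footprints that appear, move, merge, separate and vanish — not
their physics: there is no release-channel gating, no SR depletion, no
diffusion coupling, and blobs are exactly Gaussian. Passing the
ground-truth tests therefore demonstrates that the detector and tracker
recover what the segmentation definitions say they should recover on clean
blob-like events; it does not validate behaviour on instrument noise,
motion artifacts, or point-spread blurring, which real recordings add.

Placement in the population scenario is rejection sampling: events whose
lifetimes overlap (± 1 frame) keep ≥ 20 voxels between centres, which at
the default amplitude/width ranges keeps supra-mean footprints disjoint
(footprint radii are ≈ 5–8 voxels), making scripted births/deaths exactly
recoverable. Merge and split scenarios move two blobs together or apart on
a constant background; amplitudes are unequal in the merge so the intended
survivor is unambiguous.

## Problem sizes

The validation suites use frame sizes up to 64×64 and stacks up to 200
frames with 30 events — large enough that all interaction topologies
(birth, attrition, collision, separation, thread death, window-start
adoption) occur, while the whole test suite and the acceptance script each
run in seconds.

## Known limitations

* The adaptive per-frame threshold makes detections across frames
  level-inconsistent during fast global transients (by design, following
  the per-frame definitions).
* Sub-voxel localization, gap closing across dropped frames, and
  noise-robust segmentation are out of scope.
* The collision comparator uses only the previous frame's image masses;
  a long-lived large LCR can lose to a momentarily larger newcomer.
* `periodic_x` wraps columns only; a recording spanning the full perimeter
  in both dimensions (a closed surface) is not modelled.
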