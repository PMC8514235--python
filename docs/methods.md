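# Methods

This note documents the models behind each module, the defaults that matter,
what the synthetic generators do and do not emulate, and the numerical
choices made where the design was genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Conventions

Micrometres for space, seconds for time, Hz for rates, cells/mm² for
densities, pA and pC for currents and charge. Angles are degrees at every
interface and radians only inside trigonometric kernels. Stimulus epochs are
labeled half-open intervals `[onset, offset)` on the trace's own clock; the
single exception is charge integration (below). Image rasters use a top-left
origin with y downward; the similarity transform itself is ordinary y-up
mathematical geometry, and the conversion is confined to the rasterization
path and pinned by tests.

## Mosaic statistics

The density recovery profile (DRP) counts, for every reference cell,
neighbors in half-open annuli `[kΔ, (k+1)Δ)` and divides by the annulus area
`π((k+1)²−k²)Δ²`, averaging over reference cells. Δ defaults to 15 µm, with
25 µm appropriate for sparse types; a distance exactly on an annulus edge
goes deterministically to the upper annulus; self-pairs are excluded by
index, so coincident somas are still counted as neighbors of each other.

Edge handling is explicit because it is quantitatively decisive. With every
cell as a reference and no window compensation, annuli overhang the field
border and the profile underestimates density by roughly `4r/(π·side)` for a
square field — about 6% at r = 45 µm and 13% at r = 100 µm on a 1 mm field,
far larger than the Monte-Carlo error of a few hundred replicate fields.
`edge_correction="none"` (the default) reproduces that uncorrected estimator
and its bias is asserted in the tests as a documented limitation;
`edge_correction="border"` restricts the reference set to cells at least
`max_radius` from every border, whose annuli are complete, making the
estimator unbiased (for a homogeneous Poisson process, conditioning on a
reference cell leaves the remaining points Poisson, so each annulus's
expected density is exactly the intensity). Convergence checks and the
acceptance script use the border option.

The 4-parameter logistic fit (`floor + (ceiling−floor)/(1+exp(−(r−m)/s))`)
is for display only: no inference is drawn from its parameters, constant
profiles short-circuit to `floor = ceiling` with zero residual, and
non-convergence is reported via a flag rather than raised.

## Registration

The transform family is similarity (rotation, isotropic scale, translation),
solved in closed form by the SVD (Umeyama) least-squares construction, with
the RMS landmark residual reported so users can judge whether the family is
adequate for their tissue; no affine shear or nonrigid warp is fitted, and
no automatic vessel segmentation is attempted — landmarks are supplied as
paired coordinates. Stitching snaps stage offsets to the nearest whole pixel,
averages overlapping pixels and marks uncovered canvas as NaN. ROI
rasterization uses the pixel-center-in-polygon rule (a pixel belongs to the
ROI iff its center lies inside), which is deterministic and makes
whole-pixel translations preserve mask pixel counts. ROIs whose transformed
footprint covers no target pixel are excluded and reported, not raised.

## Calcium-response indices

z-scoring uses each trial's own baseline epoch mean and SD, so a flat
(zero-variance) baseline is an error rather than silently producing infs.
Per-direction responses take the **trial-average first, then the maximum**
within the direction's bar epoch; the alternative (per-trial maxima averaged)
is biased upward by noise, and the average-then-max convention is the one
the rest of the package assumes. Responses are rectified at zero before any
index so DSI, OSI and the ON-OFF index stay in their nominal ranges; the
index formulas implicitly assume non-negative responses.

DSI/OSI are the first/second circular harmonics of the tuning curve
normalized by its sum; both are scale-invariant and equivariant under
rotation of the curve, and the implementation is checked against a
brute-force complex summation oracle to 1e−12. Preferred angles are wrapped
into [0, 360) / [0, 180); a floating-point argument a hair below zero that
wraps to exactly the period is canonicalized to 0.

The quality index is the variance over time of the trial-averaged trace
divided by the trial average of per-trial variances: 1 for perfectly
repeatable responses, ≈ 1/n_trials for independent noise. The conventional
responsiveness threshold of 0.45 is a configurable default, not a measured
constant. Group templates for cosine-similarity assignment are built by
normalizing each member trace, averaging, and re-normalizing, which makes
the score a pure shape comparison; assignment ties go to the lowest group
index and the full trace × group similarity matrix is returned.

## Electrophysiology

Spike detection thresholds local maxima at
`median + k · 1.4826 · MAD` (k defaults to 5) of the baseline — the whole
trace when no baseline epoch is named — which makes detection exactly
invariant to constant offsets. Within a refractory window (default 2 ms) the
earliest peak wins; this is a deliberate contract (one action potential, one
peak) and differs from amplitude-priority peak pickers. PSTHs divide
per-trial counts per 50 ms bin by the bin width and average over trials, so
`Σ rates · bin_width · n_trials` reproduces the total spike count exactly.

Charge integration subtracts the **median** of the pre-stimulus window
(robust to spontaneous events), then integrates trapezoidally over the
stimulus epoch. The epoch is treated as **closed** `[onset, offset]` so that
a constant step integrates to exactly amplitude × duration; with the
half-open convention the final sample interval would be dropped and a 10 pA
× 0.5 s step would integrate to slightly under 5 pC. The peak is the signed
extremum of the baseline-subtracted current. Per-cell orientation curves of
charge are divided by a control reference (the average maximum in control
cells), circularly shifted so each cell's maximum sits at the center grid
index (ties to the earliest orientation), and averaged element-wise; the
shift is a pure rotation, so each cell's multiset of values is preserved.
The response window for tuning from spikes defaults to the full stimulus
epoch and is configurable.

## Morphometry

Arbors are rooted trees; SWC reading rejects cycles, multiple roots and
dangling parents with line numbers, and collapses multi-sample somas
(type-1 nodes attached to the root) to their centroid. Total length is the
sum of parent→child edge lengths and equals the sum of per-segment lengths
(segments are maximal unbranched paths between root, branch points — nodes
with ≥ 2 children — and terminals); this partition identity is a standing
test. Hull area is computed on the x-y (en-face) projection, matching
whole-mount measurements, and returned in µm²; degenerate projections give
0 with a warning.

Sholl analysis uses 3-D distance from the soma: flat-mount arbors are
quasi-planar so 2-D and 3-D counts rarely differ, and 3-D is the more
general choice. Each edge is split at its point of closest approach to the
center so distance varies monotonically on each piece; a piece crosses the
shell of radius r iff `d_near < r ≤ d_far`, so an edge that dips into a
shell and re-emerges counts twice. Radii run from one step up to, but
excluding, the maximal node distance (a shell exactly through the farthest
tip is not counted); the step defaults to 10 µm. The implementation is
checked bin-for-bin against a dense-resampling oracle.

IPL depth profiles normalize each linescan channel to its maximum, map the
scan onto 0–100% depth (0% at the inner nuclear layer border, increasing
toward the ganglion-cell layer — stated explicitly because "percent depth"
alone does not fix a polarity), and report the two largest reference-channel
peaks as the cholinergic band depths.

## Synthetic data: what it emulates, and what it does not

The generators define the conditions under which the pipeline is validated.

*Mosaics* use random sequential adsorption: a Poisson-drawn target count,
uniform darts, rejection inside the exclusion radius, and at most 10⁴
attempts per point before a packing-infeasibility error. This reproduces the
exclusion-zone phenomenology the DRP detects, not the full spectrum of real
mosaic regularity (no pairwise interaction potentials, no density gradients
across the retina).

*Trial traces* drive a cell with `on_amplitude · vonMises(θ; preferred, κ)`
during each direction's leading-edge epoch, the `off_amplitude` analog
during the trailing-edge epoch, and the plain amplitudes during full-field
flashes, convolve with a single-exponential kernel (`exp(−t/τ)`, τ default
0.2 s, unit peak, support truncated at 5τ) and add i.i.d. Gaussian noise per
frame. The default protocol uses eight directions, a 1200 × 3200 µm bar at
240 µm/s (a 960 µm/s fast variant is a parameter), a 360 µm field, 2 s
baseline and full-field epochs, 8 Hz sampling, and 5 trials — trial count is
a convention of this package, not a measured value. Epoch bookkeeping
derives the bar-crossing time as `(bar_length + field_width)/speed` and each
edge's passage as `field_width/speed`; a 1 s background gap (≥ the kernel
support) separates stimulus epochs so indicator decay from one epoch cannot
leak into the next, which keeps the noiseless closed-loop identities exact
(e.g. a cell with no OFF drive has an ON-OFF index of exactly 1). Not
modeled, deliberately: photon shot noise, indicator nonlinearity and
saturation, optics/PSF, neuropil contamination. Passing recovery tests
therefore demonstrates the estimators, not robustness to every artifact of
real movies.

*Landmark fields* apply a known similarity transform plus per-coordinate
Gaussian jitter to uniformly placed points. *Spike trains* are inhomogeneous
Poisson by thinning against a bound taken from a dense grid (no refractory
structure or bursting). *Arbors* grow an initial path from the soma and
attach a fresh path at a randomly chosen pass-through node per branch event,
with Exp-distributed step lengths, smoothly drifting directions and a
flattened z axis; the generator records total length, branch-point and
terminal counts, giving exact bookkeeping identities for the morphometry.
*Currents* are piecewise-constant epochs over a baseline plus Gaussian
noise.

In the grouping benchmark, "noise at 0.2× the signal norm" is implemented as
per-sample Gaussian noise scaled so the expected noise-vector norm is 0.2
times the (unit) template norm.

## Problem sizes

Validation workloads are sized to make the statistical assertions sharp while
keeping the whole suite interactive: 1,000 random tuning curves for oracle
equivalence; 200 replicate 1 mm² CSR fields at 100 cells/mm² (and five
hard-core fields) for the DRP; 1,000 random noiseless transforms plus 100
jittered 50-landmark fields for registration; 200 simulated cells (κ = 3,
amplitude/noise = 10, 5 trials) for direction recovery and 100 replicate
20-trace mixtures for grouping; 100 × 10 s Poisson trains for the PSTH; three
generated arbors plus the hand-built fixtures for morphometry. The full test
suite and the acceptance script each run in seconds on one CPU.

## Known limitations

No edge-corrected DRP beyond the border method; no nearest-neighbor
regularity index or Ripley's K. Similarity-only registration (no affine or
moving-least-squares warps). No spike inference from calcium and no
receptive-field mapping. Sholl assumes straight edges between traced nodes —
the dense-resampling oracle shares that assumption. The pipeline stages are
simulation-backed reference implementations of the analysis path; applying
them to real data means supplying the CSV/TIFF/SWC inputs those stages
otherwise generate.
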