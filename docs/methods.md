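# Methods

`flyheart` quantifies cardiac function in high-speed optical videos of the
semi-intact *Drosophila* heart tube and predicts specimen age class from the
resulting statistics or from the raw video.  This note documents the models,
conventions and numerical choices behind each stage, and what the built-in
simulator does and does not emulate.

## The signal model

The heart tube appears in a grayscale video as two bright horizontal wall
bands on a dark background.  The observable the whole pipeline is built on
is the per-frame mean lumen diameter d(t): within a user-chosen column range
(ROI), each pixel column contributes the gap between the inner edges of the
topmost and bottommost wall runs, and the frame's diameter is the mean of
the valid columns, in µm.  Frame rate and pixel size are mandatory explicit
metadata: recording rigs report frame rates inconsistently, so the package
never infers them.

A heartbeat is modelled as a diastolic interval (DI) at the diastolic
diameter (DD, relaxed) and a systolic interval (SI) at the systolic diameter
(SD, contracted).  Derived per-beat statistics use the standard conventions:

- FS = 100·(DD − SD)/DD (fractional shortening, %)
- EF = 100·(1 − (SD/DD)²) (ejection fraction under a cylindrical lumen;
  the only volume model consistent with diameter-only data)
- HP = DI + SI (heart period, s); HR = n_beats / Σ HP (Hz)
- AI = sd(HP)/median(HP), sample standard deviation (ddof = 1) —
  dimensionless rhythm dispersion
- SV = (π/4)·L·(DD² − SD²) with L the ROI length in µm, reported in pL
  (1 pL = 10⁶ µm³); CO = Σ SV / Σ HP (pL/s), normalised by summed beat
  times rather than recording length (switchable)
- wall velocity by central differences of d(t) (`numpy.gradient`);
  contraction is negative, relaxation positive
- tachycardic events: SI > 0.5 s; bradycardic events: DI > 1.0 s (strict
  inequalities)

## Boundary convention

Real traces ramp smoothly between plateaus, so "where DI ends" needs a
convention.  The package places every DI/SI boundary at the
mid-reference-level crossing of the transition — the point where the trace
crosses halfway between the adjacent plateau levels — which is the standard
pulse-timing convention and is robust because the trace's slope is maximal
there (a fixed-level convention near a plateau is ill-conditioned, since the
slope vanishes at the plateau).  The simulator defines its ground-truth
boundaries the same way (its cosine ramps are centred on the boundaries), so
a beat occupies exactly DI + SI seconds.  One consequence: peak contraction
velocity coincides with the DI end itself, so the latency from DI end to
peak contraction is ~0 for symmetric ramps; the latency from peak
contraction to peak relaxation is the meaningful temporal statistic.

## Beat detection

Detection runs on the trace smoothed with a centred moving average (default
5 frames) and uses hysteresis: with m, M the trace extrema, thresholds sit
at α = 0.35 and β = 0.65 of the excursion.  A DI starts at an upward
crossing of the high threshold; a candidate DI end (downward crossing) is
confirmed only after the trace dips below the low threshold, so shallow
wiggles near the high threshold cannot split a beat.  Traces whose excursion
is below 10 % of their maximum are treated as non-beating and yield an empty
table.  Only complete beats (DI start to next DI start) are emitted.
Confirmed boundaries are then refined to sub-frame times by linearly
interpolating the crossing of the local mid-level, where the local plateau
levels are the trace minimum before / maximum after the crossing (bounded by
the neighbouring events); this keeps boundary timing unbiased when DD/SD
vary beat to beat.  All constants live in `DetectorConfig`.

DD is the largest diameter attained during the DI, SD the smallest over the
following SI, both read from the unsmoothed trace.  Frames where walls merge
(single run) or the mask is empty are invalid; a frame is dropped when fewer
than 25 % of ROI columns are valid, and dropped frames are filled by linear
interpolation with their flags preserved so the time base stays regular.

## Segmentation

Heart walls are labelled by a 2-D attention U-Net applied to temporal
composites: frame t is presented with frames t−4 and t+4 as three input
channels (edge frames are clamped), so wall motion — not just brightness —
informs the labelling.  The encoder uses five depths with 8, 16, 32, 64 and
128 filters, two convolutions per depth with a rectangular 3×5 kernel
(wider along the tube axis, matching the walls' horizontal elongation),
2×2 max pooling, additive attention gates on the skip connections (gating
signal from the coarser decoder level), nearest-neighbour upsampling, and a
single-channel sigmoid head.  Inputs are padded internally to multiples of
16 and cropped back, so arbitrary frame sizes work.

Training minimises Dice loss with Adam (learning rate 10⁻³, batch 16,
30 epochs by default) and keeps the epoch with the lowest validation loss.
Training frames are sampled balanced across lumen-diameter bins (default
75 frames per 2-px bin) so rare fully-contracted frames are not swamped;
augmentation applies horizontal/vertical flips (image and mask together)
and ±10 % brightness jitter (image only).  Videos are split 85/15 into
train/validation by video, not by frame, to avoid temporal leakage.  The
networks run on a small in-package numpy autodiff (channels-last layout;
gradients verified against central differences in the test suite), so
training sizes are deliberately desk-scale: the reference study uses three
annotated 64×128 videos (~450 frames each, ~30 samples per diameter bin,
6 epochs), which trains in a few minutes on one CPU and reaches held-out
Dice ≥ 0.9 on simulated tubes.

## Age classification

Route 1 — cardiac statistics.  Per-heart summaries (DD, SD, FS, DI, SI, HP,
AI; fixed column order) feed a logistic model inside a
`StandardScaler + LogisticRegression` pipeline (unit L2 penalty), evaluated
with stratified 5-fold cross-validation; standardisation uses training-fold
statistics only, and hearts with fewer than two beats (undefined AI) are
excluded.  Feature attributions use the exact linear-model Shapley values
under feature independence, φ_j = w_j·(x_j − x̄_j) on the model's input
scale; attributions plus the base value reconstruct each logit exactly, and
global importance is mean |φ_j|.

Route 2 — raw video.  The motion signal SSD(t) = Σ_pixels (I_t − I_t0)²
(reference t0 = frame 0, configurable) is min-max normalised and binarised
at 0.5; each maximal run of equal values contributes its centre frame
(floor of the midpoint for even runs) until 96 frames are collected, so
selections alternate near peak relaxation and peak contraction.  The 96
frames enter a CNN as input channels (three blocks of two 3×3 convolutions
plus 2×2 max pooling, with 16/32/64 filters); the flattened features are
fused with the 95 inter-selection durations (seconds, z-scored with
training-set statistics — per-clip scoring would erase the heart-period
signal) and passed through dense layers of 128/32/8 units to a sigmoid
output, trained with binary cross-entropy and Adam.  Filter counts, dense
widths and kernel sizes are configurable; channel stacking was chosen over
per-frame shared-weight processing as the simpler reading of a 2-D
architecture over a fixed-length clip.

## The simulator

The simulator is the package's ground-truth substrate.  It draws per-beat
(DI, SI, DD, SD) from truncated normals (resampled until SD < DD and
intervals exceed the ramp time; deterministic given the seed), synthesises
the plateau-plus-cosine-ramp waveform, and renders it as two Gaussian-profile
wall bands (FWHM = wall thickness) at continuous sub-pixel positions, with
additive Gaussian noise and optional static clutter blobs placed away from
the walls.  Masks mark the wall bands at integer rows, so mask-derived
diameters are exact to ±1 px.  `lead_in`/`lead_out` add resting baseline
before and after the beats (a recording rarely starts or ends on a beat
boundary; a lead-out also lets the final beat complete).  Cohorts re-seed
every specimen and add between-heart variation: a common size scale
(multiplying DD and SD, leaving FS untouched), a common tempo scale
(stretching DI and SI together), and small independent jitters.  The young/
old presets encode the aging contrast (FS ≈ 35 % vs 22 %, HP ≈ 0.60 vs
0.66 s, with a mildly higher beat-to-beat variability when old — aging
shifts contractility far more than rhythm); the video-cohort presets
use a stronger contrast (FS 50 % vs 20 %, HP 0.6 vs 1.0 s) and 50 fps,
32×64 frames to keep clip experiments desk-scale.

What the simulator does not emulate: real anatomy (conical chambers, ostia,
pericardial cells), body movement, focus drift, fluorescence, or annotation
error in training masks.  Passing tests therefore demonstrate that the
algorithms recover known truth under the stated image model; they do not
certify performance on lab recordings, where segmentation quality and ROI
choice dominate.

## Numerical choices and limitations

- Diameter is the lumen gap (inner edge to inner edge); an `outer_span`
  switch measures outer edges instead.  With >2 runs in a column, the
  topmost and bottommost runs define the walls.
- Threshold semantics: mask = probability ≥ threshold, so raising the
  threshold never grows a mask; thresholds must lie strictly inside (0, 1).
- Dice loss uses ε = 10⁻⁶ smoothing; it is symmetric and bounded in [0, 1].
- Even-length SSD runs take floor of the midpoint; binarisation uses ≥ 0.5.
- All randomness flows through explicit integer seeds; simulation,
  sampling, initialisation and fold assignment replay bit-exactly, and run
  manifests record config, seeds and version.
- Sub-pixel wall localisation is out of scope; diameters are quantised to
  1 px by the masks, which bounds FS accuracy at roughly 2 points for
  ~80 µm hearts at 1 µm/px.
- The reference studies (`flyheart.experiments`) fix desk-scale problem
  sizes — tens of hearts, minutes of simulated video — chosen so the full
  suite runs on one CPU in minutes.
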