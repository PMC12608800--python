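# Methods

`thermarousal` estimates, frame by frame, whether a person watching
digital content is in a state of emotional arousal, using only noncontact
signals: facial skin temperature from a thermal camera and the eye-opening
degree from a visible camera. This note records the model, the choices
that were genuinely open, and what the synthetic cohort does and does not
demonstrate.

## Signal model

Sympathetic activation redistributes facial blood flow: the nasal tip
cools (typically a few tenths of a °C) while the cheeks change little or
warm slightly, and lid aperture tends to widen with alertness. The
pipeline therefore tracks three rectangular regions of interest (ROIs) on
the registered 640×480 thermal frame — the nasal ridge (10×30 px,
nostrils excluded) and the two infra-orbital cheek patches (20×20 px) —
plus the distance between the upper and lower eyelid landmarks of each
eye.

### Registration and normalization

Temperatures are mapped to 8-bit "thermal grayscale" over a fixed band
T_min = 29.0 °C to T_max = 37.0 °C (luminance 0–255, round-half-to-even,
saturating outside the band). A region's *luminance temperature* (LT) is
recovered from its mean luminance G_avg by the inverse affine map

    T_color = (G_avg / 255) · (T_max − T_min) + T_min,

which commutes with spatial averaging and has a quantization resolution
of (37−29)/255 ≈ 0.0314 °C — the accuracy bound for every temperature in
the pipeline. Visible frames are registered onto the thermal geometry by
a projective transform fitted by direct linear transform to exactly four
fiducial markers (the markers are rigidly fixed, so no robust estimation
is used); warping is bilinear with zero fill. Landmarks are assumed to be
detected on the already-registered visible frame; a config flag covers
the other order.

### Temporal alignment

The visible stream runs at 60 fps, the thermal at 30 fps. Each thermal
frame t is matched to visible frame round(t·(n_visible−1)/(n_thermal−1))
(round-half-to-even), i.e. linear interpolation of frame counts expressed
on the thermal timeline, where all features live. The mapping is monotone
and endpoint-exact.

### ROI placement

Landmark geometry is evaluated in a de-rotated face frame (roll = angle
of the line through the two eye outer corners) and the axis-aligned
rectangles are rotated back about the inter-nostril reference point, so
ROIs follow head roll rigidly. The nose ROI is centred on the midpoint of
nose root and apex; each cheek ROI on the eye's horizontal midpoint,
dropped 0.6 of the vertical distance from the lower lid to the nose apex
(below the eye, clear of eye, nose and mouth). The 106-point landmark
indices and the 0.6 drop are configuration, since no landmark convention
is universal. A frame whose rotated ROI leaves the image is masked
invalid rather than raising.

### Features (11 per frame)

1–3. LT of nose, right cheek, left cheek.
4–6. Pairwise LT differences (nose−right, nose−left, right−left), which
     cancel drift components shared between regions.
7–9. Amount of temperature change (ATC): the LT is first smoothed with a
     3-frame centred moving average (edges truncate), then differenced
     against its value 30 frames (one second) earlier. The first second
     of every recording is therefore masked.
10–11. Eye-opening degree (EOD) per eye: the eyelid landmark distance,
     low-pass filtered at the native 60 fps with a zero-phase order-2
     Butterworth at 0.5 Hz, then sampled onto the thermal timeline.
     Blinks are ~150 ms transients (spectral content ≫ 2 Hz), so a
     0.5 Hz zero-phase filter removes them with unit DC gain; filtering
     before downsampling keeps the full blink bandwidth visible to the
     filter. Filter family, order and cutoff are design choices exposed
     in `FilterConfig`.

This 3 LT + 3 ΔLT + 3 ATC + 2 EOD composition is the unique reading of
the feature description consistent with the printed feature count of 11,
given per-eye EOD.

## Classifier

Windows of 30 consecutive valid frames (one second, stride 1, target =
label of the last frame; 0 = arousal, 1 = non-arousal) feed a single
bidirectional LSTM layer with 100 units per direction; the final forward
and backward hidden states are concatenated (200-d) into one sigmoid
output unit. Loss is binary cross-entropy, optimised by Adam at step size
0.001, batch 1024, 100 epochs, no early stopping and no class
re-weighting. "Intermediate layer 100" is read as 100 units per
direction; this and the window anchoring (trailing/causal, with the
bidirectionality operating inside the window) are exposed in
`ModelConfig`.

The network is implemented directly on numpy: a vectorised LSTM forward
pass and backpropagation through time in float32, Glorot-uniform
initialisation with forget-gate bias 1, seeded end to end so a fixed seed
reproduces every downstream number bit-for-bit on a given platform.
Features are z-scored per column with training-fold statistics (computed
in float64, applied before the float32 cast), which makes predictions
invariant to per-column rescaling of the inputs.

## Decision rule and evaluation

Each test participant's probability track is thresholded at its own
median (self-calibration on predictions only — no labels are used).
Probabilities above the threshold become non-arousal; at or below,
arousal. A consequence worth stating: the median forces an approximately
50/50 predicted split, so high macro-F1 is attainable only when the true
arousal prevalence is itself near one half — a property of the
thresholding rule, not of this implementation.

Raw labels are then corrected once (not iterated) by a majority vote
over ±1350 frames (2700 frames ≈ 90 s at 30 fps, motivated by the
~90-second persistence of emotional physiological responses), computed
with prefix sums; window truncated at the track bounds, invalid frames
excluded, exact ties keep the original label. The vote has a geometric
feasibility condition: any run of identical labels shorter than half the
window (45 s) is provably overwritten by its surroundings, so both
episodes *and* the non-arousal gaps between them must exceed the window
for correction to help. On episode layouts near that limit the vote
trims episode boundaries and can cost a point or two of F1 even while it
removes isolated misclassifications.

Scoring is macro-averaged F1 in percent, F1 = TP/(TP + ½(FP+FN)) × 100
per class, averaged over the two classes, under leave-one-subject-out
(LOSO) cross-validation; the report carries both pre- and post-correction
scores per fold because the correction stage is a separable design
choice. A class absent from both reference and prediction scores 100 for
that class; absent from the reference but predicted, 0. Participants
lacking both classes are skipped with a warning rather than failing the
batch.

## Synthetic cohort

Real recordings are private, so the package ships a generator whose
defaults define the simulated study conditions: 9 participants (tests use
6), 10 minutes each, thermal 30 fps / visible 60 fps. Per ROI the
temperature is baseline (nose 33.5 °C, cheeks 34.0 °C) + random-walk
drift (0.005 °C/√s) + episode effect + white noise (0.05 °C), clipped to
[25, 40] °C. Four arousal episodes of U(60, 90) s with ≥30 s refractory
gaps give an expected arousal prevalence near 0.5 (see the median
threshold note above). The episode effect is a trapezoid with a 10 s
onset/offset ramp, −0.5 °C on the nose and +0.1 °C on the cheeks —
nasal cooling as the arousal signature, consistent with the
thermal-affective literature; sign and magnitude are scenario
parameters, not pipeline assumptions. EOD is a 12 px baseline raised 20%
during episodes, with Poisson blinks (18/min, 150 ms cosine closures to
near zero). Landmarks come from a parametric 106-point face template
with the eyelid points animated by the EOD process and an optional ±2°
sinusoidal head-roll wobble that exercises the ROI rotation code.
`render_thermal_frames` paints the ROI tracks into landmark-positioned
polygons on a constant 30 °C background so the full image pipeline can
be round-tripped; multi-participant runs use the equivalent track-level
fast path (`features_from_tracks`), whose agreement with the image path
is itself under test.

What the simulator does *not* model: perspiration and respiration
artefacts, ROI occlusion (glasses, hair), landmark jitter and drift of a
real detector, camera noise and vignetting, expression-driven
deformation, and inter-region drift correlation. Passing the simulation
checks therefore demonstrates that the pipeline recovers the assumed
signal structure, not that real recordings achieve any particular score.

## Problem sizes and numerical choices

The end-to-end LOSO checks run two regimes of 6 participants × 10 min on
one CPU: a separable regime (the scenario defaults above) and a chance
regime (all effect sizes zero). Training uses the study hyperparameters
with epochs scaled 100 → 20 and the training windows thinned to one per
second (stride 30, ≈3,000 windows per fold); the held-out participant is
always predicted at every frame. At these sizes the separable regime
scores mean macro-F1 in the mid-90s pre-correction and the chance regime
sits near 50, the two regimes the simulator is designed to span.

Degenerate inputs: saturating clamp outside the normalization band;
landmark-failure frames propagate a validity mask instead of aborting;
ROI-out-of-bounds frames likewise; invalid samples are linearly bridged
before temporal filters but never enter training or scoring; tie rules
are fixed (probability equal to threshold → arousal; vote tie → keep);
empty windows, single-class training data and cutoffs at or above
Nyquist raise errors.

## Known limitations

* The numpy BLSTM is exact but not fast; at full stride-1 training on
  long cohorts a GPU implementation would be preferred.
* Median self-thresholding assumes near-balanced prevalence in the test
  recording (see above); strongly unbalanced recordings need a different
  calibration rule.
* The 90-s vote assumes both states persist longer than 45 s; short
  alternations are smoothed away by construction.
* Landmark indices, cheek offsets and EOD filter parameters have no
  published reference values; defaults are stated here and configurable.
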