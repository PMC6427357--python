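# Methods

## Problem setting

`blinkflow` detects eyeblinks and tracks the eye state (open/closed) in video
of a single eye filmed obliquely from inside a VR headset: portrait grayscale
frames, nominally 240 × 320 px (w × h), captured at 100 fps or more under
near-infrared illumination.  The defining requirement is *latency*: a blink
must be recognised during its closing or pause phase — i.e. while the eye is
still shut — so that a consumer (e.g. imperceptible scene redirection in VR)
can act before reopening.  Conventional blink detectors that classify a
completed blink waveform are too late by construction.

A blink has three phases.  For healthy adults the mean durations are:

| phase     | voluntary (ms) | spontaneous (ms) |
|-----------|---------------:|-----------------:|
| closing   | 70.8           | 71.5             |
| pause     | 44.2           | 13.7             |
| reopening | 168.5          | 171.5            |
| total     | 283.5          | 256.7            |

The pause of a spontaneous blink (13.7 ms) is the shortest event the camera
must not skip, which yields the minimum capture rate
`round(1000 / 13.7) = 73 fps`; at 30 fps the frame period (~33 ms) exceeds the
pause and the fully closed eye can be missed entirely.

## Detection pipeline

Each frame is cropped (by default the left 70 px, which image the headset
interior, leaving 170 × 320), and every successive frame pair is processed by
two paths whose results are both available before the state decision:

1. **Motion path.**  Dense optical flow is estimated between the pair and read
   at a regular marker grid with spacing `d = 10` px
   (`floor(w/d) · floor(h/d)` points; 544 at 170 × 320).  Markers sit at cell
   centres so none lies on the border, where flow is least reliable.  The
   sampled vectors are filtered and summed into:
   - the **downward motion vector (DMV)**: vectors with magnitude ≥ 2 px,
     positive y-component (down, in image coordinates with y growing
     downward), and y-component ≥ half the vector's own magnitude.  The last
     criterion suppresses oblique saccade motion; a variant referencing half
     the magnitude of the unfiltered total sum is available
     (`downward_criterion="total"`).
   - the **upward motion vector (UMV)**: vectors with magnitude ≥ 2 px and
     negative y-component.
   Boundary cases are kept (magnitude exactly 2; y exactly half the
   reference).  An empty survivor set gives the zero vector.

2. **Appearance path.**  The eye ROI is localized (see below) and, on demand,
   the current frame is compared against an open-eye template by the raw
   normalized cross-correlation
   `Q = Σ(f·t) / sqrt(Σf² · Σt²)`,
   which lies in [0, 1] for non-negative images.  `Q` below the verification
   threshold (default 0.80) classifies the eye as closed; `Q` exactly at the
   threshold counts as open.  A zero-mean variant (signed coefficient in
   [−1, 1]) is available behind `ncc_zero_mean`.

The blink FSM has states S0 (initial), S1 (open), S2 (candidate closure,
transient within a frame step) and S3 (closed); the only edges are S0→S1,
S1→S2, S2→S1, S2→S3, S3→S1.  While the eye is open, a DMV magnitude above the
dynamic threshold registers a candidate (S1→S2); NCC verification against the
open-eye template either confirms (S2→S3, blink event emitted — this is the
moment "detected during closing/pause" refers to) or rejects (S2→S1).  While
closed, a UMV magnitude above the reopening threshold, or — as a fallback —
the eye region matching the open-eye template again, detects reopening
(S3→S1).

### Dynamic closure threshold

While the DMV magnitude is positive, the per-frame magnitudes accumulate into
the current closing episode; when it returns to zero the episode's peak enters
a history (window of the last `window_n = 10` peaks) and the threshold becomes
the **median** of that history.  In operation the history is dominated by
small motion episodes (fixational micro-saccades, drifts), which anchor the
median far below blink scale; blink peaks tower above it.  The median's
robustness matters precisely because the history mixes small episodes with
occasional large ones.

DMV is only computed (and the threshold only updated) on frames where the eye
is open or unknown; a closing episode that flips the state to closed is
therefore truncated at the verification frame, which also keeps recorded blink
peaks below the full closing maximum.

Before the first episode completes, the threshold is `initial_threshold`
(default **50 px**).  This value is chosen between two scales: flow noise
summed over the 544-marker grid can reach tens of px even with no real eye
motion, while a genuine closure — dozens of markers moving several px each —
sums to thousands.  A much smaller initial value would let grid-level flow
noise trigger candidates and, worse, let the pre-calibration *reopening* check
fire on noise.

### Reopening threshold

Reopening requires the upward motion to **dominate**: the UMV magnitude must
exceed both the reopening threshold (an independent constant, default
**400 px**) and the downward sum computed from the same flow field.  The
dominance test costs nothing (the vectors are already sampled) and removes a
whole class of artifacts: while the lid is still descending, flow estimation
can produce sizeable spurious upward sums (several hundred px on some
textures), but the concurrent downward sum is in the thousands; during a
genuine reopening the downward sum is near zero, so the test is inert.  The
closed-state downward sum feeds only this comparison — the dynamic threshold
adapts on open-eye frames alone.  On synthetic scenes a genuine reopening
sums to ≥ ~1000 px, so 400 px leaves margin on both sides.  Tying the
threshold to the dynamic closure threshold (`reopening_threshold=None`) is
supported but unsuitable whenever fixational episodes anchor that median near
the noise floor.  The NCC fallback detects reopening regardless, typically a
few frames later.

### Eye localization

Two interchangeable backends satisfy one contract (return the best eye box or
none):

- **Dark-blob** (default): the bounding box of the largest connected region
  darker than `dark_threshold` (default 80), padded by 10%, exploiting the
  darkness of the pupil/iris under IR illumination.  Self-contained; used for
  all synthetic work.
- **Cascade**: a boosted cascade of Haar-like rectangle features loaded from
  the standard cascade-XML stages format, evaluated on variance-normalized
  sliding windows over a scale pyramid.  Training such a model is out of
  scope; any pretrained file with that schema can be consumed.  Among
  multiple accepted windows the largest is kept (`selection="best"` switches
  to highest vote sum).

On localization failure the previous frame's box is reused and the per-frame
record marks the ROI as not detected; the hit rate (localized / total frames)
summarizes localization quality over a stream.

### Open-eye template management

The template is captured automatically by a five-state machine (initial →
waiting for a reopening → timing a 500 ms wait → checking the eye state →
accepted).  The 500 ms wait after a detected reopening outlasts every blink
phase, including a double blink.  At cold start, the first confidently
localized ROI after 500 ms of stream with no downward motion is bootstrapped
as the template.

Two deliberate design choices:

- **Verification samples the template's capture box**, not the freshly
  localized ROI.  The dark-blob ROI shrinks to a sliver as the lid occludes
  the pupil, making like-for-like comparison impossible; a state-invariant
  box over the eye region (what a cascade trained on open *and* closed eyes
  provides naturally) is emulated by re-sampling the template's own box.  The
  camera is rigidly mounted, so the eye region drifts only slowly; template
  refreshes track that drift.
- **Conservative refresh.**  A refresh capture is adopted only while the
  current frame, sampled at the *existing* template's box, scores at least
  `template_refresh_min_q` (default 0.95) against the existing template —
  i.e. a refresh must be near-identical to what it replaces.  Slow drift of
  the eye region passes this bar; a capture taken at a saccade-displaced gaze
  (which scores ~0.8, indistinguishable from the open/closed decision
  boundary) does not.  Without the gate a displaced capture poisons every
  subsequent verification: even the resting open eye then scores below the
  closure threshold.  The cost is that the template does not adapt to a
  *persistently* shifted gaze; the next valid capture resumes tracking.

## Synthetic data generator

The generator renders the scene structure the detector is designed for, not
photorealism: a portrait 240 × 320 frame whose left 70-px band is the flat
headset interior; a smoothly textured skin field; a bright sclera ellipse; a
dark iris/pupil disk (the localizer's target and the NCC's discriminant); and
a textured upper-lid occluder anchored to its moving lower edge, with a dark
lash line.  During a scripted blink the lid edge descends linearly over the
closing duration, holds over the pause, and ascends over the reopening
duration.  Scripted saccades translate the iris (30 ms ramp, 200 ms hold,
30 ms return).  Gaussian pixel noise with `noise_sd` models sensor noise.
Everything is deterministic given the seed.

Ground-truth intervals follow from the closure profile `c(t)`:
`start_frame` is the first frame with the lid in motion, `closing_end` /
`pause_end` bound the fully-closed span, `end_frame` is the last frame before
the lid returns to rest.  The renderer guarantees the iris is fully hidden
throughout `[closing_end, pause_end]`.

The default scene includes one small (8 px) downward **fixational
micro-saccade** in the lead-in and in every inter-blink gap.  Real eyes are
never still, and the dynamic threshold's median is *designed* for a mixture
of small and large motion episodes: a scene containing only identical blinks
would drive the median to the blink-peak ceiling and is not a condition the
method is meant for.  The micro-saccades are scene furniture (their episode
peaks, ~30–60 px, sit below even the pre-calibration threshold), not noise.

What the generator does **not** emulate — and hence what passing tests do not
establish about real recordings: display-driven illumination changes,
specular glints and eyelashes, lid deformation (the lid is a rigid textured
occluder), realistic saccade kinematics and amplitudes, partial blinks and
micro-blinks, headset readjustment, motion blur, and rolling-shutter or
compression artifacts.  Results on the clean scene are a correctness check of
the pipeline's logic and latency, not a performance claim for real data; the
published validation counts shipped with the package are the performance
reference for real recordings.

## Standard validation scene and problem sizes

The package's standard end-to-end check uses 5 scripted spontaneous blinks
(mean phase durations 71.5/13.7/171.5 ms) at 100 fps, zero pixel noise,
~5.9 s ≈ 590 frames — large enough for bootstrap, five full
detect/verify/reopen cycles and threshold adaptation, small enough that the
full suite stays inexpensive.  On this scene the detector must achieve
recall 1.0 and FDR 0 with every blink verified at or before the last
fully-closed frame.

## Dense-flow backends

Three estimators satisfy one contract (median sampled displacement of a rigid
integer translation recovered within 0.5 px for |t| ≤ 5):

- `polyexp` (default): polynomial-expansion flow.  Every neighbourhood of
  both frames is approximated as a quadratic form via Gaussian-weighted least
  squares (separable correlations; window half-width `poly_n = 3`, applicability
  σ = 1.2); matching the two expansions gives per-pixel normal equations that
  are averaged under a Gaussian window (σ = 4) and solved 2 × 2 per pixel,
  with 3 warp-and-refine iterations per level of a 3-level image pyramid.
  Degenerate normal matrices (determinant ≈ 0, e.g. textureless regions)
  yield zero displacement.
- `block`: exhaustive SSD block matching on a stride-4 grid, upsampled by
  nearest neighbour.  Integer displacements only; independent of the
  polynomial machinery, used as a test oracle.
- `ilk`: iterative Lucas–Kanade (scikit-image).

## Evaluation conventions

Detections are matched to ground-truth blink intervals by temporal overlap
(≥ 1 shared frame, extendable by `match_slack_frames`, default 0), one-to-one,
greedily in temporal order; a second detection overlapping an already claimed
blink is a false positive.  Metrics: recall = TP/(TP+FN),
precision = TP/(TP+FP), FDR = FP/(FP+TP), accuracy = TP/(TP+FP+FN); a zero
denominator yields an explicit undefined marker, never 0.  Values are kept at
full precision and rounded only for reporting (3 decimals).  Mean rows over
multi-sample validations are unweighted means of per-sample metrics; the
shipped reference counts reproduce the published validation tables under
exactly this convention (their SD rows use the population standard deviation).
One published per-sample row (S9) is internally inconsistent — its printed
metric cells do not follow from its own printed counts — so per-row
comparisons cover the other eleven samples, while the means row reproduces
exactly over all twelve.

Annotation files are CSV with one row per frame transition: frame number, DMV
and UMV magnitudes, eye state, blink flag, ROI-detected flag, plus optional
manually reviewed ground-truth and TP/FP/FN category columns.  (The original
validation logs were multi-sheet spreadsheets of the same schema, one sheet
per video.)

## Known limitations

- The raw (non-zero-mean) NCC is sensitive to global illumination changes;
  under a flickering display the zero-mean variant is the better choice.
- The dark-blob localizer presumes IR-style imaging where the pupil/iris is
  the darkest structure; it is not meant for visible-light frontal video.
- The conservative template refresh cannot follow a persistent gaze shift
  (see above).
- Flow-based DMV saturates for very fast lid motion (> ~10 px/frame at the
  coarsest pyramid level); direction remains correct, so detection is
  unaffected, but DMV magnitudes are not calibrated lid velocities.
- Processing is sequential; the original sensor's real-time budget
  (two threads, ~11 ms/frame) is an engineering concern outside this
  package's scope, and frame timing is logged but not optimized.
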