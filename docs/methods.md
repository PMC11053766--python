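# Methods

## Optical model

The eye is reduced to three parameters: pupil diameter (mm, default 4 —
a typical indoor photopic pupil), accommodation amplitude (D, default 0 —
an absolute presbyope, the population of interest for autofocal
correction), and spherical refractive error at far (D, default 0). The
accommodation policy is optimal-within-range: for an object demanding
*D* diopters behind a lens of power *P*, the eye accommodates
clamp(*D* − *P* + refractive error, 0, amplitude). No accommodative lag,
lead, or dynamics are modelled; accommodation is treated as settling
instantly relative to the simulation step.

Blur is the thin-lens, small-angle circle of confusion: angular disk
diameter β = pupil × |ΔD| (pupil in meters, ΔD the dioptric defocus
error). This is the standard first-order relation used in defocus
psychophysics; it is exactly linear in both factors, which the tests
exploit. Higher-order and chromatic aberrations, Stiles–Crawford
apodization and diffraction are out of scope; an elliptical kernel
extends the model to sphero-cylindrical (astigmatic) blur, with the
|sphere + cylinder| diameter oriented along the cylinder axis.

## Scenes and projection

Scenes are RGB rasters in [0, 1] with co-registered metric depth and a
pinhole camera: f_px = (W/2)/tan(FOV/2), principal point at the raster
center, row 0 at top, azimuth positive rightward, elevation positive
upward. The office generator places fronto-parallel "screens" — by
default a smartphone at 0.30 m, a monitor at 1 m, a TV at 6 m — as
rectangles of their exact angular size (2·atan(size/2d)) in front of a
flat wall at 6.5 m (the backdrop distance is this package's choice; any
value beyond the far screen behaves identically). Screens whose
projections overlap are rejected rather than composited, since each
screen must own its depth pixels for the task logic. Depth I/O uses
full-precision CSV so round trips are exact; PFM export was considered
and dropped (binary, and nothing downstream needs it).

## Blur rendering

The per-pixel CoC field is converted to pixels via β·f_px (small-angle).
Two renderers share the same disk kernels (a pixel belongs to a kernel's
support when its center lies within diameter/2; diameters ≤ 1 px are the
identity, so zero defocus is bit-exact):

* **gather** — the reference: each output pixel is the full image
  convolved with that pixel's own kernel, reflect-padded. O(HWk²); used
  on small images and as the test oracle.
* **layered** — the CoC field is quantized to at most 16 levels (the
  exact unique values when there are few, else 16 evenly spaced levels),
  the full frame is convolved once per level, and levels are composited
  far-to-near with hard per-level masks.

When the distinct CoC values fit the level budget the layered result
equals the gather result exactly; otherwise the error is the quantization
step times local contrast. Alpha-compositing with *blurred* coverage
masks was considered and rejected: it feathers depth boundaries in a way
the per-pixel reference never does, so the two renderers could not be
held to a common tolerance. Like any image-space depth-of-field method,
both renderers let a blurred surface bleed across a depth edge it does
not physically occlude; this edge artifact is accepted and confined to a
band of half a kernel around depth boundaries.

## Lens and controllers

The tunable lens is a pure transport delay followed by slew-rate-limited
tracking of the range-clamped command, settling exactly (no overshoot) —
the minimal model matching the two parameters real focus-tunable lenses
are specified by. Integration is piecewise-exact across the instant a
delayed command becomes effective, so a delay shifts a trajectory by
exactly its value regardless of the step size. Defaults: range 0–4 D
(covers the 3.33 D near demand), infinite rate and zero delay for the
"ideal" lens used as a ceiling reference.

The gaze-point controller commands 1/median(5×5 depth window) at the
gaze pixel — the median suppresses single-pixel depth outliers under
saccadic gaze — optionally smoothed by a moving average. The depth-mode
controller histograms demands within a foveal radius (default 5°) into
0.25 D bins and commands the median demand of the fullest bin, ties
broken toward the nearer bin (a near-focus error blurs the background
less than a far-focus error blurs the foreground). Dioptric rather than
metric binning matches how defocus scales perceptually. Invalid or
out-of-image gaze holds the last command. Manual control is
piecewise-constant with events effective at t ≥ event time.

The progressive lens is distance power above the corridor (default
+5°…−15° elevation), distance + add below, linear within — continuous
and monotone by construction.

## Gaze simulation

Fixations are target direction plus isotropic Gaussian angular noise
(default 0.3° SD per axis, typical of consumer VR eye tracking);
saccades are linear interpolations of fixed duration (default 30 ms)
labelled as such. The trace is monocular and cyclopean; no vergence,
blinks, drift or microsaccades. Consequently, tests passing on these
traces show the control loop's behaviour under clean input statistics,
not robustness to real tracker artifacts (dropouts, calibration bias).

## Matching task and observer

Each trial assigns the ring, letter and 8-column table to a random
permutation of the three screens (table screen uniform, preventing a
fixed fixation order), draws the ring orientation and Sloan letter
uniformly from their eight alternatives, and builds the table from an
orientation permutation paired with a letter permutation, planting or
excluding the presented pair so the match prior is exactly 1/2 — making
chance performance 0.5 by construction. Stimulus angular size is
configurable with a 10 arcmin gap default (a comfortably suprathreshold
size whose blur threshold is reached near 1 D of defocus with a 4 mm
pupil); optotypes scale with distance so angular size is constant across
screens. Placement is the screen center or a corner with optional
Gaussian jitter (σ = 5 % of the screen extent), clipped so the stimulus
stays on its screen.

The synthetic observer identifies each optotype with probability
p(r) = 1/8 + 7/8·logistic(−slope·(ln r − ln threshold)), r the blur/gap
ratio; slope 4 and threshold 1 are defaults chosen so identification is
certain when blur is well below the gap and at chance when blur is
several times the gap. Table lookup is errorless given the identified
pair, so at saturating blur the "match" answer rate is 1/8 and accuracy
converges to 1/2 against the balanced prior. Reaction time is
(0.8 s + 0.4 s per focus shift exceeding 1 D along the
ring→letter→table path) × exp(N(0, 0.15²)) — a multiplicative lognormal
jitter keeps RT positive for any draw. The observer is a synthetic
instrument for exercising the task end to end; none of its parameters
are fitted to human data, and block accuracies are meaningful only
relative to each other (ceiling vs chance vs intermediate), not as
predictions of human acuity.

In a block, gaze dwells 0.6 s per screen in trial order; the defocus of
each stimulus is read from the closed-loop power at the end of its dwell,
converted to blur via the CoC relation. Default block sizes in the tests
(tens of trials for full closed-loop blocks, 2000-trial blocks at the
observer level for limit checks) keep the whole suite in seconds while
leaving binomial noise well inside the asserted bounds.

## Protocol runner

Protocols are JSON (name + ordered scene id/param list; param "0" means
none) because the original inspector-style configuration has no file
equivalent. Interactive run control is replaced by a scriptable control
stream (skip before a scene, repeat after it, restart once) so runs are
deterministic and testable. Subject folders collide to `name_1`,
`name_2`, … and are never reused; each executed scene instance owns a
subfolder, and every artifact written into it (gaze, tuning-power log,
task responses, questionnaire answers) carries a filesystem timestamp in
its name, with `_N` deduplication within the same second. Questionnaires
are JSON keyed by abbreviation; a NASA-TLX definition ships with the
package.

## Numerical choices and degenerate inputs

CoC values are rounded to 1e-6 px before level grouping so floating-point
dust cannot multiply blur layers. Kernel support uses pixel centers, so
kernels are deterministic and symmetric; the gather oracle and the
layered renderer use the same reflect boundary rule, making their
agreement exact rather than approximate on quantization-free scenes.
Depth maps must be finite and strictly positive (a zero depth has no
dioptric demand); nonpositive distances, negative defocus, empty scene or
schedule inputs, unordered manual events and out-of-range cylinder axes
all raise immediately rather than propagating NaNs.

## Limitations

Beyond the per-module non-goals above: the renderer is image-space (no
occlusion-aware partial visibility behind blurred edges); the display
optics' own depth of field is ignored; lighting, textures and
photometric realism are absent, so contrast-dependent effects on acuity
are not represented; and all results on synthetic gaze and the synthetic
observer demonstrate internal consistency of the simulation chain, not
human performance.
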