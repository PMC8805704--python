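# Methods

`dsmap` re-implements, as a tested Python pipeline, the analysis that turns
two-photon calcium-imaging movies of the developing mouse retina into (a)
a map of direction-selective ganglion cells (DSGCs) — their preferred
directions, tuning strengths, functional clusters and spatial gradients —
and (b) propagation-bias statistics of spontaneous retinal waves.  Because
no imaging data ship with the package, a first-class synthetic-data
generator renders ground-truthed movies with the statistical structure the
analysis assumes; every stage is scored against what was injected.

## Coordinate and angle conventions

Positions are micrometres relative to the optic nerve head; the array
column index is +x and the row index +y.  Directions of motion or
propagation are counter-clockwise in retinal coordinates with **0° =
temporal, 90° = dorsal, 180° = nasal, 270° = ventral**.  The
nasal/temporal anchoring (0°/180°, +x temporal) is the field's convention;
placing dorsal at 90° rather than 270° is this package's choice, applied
consistently and documented here rather than asserted as universal.

## ΔF/F₀ preprocessing

The per-pixel baseline F₀ is the temporal mean over frames outside every
stimulus-trial window (an optional guard band widens the exclusion;
default 0 frames), and ΔF/F₀ = (F − F₀)/F₀.  Pixels with non-positive
baseline are masked to 0 with a warning rather than propagating NaN.
Motion correction is exposed only as a pass-through hook: synthetic inputs
are drift-free and registration of real recordings is assumed to happen
upstream, so the pipeline is honest about what it does and does not
re-implement.

## Per-cell tuning statistics

For an ROI with per-direction mean peak responses R(θ) over the 8 bar
directions (45° apart, 3 block-shuffled repeats):

* **Vector sum.**  VS = Σ R(θ)·(cos θ, sin θ).  Its angle is the
  preferred direction.  Both the raw resultant length and the normalized
  form |VS| / Σ R(θ) are reported; the normalized form is bounded by
  [0, 1] for non-negative responses and is used wherever boundedness
  matters (e.g. detection thresholds).
* **DSI** = (R_pref − R_null)/(R_pref + R_null), where the preferred bin
  is the sampled direction nearest the VS angle (exact ties resolve to
  the smaller angle) and the null bin is its 180° opposite.  The value is
  defined as 0 when the denominator is not positive and clipped to
  [−1, 1]; both guards only engage when noise drives per-direction means
  negative, which non-negative inputs never do.
* **Significance.**  1000 permutations re-draw the trial direction labels
  by independently permuting them within each stimulus block, recomputing
  the preferred direction and DSI each time.  The percentile rank counts
  permuted DSIs *strictly* below the observed one (ties do not count);
  a cell is significantly direction selective when the rank exceeds 95.
  With exchangeable responses this yields a type-I error of
  50/1001 ≈ 5%, which the test suite verifies empirically over 400
  untuned cells.
* **ON / ON-OFF classification.**  The repeats at the preferred direction
  are block-averaged and peaks detected (prominence threshold 0.1 ΔF/F,
  configurable; the trace is padded with low sentinels so a transient
  sitting on the trial-window edge still counts).  Two peaks separated by
  bar_width/speed ± 25% mark onset and offset responses (ON-OFF); one
  peak marks ON.  Cells whose mean pairwise trial-trace correlation at
  the preferred direction is below 0.2, or that show no detectable peak,
  are classed BAD.  These three thresholds operationalize what was a
  human judgment in the original workflow and are all exposed in the run
  configuration.

## Detection of DS somata

Every pixel is treated as a miniature ROI: its trace is averaged over a
square neighborhood (default 3×3), per-trial peaks and per-direction
means extracted, and the same VS/DSI statistics computed, yielding
pixel-wise maps.  A 2-D median filter (default 3×3) suppresses speckle;
the preferred-direction map is medianed circularly (median of the
unit-vector components, angle re-derived) to avoid 0°/360° wrap
artifacts.  Candidate ROIs are connected components with normalized VS ≥
0.5 intersected with bright soma-like regions of the mean image
(median + 3 robust SDs), size-filtered to 9–500 px.  These thresholds
replace the original manual ROI drawing; they are configuration, not
constants, and the defaults are this package's own.

## Map-level analysis

Significant ON and ON-OFF cells are pooled and clustered by preferred
direction: angles become unit vectors, K-means runs for k = 2…8
(n_init = 50, seeded), and the k with the highest mean silhouette value
SV(i) = (b(i) − a(i))/max(a(i), b(i)) wins, ties going to the smaller k.
Distances are Euclidean between unit vectors (chord length), which is
monotone in angular distance.  Identical inputs are flagged degenerate
with SV 0 by convention.  Clusters are anchored to retinal axes by
marker cells (stand-ins for GFP-labelled ventral- and nasal-preferring
lines): ventral = the cluster holding the ventral-marker majority,
nasal = the nasal-marker majority (or the cluster immediately clockwise
of ventral), dorsal/temporal = their 180° rotations; ambiguous marker
majorities raise rather than guess, and a no-marker fallback labels by
nearest canonical angle with an explicit flag.  All of this runs per
stratum: ventronasal vs ventrotemporal quadrant × central (<1000 µm from
the optic nerve) vs peripheral (≥1000 µm).

Summary statistics per cluster and cell class cover cell proportions
(normalized within condition × class), DSI and VS distributions, and the
circular variance (1 − mean resultant length) of preferred angles.  The
spatial gradient of a cluster's preferred direction is fitted per FOV:
each FOV contributes its circular-mean direction (unwrapped around the
across-FOV circular mean) against its mean optic-nerve distance, and an
ordinary least-squares slope in deg/mm with 95% CI is reported — a
per-FOV rather than per-cell regression, matching how such gradients are
presented.  Group comparisons use one-way ANOVA followed by Tukey-Kramer
pairwise tests (unequal-n safe; equal group sizes reduce it to Tukey's
HSD) at α = 0.01; zero-variance inputs are reported as degenerate, not
raised.

## Retinal-wave analysis

Raw wave movies are baseline-subtracted with a moving average (default
30 s window) that excludes wave frames, bootstrapped in two passes:
frames whose spatial mean stands out from either the local moving
average (sharp events) or the global median (events longer than the
window) by 3 robust SDs are flagged active, and the baseline is then a
masked moving average over quiet frames only (windows with no quiet
frame fall back to the pixel's overall quiet mean, with a warning).  The
dF movie is smoothed with a separable 3-D Gaussian (σ = 2 px × 2 px ×
2 frames) and segmented into events as 3-D-connected suprathreshold
components (threshold either explicit or median + 5 robust SDs of the
smoothed movie; components under 100 px footprint or 3 frames are
dropped).

Propagation vectors come from activation-time maps rather than
frame-pair optical flow — the referenced macro's algorithm is
unspecified, and the activation-time gradient is deterministic and
directly checkable against ground truth.  Per 16-px grid region a plane
is least-squares fitted to each pixel's first-suprathreshold time; the
unit propagation vector points along +∇t (the front arrives later
further along its travel direction).  Region coordinates are centred so
that mirroring the movie in x negates dt/dx exactly, which makes the
nasal/temporal swap under an x-flip exact.  A wave's mean direction is
the circular mean of its region vectors, its directionality the
resultant length of the unit vectors (1 = perfectly planar, 0 = no net
direction, e.g. radial expansion).  Waves are classed temporal (+x mean
vector) or nasal (−x); zero-x waves are excluded as unclassified.  A
majority-of-regions classification is reported alongside the mean-vector
one.  Frequency is events per minute of recording.

## Synthetic data: what it emulates and what it does not

**Stimulation sessions** default to the recording constants of the
emulated protocol: 256×256 px at 2.96 Hz, bar 500 µm (along motion) ×
1000 µm at 250 µm/s, 8 directions × 3 repeats in block-shuffled order,
10 s between sweeps.  The FOV side (512 µm ⇒ 2 µm/px), soma radius
(8 µm), baseline fluorescence (100 a.u.) and indicator decay constant
(0.8 s) are this package's realism choices.  Tuned cells get a
von-Mises-shaped amplitude A·exp(κ(cos Δ − 1)) (default κ = 4, so the
null response is ~e⁻⁸ of the preferred one); κ = 0 gives untuned cells.
Transients rise instantaneously at the frame after a bar edge crosses
the soma and decay exponentially; ON-OFF cells respond to both edges,
2 s apart at the default geometry.  Transients add linearly, so a
noiseless ON-OFF cell's measured peaks track its tuning curve only up to
a ≤3% direction-dependent factor (the offset transient rides on the
onset decay, with per-trial frame rounding); tests assert
proportionality at 3% tolerance.  Trial windows recorded in the
schedule extend 5 decay constants past the sweep, and transients are
truncated there, so inter-trial frames are *exactly* at baseline — an
idealization that makes the ΔF/F round trip testable to 1e-6.  Pixel
noise is white Gaussian.  Not modelled: optics/PSF, motion drift,
photoreceptor adaptation, laser-evoked responses, bleaching — wet-lab
artifacts the original experiments control for physically, not
computationally.  Passing tests therefore certify the *analysis*, not
robustness to those nuisances.

Cell maps place non-overlapping somata uniformly in the FOV; each
cluster-labelled cell's preferred direction is its cluster's canonical
angle + gradient × optic-nerve distance (deg/mm) + truncated Gaussian
jitter (default σ = 10°, bound 3σ), and a configurable fraction of
ventral/nasal cells carry a marker flag.

**Wave sessions** default to 128×128 px / 850 µm at 5.92 Hz with ≥50
waves.  Each wave is a planar Gaussian band (FWHM 200 µm) sweeping the
FOV at 200 µm/s, nasal (180°) with probability `nasal_bias` and temporal
otherwise, ±15° Gaussian jitter (clipped at 60° so the ground-truth
label always matches the x-sign rule); waves are sequential with 4 s
gaps, so they never overlap in time.  Real waves meander, vary in speed
and can collide; the generator trades that realism for exact ground
truth.  A radial-wave renderer provides the zero-directionality control.

**Direct peak simulation.**  For calibration at scale (hundreds of
permutation tests), `simulate_cell_peaks` bypasses rendering and draws
each trial's peak as the maximum over a 12-frame noisy response window
(transient kernel + Gaussian noise), mirroring what peak extraction
measures on traces.  The window maximum matters: it makes peaks
positively biased and non-negative in practice, like real ΔF/F peaks,
keeping the DSI's null bin away from zero-crossing artifacts that a
single additive Gaussian draw would produce.

## Problem sizes and numerical choices

The test suite runs most unit tests on 128-px/256-µm sessions with a
6 s inter-trial interval and reserves the full-scale conditions for the
acceptance-level tests: a 50-cell 256-px session at noise sd 0.05
(detection recall, direction recovery within 22.5°, class agreement), a
200-cell five-FOV map for cluster/label/gradient recovery, 400 untuned
cells × 1000 permutations for type-I calibration, and a 100-wave movie
at nasal bias 0.7 for propagation-bias recovery — sizes chosen as the
smallest that exercise each claim at its stated statistical tolerance.
Movies are float32 by default (float64 available via configuration and
used where tests assert 1e-6-level identities); the wave pipeline keeps
float32 inputs in float32.  All randomness flows through
`numpy.random.Generator` seeds carried in the configuration objects;
identical seeds reproduce movies, schedules and tables bit-for-bit, and
every output table carries its configuration hash and seed in `#`
header lines.

## Known limitations

* ROI proposal approximates, but does not reproduce, hand-drawn oval
  ROIs; overlapping or touching somata can merge into one component.
* The activation-time vector method needs a front that crosses each grid
  region over ≥2 frames; single-frame (FOV-instantaneous) events are
  flagged rather than vectorized.
* The gradient regression unwraps angles around the stratum circular
  mean and assumes the per-FOV spread stays well inside ±180°.
* Baseline exclusion of waves assumes waves are episodic; recordings
  with near-continuous activity leave few quiet frames and degrade the
  moving baseline toward the global quiet mean.
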