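# Methods

This note documents the models and procedures the package implements,
the parameter choices that matter, what the synthetic generator does
and does not emulate, and the numerical conventions adopted where the
underlying methodology leaves room.

## Preprocessing

Movies are fractional-fluorescence sequences (T×H×W, default 50 Hz).
The chain runs in a fixed order — ΔF/F, temporal smoothing, spatial
smoothing, high-pass, initial trim — and a hash of the applied
configuration is stamped into the output metadata.

* **ΔF/F.** Per pixel, `(F − F̄)/F̄` with the pixel's temporal mean over
  the sequence as baseline.  This is homogeneous of degree zero: the
  result is invariant to rescaling the raw movie, which in turn makes
  the downstream S.D.-based threshold scale-free.  Pixels with exactly
  zero baseline (dead pixels, or synthetic movies without an offset)
  are zeroed with a warning.
* **Smoothing.**  Temporal: centred 4-frame moving average.  Spatial:
  8×8-pixel moving average per frame.  Both use renormalised partial
  windows at edges (no wrap-around, which would seed phantom cascades
  across borders).  When a mask is supplied, the spatial average runs
  over included pixels only, so excluded pixels cannot leak into the
  analysis (verified by poisoning them with sentinel values in tests).
  For small synthetic fields the spatial kernel should be scaled with
  the field of view: 8 px on a ~320×240 recording corresponds to ~2 px
  on a 32×32 lattice, and the simulation suites use that scaling.
* **High-pass.**  0.5 Hz second-order Butterworth applied
  forward–backward (zero phase).  Zero-phase filtering is chosen so
  that event onsets — which cascade timing depends on — are not
  shifted.  The filter order is deliberately low; the goal is removal
  of slow baseline trends, not a sharp band edge.
* **Trim.**  The first 10 s are dropped (acquisition-onset artefacts).
  Default window length thereafter is 50 s = 2500 frames at 50 Hz.
* **SNR mask.**  Pixels whose time-averaged intensity falls below 50%
  of the maximum are excluded; the maximum is taken within the manual
  (bone-window) mask when one exists, else over the full frame.  The
  peak pixel always survives its own criterion, so the mask cannot
  come out empty.

## Point process

A pixel is active only at frames where its trace crosses
`mean + threshold_sd × S.D.` (default +1 S.D., both per pixel over the
analysed sequence) from below: `x(t) ≥ θ` and `x(t−1) < θ`; frame 0 is
never an event.  Dwelling above threshold yields a single event at the
upward crossing, and no pixel can be active on consecutive frames.
Per-pixel (rather than pooled) statistics were chosen to match the
pixel-wise baseline philosophy; the threshold is configurable for
sensitivity analyses (event counts are monotone non-increasing in it).
The conversion refuses binary input so an event movie cannot be
thresholded twice by accident.

## Cascades and κ

Two events belong to the same cascade iff they are at most one frame
apart and at the same pixel or 4-neighbouring pixels (8-connectivity is
a config option).  The implementation is a 3-D connected-component
labelling with the plus-shaped structuring element replicated across
the −1/0/+1 frame offsets; it is tested against an independent
brute-force flood fill on exhaustively enumerated tiny grids and random
larger ones.  Cascades touching the first or last frame are flagged
truncated and kept by default.  The traditional avalanche definition —
maximal runs of consecutive non-empty frames — is provided for
comparison.

κ compares the empirical size CDF to a discrete truncated power law
with exponent −1.5 on the observed range [z_min, z_max], at m = 10
logarithmically spaced evaluation points, as 1 plus the mean of
(F_ref − F_obs).  Conventions:

* Log spacing is the default because it is the only spacing that
  samples the tail of a scale-free distribution meaningfully; linear
  spacing is available for sensitivity checks.
* The sign convention makes heavy-tailed samples (empirical CDF lagging
  the reference) give κ > 1.
* κ is a deviation measure, not a hypothesis test: a sample following a
  power law with a different exponent will also move κ away from 1.
  The reference exponent is configurable; −1.5 is the mean-field
  critical-branching value and the default.
* κ requires at least two distinct sizes; per-region κ returns NaN with
  a reason string for regions with too few cascades (default minimum
  10).

The discrete power-law MLE (`fit_powerlaw_mle`) is a simulator
validation utility.  For lattice data the truncated variant (support
[z_min, max observed size]) should be used: the lattice imposes a
finite-size cutoff, and the untruncated zeta-normalised fit is biased
steep by roughly 0.06 on such samples.

## State entropies

Cortex-wide point-process frames are spatially downsampled by a factor
of 2 (box kernel; any-event rule for binary data) and clustered with
standard k-means (squared error, 10 seeded restarts, best inertia)
separately per 50 s window, so one window's state inventory cannot bias
another's.  H_state is the plug-in entropy of the visitation
distribution (0 … log₂ k bits).  H_trans applies the same formula to
the first-order transition distribution; by default this is the joint
distribution over ordered pairs (i, j) (0 … 2 log₂ k bits), with the
conditional entropy H(next | current) available as an option.  The
joint reading keeps H_state and H_trans on the same footing — both are
entropies of an empirical distribution — and still separates sequences
with identical visitation but different order (A,A,A,B,B,B vs
A,B,A,B,A,B).  Zero-probability terms contribute zero.

## Regional information

The mask is tiled with non-overlapping square regions (8×8 px default,
5×5 variant) anchored at the mask bounding-box origin; tiles containing
any excluded pixel are dropped so the regions partition clean cortex.
Each region's per-frame pattern is a binary word, one bit per pixel in
row-major order.  H_reg is the plug-in entropy of the word
distribution over the window; only observed words enter (the 2⁶⁴-word
alphabet is never materialised).

Mutual information between regions is the plug-in
H(x) + H(y) − H(x,y) over word codes.  Because plug-in MI of finite
samples is positively biased, a control MI — computed after uniformly
permuting the frame order of one sequence, which preserves both
marginals — is subtracted; the control is averaged over 20 permutations
by default (a single permutation is the n_shuffles=1 case; averaging
only reduces control variance).  Corrected MI of independent regions is
near zero and can be slightly negative.  Information transmission
IT_x sums corrected MI over regions y whose centre lies at least 10% of
the mask diameter from x; the exclusion guards against spurious
short-range correlations introduced by spatial smoothing.  Distances
are Euclidean between region centres in pixels, and the mask diameter
is the maximal pairwise distance between mask pixels.

Robustness variants repeat the analysis with (a) 5×5 regions, (b) 8×8
regions, (c) half spatial resolution (factor-2 any-event downsampling),
and (d) half temporal resolution (consecutive frames OR-ed, every
second kept).

## The synthetic generator

**Branching cascades.**  Activity lives on an H×W lattice.  Each
active pixel attempts to activate each of its 4 von-Neumann neighbours
in the next frame independently with probability σ/4 (clamped at 1), so
σ is the expected branching ratio: σ = 1 critical, < 1 subcritical,
> 1 supercritical.  A pixel already activated in a frame is not
re-activated within it.  Spontaneous seeds arrive per pixel per frame
with probability `drive_rate`; each starts a new cascade.  Ground-truth
labels are post-processed into connected components under exactly the
detector's spatio-temporal adjacency, so detection on noiseless events
reproduces the ground-truth partition bit-for-bit; every merge of
distinct lineages is counted as a collision, and runs in which any
frame exceeds 50% active pixels are flagged saturated.  Identical seeds
give bit-identical simulations.

Default `drive_rate` = 7×10⁻⁴ was calibrated once so that the critical
regime on a 64×64 lattice runs at ≈1% of pixels active per frame — a
sparse regime in which cascade collisions (≈13% of cascades) distort
the size statistics little.  At σ = 1.0 this produces ≥15,000 cascades
in 6000 frames with a size distribution whose truncated MLE exponent is
−1.54 ± 0.02 and κ = 1.01 ± 0.01 across seeds.

**The supercritical regime is burst-structured.**  A continuously
driven supercritical lattice does not produce many large cascades: it
ignites into an endemic phase in which drive seeds merge into one
system-spanning component (one giant cascade per run, κ slightly
below 1).  Cortical dynamics under anesthesia are instead bursty —
large waves that terminate.  The generator therefore emulates the
supercritical regime as many short independent sequences (default 200
segments of 40 frames at σ = 1.4, sparse drive 2×10⁻⁴), each starting
from an empty lattice, with cascades detected per sequence and sizes
pooled, exactly as per-sequence detection pools distributions on real
recordings.  This yields ≥3000 cascades with κ ≈ 1.09.

**Noise.**  Per pixel, the inverse rFFT of a template amplitude
spectrum with i.i.d. uniform random phases: the expected one-sided
periodogram equals the template exactly, pixels are mutually
independent, and the construction is trivially seedable.  The DC and
Nyquist bins are phase-constrained to keep the signal real.  The
canonical control is 1/f-spectrum noise scaled to 5% fluctuations
around a unit fluorescence baseline, run through the full preprocessing
and thresholding chain; the 8×8 spatial smoothing imposes a
characteristic cluster scale with a deficient large-size tail, giving
κ ≈ 0.92 < 1.

**Rendering.**  Events are convolved per pixel with a causal temporal
kernel (default exponential, τ = 0.1 s, peak 1) and added to scaled
noise plus a constant baseline, producing a movie the full pipeline can
ingest.  A threshold sweep on rendered data with moderate noise
recovers ≥85% of planted event onsets within one frame.

**The recovery and noise suites.**  The recovery suite emulates a
recording session during recovery from anesthesia: 20 windows whose
branching parameter steps 1.4 → 1.0, each window 25 burst segments of
50 frames on a 32×32 lattice, rendered (kernel + 1/f noise at 0.3
relative amplitude) and analysed through the full pipeline (2-px
spatial kernel, 2 s trim, k = 10 states, 8×8 regions, 20 shuffles).
The noise suite is 20 matched pure-noise windows.  On fixed seeds the
recovery suite reproduces: κ and mean κ_reg decreasing with window;
H_state, H_trans and mean H_reg increasing; κ_reg anti-correlated with
H_reg; and the noise suite shows no significant trend in any metric.

## Known limitations

* **Long-range information transmission has the wrong sign in this
  generator.**  On the lattice, the only mechanism correlating distant
  regions is co-membership in a cascade spanning the distance between
  them, and the prevalence of spanning cascades increases monotonically
  with σ.  Shuffle-corrected long-range MI — and therefore IT — is
  consequently *maximal in the supercritical regime* and decreases
  toward criticality, the opposite of what is observed in vivo, where
  anesthesia collapses pattern diversity and with it the information
  content of the (still large) waves.  Reproducing an IT maximum at
  criticality would require a generative model with long-range
  coupling and state-dependent pattern diversity, which is outside
  this generator's scope.  The corresponding suite assertions are kept
  and fail by design rather than being weakened.
* The simulator has no biophysics: no refractory period, no inhibition,
  no hemodynamic or heartbeat artefacts, no two-camera ratiometric
  structure.  Passing tests demonstrate the *statistics* of the
  pipeline, not fidelity to physiology.
* Plug-in entropies and MI are biased for small windows; the shuffle
  correction removes the leading MI bias but H_reg and H_state are
  reported uncorrected and should be compared only within matched
  window lengths, region sizes and alphabets.
* Edge pixels of the lattice have fewer than 4 neighbours, making the
  boundary slightly subcritical at σ = 1; this, with the finite-size
  cutoff, is why the truncated MLE is the right exponent estimator.
* Absolute κ from the rendered pipeline sits below 1 even at
  criticality (smoothing imposes a scale); within-suite comparisons
  and signs are meaningful, absolute rendered-pipeline κ values are
  not.

## Problem sizes

Test and validation runs are sized for a single CPU: the critical
sample uses a 64×64 lattice for 6000 frames (~15,000 cascades, ~7 s),
the supercritical sample 200×40 frames (~5 s), the noise control
64×64×2500 (~4 s), and each simulation suite 20 windows of 1250 frames
at 32×32 (~20 s).  All stochastic components take explicit seeds and
are bit-reproducible.
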