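# Methods

`telemeg` decodes behavioural states from video pose telemetry and uses
them to epoch and analyse wearable (OPM) MEG.  This note documents the
models, the numerical choices, and what the synthetic validation does and
does not establish.

## Behavioural segmentation

**Observations.** A pose estimator supplies per-frame (x, y) pixel
positions and confidences for 25 body key-points.  Positions with
confidence exactly 0 (or absent records) are treated as missing —
OpenPose-style detectors emit zero confidence for undetected parts — and
repaired by per-coordinate linear interpolation over frame index; edge
gaps take the nearest observed value.  Confidence is carried as metadata
but not otherwise used (no weighting).  Speeds are Euclidean step lengths
in pixels/frame; the first frame is padded with 0 so speeds stay
index-aligned with video frames, which keeps state sequences and frames
on one clock.  Each session is z-scored per key-point *before*
concatenation, so sessions with different cameras or distances are
commensurate; 50 Hz sessions are linearly interpolated to the common
30 Hz time base.  Normalisation and resampling are independent
operations and may be composed in either order; the recommended (and
default-documented) order is z-score first, then resample, matching how
mixed-rate sessions are usually harmonised.  The difference is
negligible for smooth speed traces because linear interpolation nearly
commutes with an affine per-column transform.

**Model.** A k-state hidden Markov model with a multivariate Gaussian
observation density per state (optionally a Gaussian mixture, `n_mix`;
the default is a single full-covariance Gaussian, which is stable on
z-scored speeds and is what the common neuroimaging HMM toolboxes do for
this configuration).  Defaults follow the study designs: k = 15 for the
single-subject block paradigm, k = 25 for multi-subject dance telemetry.

**Fitting.** Expectation–maximisation with k-means initialisation.
`n_restarts` seeded initialisations are each run for `select_iter` (15)
iterations; the best-likelihood candidate is run to convergence
(relative log-likelihood change < 1e-6, `max_iter` 500).  The short-run
selection exists because the practically relevant failure mode is a
local optimum in which one movement cluster is duplicated across two
states while another is missed; restarts escape it cheaply.  Every
covariance update adds a 1e-6 identity floor.  A state that loses all
responsibility is re-seeded once from a random frame; a second collapse
is an error.  The alpha/beta and Viterbi recursions are scaled (not
log-space) and JIT-compiled; emission quadratic forms and M-step moments
are arranged as large matrix products.  Viterbi ties break toward the
lower state index.  Fitting is bit-reproducible for a fixed seed.

**Labelling.** Each experimental condition claims the state whose
binarised Viterbi path has the highest Jaccard overlap with the
condition's cue boxcar; claims are resolved greedily in descending
Jaccard order so no two conditions share a state.  Unclaimed states form
the pooled "rest" meta-state.  For unconstrained movement the per-state
regression heat maps (mean z-speed when the state is on minus off — the
OLS slope on a binary regressor with intercept) characterise which body
parts a state moves, and limb states are pooled into meta-states by
logical OR of their paths.

**Metrics.** Per-frame multi-class confusion; per-class Dice
2TP/(2TP+FP+FN); macro F1 = unweighted mean Dice; one-vs-all AUC via the
midrank Mann–Whitney statistic; permutation p-values from circular
time-shifts of the state path (shifts preserve run-length structure
while destroying alignment; p = (1 + #{null ≥ obs})/(1 + n_perm));
split-half cross-validation fits and labels on half the sessions and
decodes the held-out half with the fitted model.

## MEG conditioning

Anti-aliasing uses a 60th-order Kaiser-window FIR (beta chosen for 60 dB
sidelobe attenuation) at 500 Hz, applied forward–backward, followed by
integer decimation to 2 kHz.  Zero-phase filtering is used throughout
because the downstream envelope analyses are phase-insensitive.
Behavioural state paths are attached as trigger channels by
nearest-neighbour lookup on the shared hardware clock; trigger channels
are never filtered.

**Homogeneous field correction (HFC).**  Environmental interference at
the array scale is modelled by the lowest-order regular expansion of an
external field: 3 uniform components and the 5 independent components of
a symmetric traceless gradient tensor, evaluated at sensor positions
(referenced to the array centroid) and projected on sensor orientations.
The 8 columns are orthonormalised by QR and projected out:
P = I − QQᵀ.  Channels whose post-HFC residual RMS amplitude exceeds
100 pT are disabled, the projection undone, and HFC recomputed over the
remainder, iterated to a fixed point (≤ 5 rounds; the threshold is
dimensionally an amplitude, so it is applied to the RMS, and it is
configurable).  The same projector multiplies the lead fields so model
and data live in one subspace.

## Source reconstruction

Sources live on a 5 mm lattice clipped to a spherical volume.  The
forward model is the closed-form field of a current dipole in a
homogeneous conducting sphere; it is exactly linear in the moment and
exactly silent for radial dipoles, which gives sharp unit tests (the
package also accepts externally computed lead fields for mesh-based
models).  The lattice centre is offset from the sphere origin by half a
step because the forward model is singular at the exact centre.  Each
point's 3-orientation lead field is SVD-reduced to the two strongest
directions.

The inverse is a scalar LCMV beamformer.  The covariance is
eigendecomposed and the 8 smallest eigenpairs discarded — matching the
rank lost to HFC — before pseudo-inversion.  Per point, the source
orientation maximises the noise-normalised output variance
(uᵀLᵀC⁺Lu)/(uᵀLᵀC⁺C⁺Lu), a 2×2 generalised eigenproblem; the weights
w = C⁺l/(lᵀC⁺l) satisfy unit gain wᵀl = 1 with l the unit-norm-orientation
lead field.  Orientation signs are fixed by the first non-zero
component.  Variance maps can be depth-normalised by wᵀw (neural
activity index); the GLM contrasts do not need it because they compare
conditions within a point.  Covariance is estimated from the whole
band-passed recording, per dance/session.

## Envelope GLM

First level, per source: the 8–30 Hz source time course is converted to
its Hilbert amplitude envelope, log-transformed (floor 1e-30), and
regressed (OLS) on the design: for the motor task, active (cue boxcar
0–4 s or the HMM state path), rest boxcar 6–10 s and a mean column; for
the dance, the five limb meta-states plus a mean and a linear trend
scaled to [−0.5, 0.5] (meta-states are mutually exclusive in time by
construction, so the design stays well conditioned; overlap beyond 1 %
of samples warns).  Regressors are not convolved with any response
kernel.  First-level standard errors are not autocorrelation-corrected:
only the betas propagate to the second level, so second-level inference
is unaffected.

Second level: a paired t between per-trial active and rest beta images
(identical to the one-sample t on differences), or a 1×n factorial over
meta-state images across dances with arbitrary contrasts.  Family-wise
error is controlled by max-|t| permutation — sign flips of paired
differences or within-unit level permutations — rather than volumetric
random-field theory: the permutation approach is assumption-light and
exactly verifiable by simulation at this scale, and the image metadata
records the method.  Display thresholding at 70 % of the extreme
t-statistic is cosmetic only.

## Synthetic ground truth

The generators emulate the study conditions rather than idealised toys:

* **Block telemetry** — 4 limb conditions × 15 trials × 2 blocks in
  pseudorandom order, 4 s cue epochs, 10–11 s inter-trial intervals,
  30 frames/s.  The cued limb's key-points (3 per arm, 6 per leg)
  receive compact positive speed bursts from the cue until a per-trial
  *cessation lag* ~ N(1.0, 0.2) s after the cue ends, mirroring the ~1 s
  late stop seen in subjects; movement durations therefore exceed the
  cue by about the mean lag.  Idle behaviour switches among 8 latent
  "fidget" regimes (per-key-point jitter scales, 2–6 s dwells), which is
  both what idle humans do and what gives a k = 15 HMM its ~11 rest
  states; fidgeting is suspended while an instructed movement is
  executed.  Brief spurious movements are injected at ~1/min.  Positions
  integrate the target speeds along smooth random-walk directions, so
  differentiation recovers them exactly.
* **Dance telemetry** — a fixed 158 s schedule (left arm, right arm,
  left leg, right leg verses, each followed by a both-arms chorus) with
  per-session onset jitter ~ N(0, 0.5 s).
* **Sensor array** — Fibonacci-spiral cap of triaxial magnetometer sites
  at scalp radius 9 cm + 2 cm standoff.  Triaxial sites are the default
  because measured HFC signal attenuation for dipolar sources is
  < 0.1 dB on a ~64-channel triaxial array versus several dB for
  radial-only caps; the study hardware likewise mixed dual-axis and
  triaxial sensors.
* **MEG** — per behavioural state one planted cortical dipole (4 limb
  sources on the lattice, arms lateral, legs medial, contralateral;
  the both-arms state drives *both* arm sources, which is what makes the
  "single arm minus both arms" contrast isolate the other arm).  Source
  dynamics are 8–30 Hz filtered noise — not sinusoids — so envelopes
  have realistic variability; the envelope is multiplied by
  (1 − erd_depth), default 0.5, while the state is active
  (event-related desynchronisation).  Interference is a < 5 Hz drift
  injected exactly through the 8 HFC basis patterns at 1 pT RMS; sensor
  noise is white at 15 fT/√Hz; dipole moments default to 20 nAm.

**What passing does not show.**  The generators are Gaussian/indicator
caricatures: real telemetry has tracking glitches, occlusions and
correlated whole-body motion; real MEG has coloured noise, muscle
artefact, cardiac fields, head movement inside the array, and
interference that is not exactly low-order in space.  Recovery at the
planted effect sizes therefore validates the *implementation* (and the
method's behaviour under its own assumptions), not clinical-grade
performance on real recordings.  Real-data headline figures (e.g. a
labelled-state Jaccard of ~0.65 against cue timings) are not
reproducible from synthetic data because they depend on the subjects'
actual behaviour and a toolbox HMM with unstated initialisation.

## Problem sizes used in validation

The shipped tests and `scripts/acceptance.py` run, on one core: the full
block design (≈ 52 000 frames, k = 15, 3 restarts) for 5 and 2 seeds
respectively; 10 synthetic dances at 250 Hz against a 5 mm lattice of
≈ 7 000 points (sources are analysed in chunks of 1024 to bound memory);
20 and 10 beamformer seeds on a ≈ 4 200-point grid; and 200- and
100-repetition family-wise-error calibrations with 99 permutations
each.  The 250 Hz simulation rate keeps the 8–30 Hz band comfortably
below Nyquist while making hour-scale runs tractable; results are not
sensitive to it.

## Known limitations

* The spherical forward model ignores realistic conductor geometry; use
  the lead-field import path for mesh-based models.
* `label_states` assigns exactly one state per condition; conditions
  genuinely split across several states are only recovered via manual
  meta-state pooling.
* The bad-channel rule assumes interference dominates bad channels'
  residuals; a channel that is merely dead (flat) is not flagged.
* Permutation FWE needs ≥ 8 exchangeable units; small designs must fall
  back to uncorrected inference.
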