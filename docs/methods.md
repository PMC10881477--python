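# Methods

## Protocol engine

Calibration follows the three-press rule: the participant presses at
maximum three times for at least 1 s; MaxF is the maximum of the three
per-press means, each mean taken over exactly the first `round(fs)`
samples of its press. The target force is 0.15 · MaxF.

The visual mapping is the affine cursor rule
`position = (F_p − F_t) · G + F_t`; the gains 0.04 (low) and 6.9 (high)
are stored as dimensionless multipliers numerically equal to the visual
angles used on screen. Screen geometry (90 cm viewing distance) is
carried as optional metadata only — the analysis never needs it.

The auditory mapping is under-determined by its three published anchors
(120–880 Hz range, 440 Hz at match, linearity in the force error). We
resolve it as a *signed* linear map — force below target lowers the
pitch — with the slope fixed so that zero force at unit audio gain maps
to the 120 Hz lower anchor, and symmetric clipping at 120/880 Hz. Audio
gain levels default to 1 (low) and 172.5 (high), preserving the visual
high:low ratio 6.9/0.04. Both choices are configuration, not physics;
whether the original task used a signed or absolute distance, and what
numeric audio gain, cannot be recovered from the published description.

Schedules are always vo → va → ao in blocks of four; within each block
the gain sequence is a seeded permutation of {low, low, high, high}.

## Synthetic cohort model

The generator encodes effect structure, not tremor mechanism. Per trial
the task-window force is

    F(t) = F_t · [1 + d(t) + A sin(2π f_tr t + φ) + ε(t)],
    A = a₀ · (1 + β_type · w_type · 1[gain = high]),

with a₀ the baseline tremor amplitude (normalized units), β the gain
sensitivity, w the modality weight {vo: 1.0, va: 1.2, ao: 1.0} (the
combined condition carries the strongest effect), d(t) low-passed
Gaussian drift (≤ 1.5 Hz, SD 0.05 — voluntary corrective movement) and ε
white sensor noise (SD 0.005). Rest windows are near-zero force; the
rest/task transitions use 0.5 s raised-cosine ramps so the epoch edges
inject no broadband step into the tremor band. Tremor peak frequencies
are drawn clear of the 4/12 Hz band edges (clipped to [4.5, 11.5] Hz;
patients centred at 6 Hz, controls at 9 Hz), because a sinusoid at the
band edge necessarily loses up to half its spectral mainlobe outside the
integration band — a property of band-power estimation at any finite
resolution, not of this implementation.

Pupil diameter is `base + arousal[type, gain] · ramp(task) + slow noise`
(noise low-passed at 0.5 Hz, SD 0.05 mm); the dilation ramp rises
linearly over the first 5 s of the task and plateaus, so its analytic
task-window mean is 1 − 5/60 ≈ 0.917. Blinks are a Poisson process
(default 0.08 /s — blink suppression during demanding visuomotor
tracking — 0.2 s duration): diameter collapses with 20 ms lid ramps,
confidence drops below 0.3, and the occluded pupil-centre estimate jumps,
giving the gaze-acceleration transient the detector keys on. Clean gaze
is a smooth fixation wander whose faster component's *acceleration*
amplitude is drawn in a fixed narrow range (40–60 px/s²), continuous
across trials; its acceleration is therefore bounded well below the
robust-z threshold. Real eye-tracker noise has heavier acceleration
tails, so on real data the acceleration criterion would flag a small
share of clean samples that this generator does not emulate — passing
the false-masking bound here certifies the pipeline's logic, not a field
false-alarm rate. Streams share one ideal clock; acquisition jitter is
not simulated.

### Group effect defaults

Multiplicative participant parameters are lognormal around their
medians; a median of exactly zero is exactly zero (a true null).

| parameter | pET | HC |
|---|---|---|
| tremor amplitude a₀ (median, σ_ln) | 0.03, 0.25 | 0.012, 0.25 |
| gain sensitivity β (median, σ_ln) | 0.4 all types, 0.25 | va only 0.2, 0.25 |
| pupil Δ(high−low) mm (median, σ_ln) | va 0.25, ao 0.20, vo 0 | 0 |

These defaults were fixed once, by an up-front power analysis rather
than by fitting: published figures do not permit recovery of the true
effect sizes in normalized power units, so the defaults are calibration
knobs chosen to realise the reported *qualitative* pattern with high
per-test power. Because the tremor contrast per participant is a product
of lognormal factors, its coefficient of variation — and hence the
paired effect size d_z ≈ 1/CV ≈ 1.6 — is scale-free; at n = 14 this
gives per-test power above 0.999, while every truly null condition stays
at the nominal 5% false-positive rate. The probability of reproducing
the complete nine-way significance pattern is therefore bounded by
0.95³ ≈ 0.86 from the three must-be-null tests alone; the observed rate
is ≈ 0.85–0.89.

### Two generation paths

The stream path renders full 80 Hz force, 240 Hz pupil and marker
streams. The feature path (`simulate_trial_features`) draws per-trial
*measured* features directly from the same statistical model: analytic
sinusoid band power A²/2 plus the white-noise band floor
(σ² · 8/40) with 3% Welch estimation scatter, realised drift power with
18% scatter, and the baseline-corrected pupil mean with its 0.025 mm
slow-noise scatter. Calibration-scale experiments (1,000 null cohorts,
200 pattern-recovery studies, the sequential power curve) run on the
feature path; its agreement with the waveform chain is itself under
test (sinusoid band power within 10% through the full spectral chain,
pupil contrasts within the slow-noise scatter, and a direct
feature-vs-waveform comparison of the tremor power's deterministic
part). Stream-path problem sizes in the test suite (sessions of 12
trials, cohorts of 2–14 per group) were chosen as the smallest that
exercise every contract.

`CohortEffects.null()` zeroes every effect *and* degenerates the
participant-level spreads, making trials exchangeable across the whole
cohort. This is deliberate: the trial-level fixed-effects ANOVA treats
trials as independent, so under participant heterogeneity it is
anticonservative (pseudo-replication) — a known limitation of that
design, documented below — and its nominal null is iid trials.

## Force features

Normalisation divides every sample by 0.15 · MaxF, so the target reads
1.0 and all features are scale-free (scaling raw force and MaxF together
changes nothing, which is tested exactly). The band-pass (5th-order
Butterworth, 0.1–12 Hz, second-order sections) is applied
forward-backward: offline analysis needs no causality and zero phase
keeps epoch boundaries aligned; single-pass filtering remains available
through the same SOS design. The continuous stream is filtered before
epoching, so no within-epoch edge trimming is needed.

Welch parameters — 4 s Hann, 50% overlap, density scaling — give
0.25 Hz resolution, putting the 3 and 4 Hz band boundaries exactly on
the frequency grid; the originating analysis did not publish its window
choice, so this is the package's own documented default, configurable.
Band power is the trapezoidal integral of the PSD (units: power), not
the mean PSD. Mean force and RMSE (root of the mean squared deviation of
the normalized samples from 1.0) are computed on the unfiltered epoch.

## Pupil features

Blink detection flags samples with confidence < 0.6 (vendor-documented
convention) or robust gaze-acceleration z > 3 (median/MAD); runs closer
than twice the 0.1 s pad merge, and every run is padded 0.1 s per side.
The published description names the two signals but no cut-offs; all
three numbers are configuration recorded in the output metadata.

The 120-sample Gaussian kernel "span" is read as total support
(≈ 0.5 s at 240 Hz) with σ = span/8 = 15 samples, so the ±4σ tails fit
inside the span. Interpolation is a normalized convolution: the kernel
is FFT-convolved with the zero-filled trace and with the validity mask,
and the ratio replaces only the missing samples — valid samples are
never smoothed. Gaps wider than the kernel fill iteratively from their
edges; a few fixed-point refinement passes then re-smooth the filled
positions against their full neighbourhood, removing the one-sided
centroid bias a single pass leaves on sloped signals (reconstruction
error on a 0.2 Hz test oscillation drops from ≈ 6% to ≈ 1% of
amplitude). Epochs with ≥ 50% missing samples are rejected rather than
invented.

Baseline correction subtracts the mean of the half-open window
[−10, −2) s before task onset (inside the rest period) from every sample
of the epoch, individually per epoch; the trial feature is the mean over
the half-open [0, 30) s task window. Both steps are exactly invariant to
adding a constant to the raw trace.

## Statistics

The primary outcome is the high-minus-low contrast per (participant,
modality). The default unit pairs the k-th low with the k-th high trial
in presentation order, giving 2 contrasts per cell and 56 per modality
at n = 14/group — matching the ≈ 53 degrees of freedom of the reported
between-group t-tests; a participant-level unit (averaging the two
trials per gain first) is available. Within-group gain effects default
to a paired t-test on participant means, replaced by Wilcoxon
signed-rank when Shapiro–Wilk rejects normality of the differences at α;
the branch taken is always recorded.

The trial-level ANOVA runs one one-way fixed-effects model per factor
(group; feedback type): the reported residual degrees of freedom differ
between factors, which is incompatible with a single two-way model, and
separate one-ways reproduce that df pattern. Being trial-level, it is
anticonservative under participant clustering; it is retained as
specified for the control outcomes and calibrated against its
exchangeable null.

Covariates use a Shapiro-gated Mann–Whitney/t-test (with an override to
force either branch); correlations gate Pearson vs Spearman on
Shapiro–Wilk (and Levene across groups when a grouping is given), with
partial correlations by residualisation via pingouin. No
multiple-testing correction is applied by default (per-condition
p-values are reported uncorrected); a Holm adjustment column is
available as an option.

`sequential_power` simulates the sequential accrual design: each study
grows both groups in step to the cap (n = 25), testing the primary
between-group contrast after each accrual; it reports the power curve
over n, the smallest n reaching the 0.80 target, and the per-study
distribution of the first significant interim analysis. At the default
effect sizes the target is met at the smallest n examined — the design's
cap is generous for effects of this size.

## Numerical and I/O choices

All randomness flows from one master seed through
`numpy.random.SeedSequence` spawning (participant → session → trial), so
cohorts, feature tables and whole pipeline runs are bit-reproducible;
TSV output uses fixed `%.10g` formatting, making repeated runs
byte-identical. Timestamps are seconds as decimal text; all epoch
windows are half-open `[onset, offset)`. Markers are sorted on load, so
row order on disk is immaterial. Band edges lying off the spectral grid
raise no error (trapezoid over the covered bins); bands outside the grid
do. Degenerate inputs follow one rule: impossible analysis states
(constant correlation input, empty groups, epochs shorter than one
window) raise typed errors, while legitimate extremes (identical high
and low values, zero-variance ANOVA cells) return the no-effect answer
with a degeneracy note.

## Known limitations

* The generator reproduces effect structure, not biomechanics: no
  tremor-circuit dynamics, no feedback-loop coupling between displayed
  error and motor output within a trial (the gain acts on the tremor
  amplitude parameter directly), no learning or fatigue across trials.
* Clean-gaze acceleration is bounded by construction; real pupil data
  would yield some acceleration-triggered false masking at z > 3.
* The trial-level ANOVA inherits the pseudo-replication problem on
  heterogeneous cohorts; a mixed-effects alternative is out of scope.
* Audio-channel gain magnitudes and the signed-vs-absolute pitch mapping
  are assumptions exposed as configuration.
* True effect sizes in normalized power units are unknown; all
  recovery and power results are statements about the configured
  defaults, not about the human cohort.
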