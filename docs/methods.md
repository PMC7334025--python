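# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `auriclab`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Signal chain

### Filtering

All filters are applied forward–backward (zero net phase; the effective
magnitude response is the squared single-pass magnitude). Role-specific
chains at the 9600 Hz acquisition rate:

| role | chain | rationale |
| --- | --- | --- |
| auricular EMG | 10–1000 Hz FIR (order 2000, Hamming windowed-sinc) + 50 Hz IIR notch (2nd order, Q = 30) | surface-EMG band; mains rejection |
| neck EMG (SCM) | 60–1000 Hz FIR (order 2000) | suppresses slower postural drift on the neck channel |
| EOG | 0.01–20 Hz Butterworth bandpass (order 2, second-order sections) | gaze signals are slow; drift below 0.01 Hz removed |

The FIR design method is windowed-sinc (Hamming): deterministic, linear
phase, and fully specified by family and order. Long FIR chains are
evaluated in the frequency domain: a linear-phase kernel convolved with its
time reverse is itself exactly zero-phase, so one centered FFT convolution
of the reflect-padded signal (pad length 3× the order, capped at signal
length − 1) reproduces the forward–backward result at O(N log N). IIR
chains are realized as second-order sections and run through
`sosfiltfilt` for stability. The notch is applied after the bandpass; the
order is exposed in the configuration and does not matter for the linear,
zero-phase chain beyond edge effects.

Downsampling to 2400 Hz is plain sample picking (every 4th sample): the
1000 Hz low-pass edge already bounds the spectrum below the new 1200 Hz
Nyquist, so no additional anti-alias stage is inserted, and the operation
is exactly index-invertible for tests.

### RMS envelope

The envelope is a sliding root-mean-square, 150 samples (62.5 ms) with step
1 at 2400 Hz. Windows are clipped at the signal edges (the mean runs over
available samples). The window *trails* the output sample by default
(`rms_align="causal"`): a centered window smears burst energy about half a
window (~31 ms) before the true onset, which would bias any
threshold-crossing onset estimate early by ~30 ms; with a trailing window
the envelope cannot rise before the burst does, so onset estimates carry
only a small positive bias (threshold crossing partway up the rise, a few
ms). Amplitude measures over 100–1500 ms are insensitive to the alignment
choice; `rms_align="center"` is available for waveform display.

### Exogenous measures

Epochs span [−3 s, stimulus offset + 3 s) around onset; baseline correction
subtracts the pre-stimulus envelope mean. Normalization divides each group
of four epochs (one muscle channel × one stimulus type, one epoch per
speaker) by the largest voltage at any time point within those four
baseline-corrected epochs — the signed maximum by default, since a
baseline-corrected envelope exceeds baseline positively at response peaks;
an absolute-value variant is selectable (`norm_mode="abs"`). Cells average
variable-length epochs after truncating to the shortest member; the
shortest possible epoch (1.7 s stimulus + 3 s post) comfortably covers the
100–1500 ms measurement window. The 50–300 ms phasic measure is computed
per trial and summarized as mean and SD across the trials of a cell.

Onset latency of a (grand-average) waveform is the first post-stimulus time
the waveform exceeds its own pre-stimulus mean + 3 SD and stays above for
≥ 10 ms. The estimator inherits a small positive bias (~5–8 ms at the
default generator SNR) from crossing partway up the 20 ms burst rise; the
onset-recovery study documents the achieved accuracy.

### Endogenous measures

Each run is reduced per channel to mean energies of 1-s non-overlapping
segments (trailing partial segment discarded). Artifact rejection masks
segments deviating from the run mean by more than 2 SD, with mean and SD
computed in a single pass over all segments — the artifacts being tested
are included in the statistics, which keeps the rule simple and
reproducible; an iterative variant was considered and rejected as
under-specified.

Condition normalization (`run_norm="max_condition"`, the default): per
channel, the four condition mean energies (left/right × front/back runs)
are divided by their maximum across the runs, giving unitless values in
(0, 1] that preserve relative condition differences. The alternative
reading — dividing each run's mean by that run's own largest retained 1-s
segment (`"max_segment"`) — is selectable but makes the measure
scale-invariant per channel and therefore blind to tonic gain differences
between conditions; it is retained for completeness, not used by default.

The time-resolved view computes 10-s segment energies for the pooled ipsi
and contra channels and normalizes each bin's pair to unit sum, so the
traces are lateralization proportions (0.5 = no lateralization); a 5-min
run yields 30 points. Zero-energy bins are marked missing.

### Octave filter bank

The eight-band decomposition is the à-trous stationary wavelet transform
(db5 — "5th order Daubechies", 10 taps — with normalized filters), computed
by PyWavelets. All bands have the input's length (nonsubsampled), detail
level *j* nominally covers [fs/2^(j+1), fs/2^j), and the transform is
circularly shift-equivariant. Signals are symmetrically padded to a
multiple of 2^8; the untrimmed coefficients are retained so that
reconstruction is exact to numerical precision, and modified (e.g. zeroed)
bands are overlaid onto the stored coefficients before inverse
transformation. The reported "eight frequency bands" are the detail levels;
the final approximation is kept internally for reconstruction but excluded
from statistics. Band energies are computed on raw band samples (squared),
consistent with the broadband energy definition; no rectification is
applied.

### Oculomotor controls

EOG calibration is an ordinary least-squares line from voltage to degrees
(positive = rightward), fit on any paired series spanning the ±35° tracking
range; the residual SD is reported as the per-participant resolution.
Macrosaccade detection thresholds the 20 ms-smoothed derivative at 30°/s,
merges supra-threshold stretches separated by < 20 ms, and keeps events
with |amplitude| ≥ 2° — defaults chosen to capture macrosaccades given the
1–2° resolution of EOG. The event-locked control reports
|mean post-event gaze − pre-event mean| and flags "no systematic diversion"
when that shift stays within one SD of the gaze signal. Saccade–stimulus
timing density is a rate histogram of saccade onsets relative to the
nearest preceding stimulus.

## Statistics

The mixed repeated-measures ANOVA (2 within × 2 within × between-group) is
computed from sums of squares via per-subject orthogonal contrasts: with
two-level within factors, each within effect reduces to a one-way analysis
of a contrast score (subject mean → between effect; correspondence
difference → correspondence and correspondence × group; likewise
anteriority and the interaction contrast). Contrasts are scaled so the
stratum sums of squares match the classical ANOVA table. Main effects test
the unweighted mean of group means (Type III), so unequal group sizes
(16/12 and 10/11 in the default cohorts) reproduce conventional
statistical-package output; error strata are subjects-within-groups for the
between effect and the corresponding subject × factor stratum for each
within effect. No sphericity correction is applied — every within effect
has one numerator degree of freedom. p-values come from the F survival
function (regularized incomplete beta); ηp² = SS_effect/(SS_effect +
SS_error), algebraically F·df₁/(F·df₁ + df₂).

The covariate screen enters a cell-wise covariate (e.g. neck-EMG energy or
EOG shift), reduced by the same contrasts, into each stratum's linear model
and tests effects by Type III general linear hypotheses. The underlying
supplementary model was not fully specified; this ANCOVA-style extension is
an approximation and is labeled as such. A covariate identical to the
response saturates the model; the screen then reports the effect as fully
absorbed (F = 0) rather than a 0/0 failure. Constant covariates are dropped
with a collinearity warning.

With a single group level the group terms are omitted and the analysis
reduces to the pure within-subject design.

## Synthetic data

EMG is amplitude-modulated band-limited Gaussian noise — the convolution
view of the interference EMG: channel = noise_floor · (1 + modulation) ·
unit-RMS carrier (4th-order Butterworth band, default 20–500 Hz), plus
50 Hz line interference with random phase and white sensor noise.

Exogenous modulation: per event, a raised-cosine rise (20 ms) beginning
70 ms after stimulus onset, plateau until stimulus offset, raised-cosine
decay (200 ms); gain = burst_gain × 2 (ipsi) × 1.5 (back) for PAM/AAM/TAM,
flat for SAM, times a lognormal trial amplitude (CV 0.3) — the 2:1 and
1.5:1 ratios encode the qualitative response ordering (largest
posterior-ipsilateral) that the analyses are expected to recover; true
single-trial variability is only qualitatively known, hence a tunable CV
rather than a fidelity claim. Sessions draw 9 stimulus types × 4 speakers
in random order, durations uniform on 1.7–10 s, onset-to-onset intervals
uniform on 15–40 s.

Endogenous modulation: constant tonic level per run, gain = tonic_gain × 2
(ipsi, PAM/AAM/SAM) × 1.3 (back), flat laterality for TAM, a linear decline
(30%) for PAM across the run, and lognormal run-to-run gain variability
(CV 0.2) so condition means carry realistic within-subject noise. Artifact
bursts are band-limited (they must survive the analysis bandpass), Poisson
in number, each confined to one 1-s segment and scaled so that segment's
energy reaches 10× the clean level. The EOG channel is gain × gaze + offset
with fixations, reading-like saccades (Poisson rate 0.25 /s, amplitudes
2–12°, 30 ms transitions, confined to ±25°) and 1° resolution noise.

Default cohorts follow the study design the package analyzes: 16 young +
12 old subjects (exogenous) and 10 + 11 (endogenous, four 5-min runs each).
Everything is deterministic given a seed (per-subject and per-run seeds are
spawned from one seed sequence), and GroundTruth objects record injected
per-event amplitudes, artifact segments and saccades.

What the generator does *not* emulate: real motor-unit statistics,
inter-muscle crosstalk/volume conduction, electrode impedance drift,
heterogeneous response morphologies across subjects, or any acoustic
stimulus content. Passing recovery tests therefore demonstrate that the
pipeline measures what the model injects — not that real recordings meet
the model's assumptions.

## Simulation-study problem sizes

Reduced-scale presets keep studies tractable on one CPU while preserving
the decisions under test: the type-I calibration and effect-recovery
studies run ~30 s sessions at 480 Hz raw / 240 Hz processed (band edges,
filter orders and the 62.5 ms RMS window rescaled proportionally; one
muscle pair; 28 and 12 subjects respectively); onset recovery uses 2400 Hz
raw / 1200 Hz processed for millisecond resolution with 12 subjects and 16
events. Statistical calibration does not depend on the sampling rate; the
achieved rates and errors are whatever the studies compute.

## Known limitations

- The EDF writer emits plain continuous 16-bit EDF (no annotations
  channel); events live in the TSV sidecar. Recordings that are not a
  whole number of seconds are zero-padded to the last 1-s record, with a
  logged warning.
- The onset estimator's threshold-crossing bias depends on response rise
  time; it is characterized here only for the generator's raised-cosine
  rise.
- The covariate screen approximates an unspecified supplementary model.
- Epoch averaging truncates to the shortest epoch rather than
  interpolating to a common length; grand averages across stimulus
  durations therefore represent the common time support only.
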