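# Methods

This note documents the models, parameter choices and numerical
conventions behind `somnarch`, and what the synthetic-data validation
does and does not establish about real recordings.

## Scoring model and hypnogram rules

The analysis operates on vigilance-state labels (WAKE/NREMS/REMS) on a
strict 4-s epoch grid; a trailing partial epoch of signal is dropped,
never padded. Labels are an *input* — the package does not classify
states from raw EEG/EMG.

**State-change smoothing.** A left-to-right scan accepts a change of
state only when the new state is sustained for at least `min_run = 3`
consecutive epochs (12 s); shorter intrusions are relabelled to the
ongoing state. The first run of the recording, however short, defines
the starting state — the rule defines *changes*, so initialization is
a convention; this choice is symmetric and idempotent (smoothing a
smoothed hypnogram is a no-op, which the tests verify). Artifact
epochs are transparent: skipped when counting consecutive epochs,
retained unchanged in the output, and excluded from every numerator
and denominator downstream. This treatment assumes artifacts are a
negligible fraction of data (the emulated protocol reports <0.015%);
none of the metrics would be trustworthy under heavy artifact load.

**Artifact marking.** Where the original protocol thresholded
artifacts manually, `somnarch` uses a reproducible automated stand-in:
an epoch is marked when its peak absolute EEG deviation from the
median exceeds `artifact_sd` robust standard deviations
(1.4826 × MAD) of the whole trace. The default is 15 robust SD.
The value separates the two amplitude populations the generator
produces: movement artifacts at 20 robust SD versus spindle bursts,
whose peaks reach 7–11 robust SD of the mixed-state trace; a
noticeably lower threshold starts flagging genuine spindles as
artifacts and silently depresses every spindle metric. Marking is
monotone in the threshold, and the marked fraction is logged so a
user can notice a badly calibrated threshold.

**Phases.** ZT0 = lights-on; windows are half-open, light [0, 12) and
dark [12, 24) hours, so each epoch belongs to exactly one phase and a
23-h ZT0-anchored recording splits into 10,800 light and 9,900 dark
epochs. Transitions are counted between consecutive non-artifact
epochs after smoothing; a change straddling the boundary is assigned
to the later epoch's phase, and per-hour rates divide by the phase
duration (12 vs 11 h are not interchangeable). Bout summaries use the
median duration; the mean is available but secondary, because bout
distributions are heavy-tailed.

## Spindle detector

Band-pass 10–15 Hz (Butterworth order 4, applied forward–backward so
event timing is not phase-shifted), sliding centered 750 ms RMS,
raised to the third power. Cubing sharpens the contrast between burst
and background; it is also why the detector is scale-free — both
thresholds are multiples (1.0× lower, 2.5× upper) of the mean cubed
RMS, so multiplying the EEG by any constant leaves the detected event
set identical (tested exactly).

Conventions that the two-threshold rule itself does not fix, resolved
as follows:

- the threshold baseline is the mean cubed RMS over **NREMS samples
  only** (non-artifact), so state composition and group differences in
  WAKE amplitude cannot move the operating point;
- an event is a maximal region above the lower threshold containing at
  least one sample above the upper threshold; its boundaries are the
  lower-threshold crossings;
- events are kept only if 0.5 s ≤ duration ≤ 2 s and the region lies
  entirely inside NREMS epochs — boundary-crossing events are rejected
  rather than truncated, keeping duration semantics clean;
- `normalized_amplitude` is the peak band-passed amplitude divided by
  the mean NREMS band-passed RMS (unit-free, comparable across
  amplifier calibrations).

A property worth knowing: on a *spindle-free* Gaussian background the
upper threshold sits only ~1.4 standard deviations above the mean of
the band envelope (whose relative spread is set by the 5 Hz bandwidth
× 750 ms window product), so sporadic threshold crossings are
expected. In realistic use the events themselves lift the mean cubed
RMS several-fold, pushing the upper threshold far into the background
tail; measured precision on simulated 23-h recordings is 1.0.

## Spectral statistics

The PSD estimator is the mean of Hann-windowed periodograms over the
4-s scoring epochs of one state (Welch's method with the segmentation
aligned to the scoring grid), giving 0.25 Hz resolution and satisfying
Parseval within the window correction. Each animal's spectrum is
normalized to percent of its total 0.5–45 Hz power (Riemann sum, so
the normalized values integrate to exactly 100 over that range) before
any cross-animal statistic; dB/Hz conversion exists only at the
reporting layer, statistics stay linear.

The band table is taken literally: δ 0.5–5, θ 6–9, α 10–15,
η 16–22.75, β 23–31.75, γ 31.75–45 Hz. The gaps (5–6, 9–10, 15–16,
22.75–23 Hz) belong to no band — band powers deliberately sum to less
than the total — and the shared β/γ edge at 31.75 Hz is an endpoint of
both trapezoidal integrals.

**Bootstrap.** All group CIs are percentile bootstraps resampling
*animals* (the unit of observation; epochs within an animal are not
independent), B = 10,000, seeded. Two small-sample caveats, both
measured: (i) the true coverage of the percentile CI for a median of
n = 8 Gaussian animals is ≈92–95%, slightly anti-conservative at the
nominal 95%; (ii) the bootstrap distribution of a median of 8 is
discrete, so CI endpoints carry Monte-Carlo jitter proportional to the
between-animal spread when a percentile falls between atoms.

**Group comparison.** ROC-AUC per frequency bin or band via the rank
identity AUC = U/(n_A·n_B) with ties counted ½ (verified exactly
against exhaustive pair enumeration), bootstrap CI over both groups;
per-animal summaries are the default observations. Student's
two-sample t-test (pooled variance, two-tailed) with raw p-values and
α = 0.05 flags, no multiplicity correction by default — matching the
per-metric testing style the pipeline emulates; a Benjamini–Hochberg
pass can be applied downstream by the user.

## Synthetic-data generator

The generator provides ground truth, not biophysics. Vigilance
dynamics are a first-order Markov chain at epoch resolution with
separate light/dark matrices; the defaults are dwell-time-realistic
(minutes-long WAKE bouts, longer in the dark; 1–2 min NREMS bouts;
~1 min REMS bouts ending mostly in WAKE) but *illustrative* — no
published numeric matrices exist for the emulated protocol, and any
study-specific use should supply its own.

EEG is a state-gated sum of band-limited Gaussian noise components,
each filtered track normalized to unit RMS then scaled by the state's
component amplitude: NREMS delta-dominant (0.5–5 Hz, amplitude 2.0,
plus broadband 0.5), REMS theta-dominant (6–9 Hz, 1.8), WAKE broadband
(0.5–45 Hz, 1.0, plus theta 0.6); amplitudes are arbitrary units since
the whole analysis is scale-free. EMG is white noise with RMS 1.0 (W),
0.25 (N), 0.08 (R, atonia).

Spindles are Hann-windowed sinusoids, frequency uniform in 10–15 Hz,
duration uniform in 0.5–2 s, placed by a Poisson process at 2 events
per NREMS minute with two rejection rules: an event may not cross out
of its NREMS run, and may not come within 0.5 s of an already placed
event (spindles are discrete thalamocortical events; overlapping
injections would merge into one long envelope region and make
recall/precision against truth ill-defined). Burst peak amplitude is
`spindle_amp_gain` (default 5) × the raw NREMS background RMS — the
scale on which spindles visibly stand out in a trace. Movement
artifacts are brief 8 Hz biphasic pulses at 20× the EEG robust SD,
0.1/h, keeping the artifact fraction in the sub-0.1% regime of the
emulated protocol.

Determinism: one seeded generator, fixed draw order; identical
(config, seed) gives byte-identical recordings, and the pipeline
inherits end-to-end byte reproducibility (tested on the CSV outputs).

**What passing tests show — and don't.** The simulator validates the
*rules*: exact smoothing/bout/transition logic, detector recovery when
events match the generative model, spectral identities, bootstrap
mechanics. Real EEG has 1/f background, state-transition
nonstationarity, spindle chirp and amplitude asymmetry, scorer
disagreement, and artifacts that are not clean biphasic pulses; none
of these are modeled, so detector performance figures from synthetic
data (recall ≈ 0.99, precision 1.0 at gain 5) are upper bounds, not
field estimates.

## Problem sizes and numerics

Default validation scenarios: 23-h single-animal recordings
(20,700 epochs, 21.2 M samples) for full-scale checks; 30-min all-NREMS
blocks for detector scoring; 4-animal cohorts in the acceptance script;
B = 10,000 bootstraps where CIs are reported, smaller B only where a
test exercises plumbing rather than calibration. Chain fidelity is
checked by χ² goodness-of-fit per phase row (cells with zero configured
probability excluded, dof reduced accordingly) at α = 0.01 over 100
seeded runs.

Numerical conventions: EDF quantizes each channel to 16 bits over its
own peak amplitude (round-trip error ≤ peak/32767); the RMS window
uses reflective edges so constants map to closed-form values; tiny
negative mean-squares from floating-point cancellation are clamped
before the square root; degenerate t-tests (zero variance, equal
means) return p = 1 by convention; resampling refuses to upsample.

## Known limitations

- No automatic vigilance-state classification; labels are inputs.
- The EDF layer implements the minimal subset this pipeline needs
  (16-bit, 1-s records, integer sampling rate), not EDF+.
- Bout durations and transitions at phase boundaries are clipped to
  the phase, which shortens boundary bouts slightly.
- `spectral_auc` accepts whatever observations the caller supplies;
  the pipeline passes per-animal summaries. Pooling per-epoch values
  instead is possible but ignores within-animal correlation.
- The percentile bootstrap at n ≤ 8 is mildly anti-conservative (see
  above); BCa intervals are not implemented.
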