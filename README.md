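# somnarch

Sleep architecture, sleep-spindle, and EEG spectral analysis for rodent
polysomnography — plus a synthetic recording generator with full ground
truth, so every analysis stage can be validated against known answers.

`somnarch` is aimed at sleep researchers working with chronic EEG/EMG
recordings in mice (typically 23 h sessions at 256 Hz under a 12 h
light / 11 h dark schedule), scored into WAKE (W), non-REM sleep
(NREMS, N) and REM sleep (REMS, R) on a 4-s epoch grid.

## What it computes

**Hypnogram rules.** Raw epoch scores are regularized with a sustained
state-change rule: a transition to a new vigilance state counts only if
the new state persists for at least three consecutive epochs; shorter
intrusions are relabelled to the ongoing state. Movement-artifact
epochs are flagged by a robust amplitude threshold, excluded from all
statistics, and transparent to the rule. Recordings are split into
light (ZT0–12) and dark (ZT12–23) phases on the zeitgeber clock.

**Architecture metrics.** Per phase: state proportions, maximal-run
bout tables with median bout durations, directed state-transition
counts and per-hour rates (W→N, N→R, R→N, …), and group time-course
profiles (median state occupancy in 2-h bins with percentile bootstrap
95% CIs over animals, B = 10,000).

**Spindle detection.** Sleep spindles during NREMS are detected by the
cubed-RMS double-threshold method: the EEG is band-passed 10–15 Hz
(zero-phase 4th-order Butterworth), a sliding 750 ms RMS is cubed, and
an event is a maximal region above 1.0× the NREMS mean cubed RMS that
contains an excursion above 2.5× it, lasting 0.5–2 s, and lying wholly
inside NREMS. Reported per event: onset, duration, peak cubed RMS, and
amplitude normalized by the NREMS band RMS. Summaries: amount, density
(spindles per NREMS minute), median duration and amplitude. Because
both thresholds scale with the signal, detection is invariant to
amplifier gain.

**Spectra.** Per-state power spectral density as the mean of
Hann-windowed periodograms over 4-s epochs (0.25 Hz resolution), each
animal normalized to percent of its total 0.5–45 Hz power; band powers
in δ 0.5–5, θ 6–9, α 10–15, η 16–22.75, β 23–31.75, γ 31.75–45 Hz;
group median spectra with bootstrap CIs; group comparison per bin or
band by ROC-AUC (the rank / Mann–Whitney identity `AUC = U/(n_A·n_B)`,
ties = ½) with bootstrap CIs, and two-sample Student's t-tests
(α = 0.05).

**Simulator.** A first-order Markov chain over (W, N, R) at epoch
resolution with separate light/dark transition matrices generates
labels; signals are state-gated mixtures of band-limited noise (NREMS
delta-dominant, REMS theta-dominant, WAKE broadband, EMG tone tracking
state) with Hann-windowed 10–15 Hz spindle bursts injected into NREMS
and rare high-amplitude artifacts. Every injected event is recorded in
a truth object for recall/precision scoring.

## Worked example

```python
import somnarch as sa

cfg = sa.SimulationConfig()                      # 23 h, 256 Hz defaults
rec, raw, truth = sa.simulate_recording(cfg, seed=1)
hyp = sa.smooth_hypnogram(sa.mark_artifacts(rec, raw))

print(sa.state_proportions(hyp, "light"))
events = sa.detect_spindles(rec.eeg, hyp, rec.fs)
print(len(truth.spindles), "injected,", len(events), "detected")
print(sa.spindle_stats(events, hyp, "light").density_per_min)
```

prints (seed 1):

```
{'W': 0.4268913788313733, 'N': 0.45217149736086676, 'R': 0.12093712380775998}
794 injected, 787 detected
1.836985459758345
```

i.e. this simulated mouse spent 43% of the light phase awake, 45% in
NREMS and 12% in REMS; 787 of 794 injected spindles were recovered
(99.1% recall, no false positives), at a detected density of 1.84
spindles per NREMS minute against an injected rate of 2 per minute
(the shortfall comes from spindles whose host NREMS run was relabelled
by smoothing or clipped at a state boundary).

The same pipeline runs from the shell:

```bash
somnarch simulate --seed 7 --out data/
somnarch run --config run.yaml        # metrics.csv, spindles.csv, psd.csv, ...
somnarch compare groupA/ groupB/      # t-tests + ROC-AUC per metric
```

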