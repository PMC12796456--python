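"""Synthetic mouse polysomnography with known ground truth.

The generator emulates the structure of a 23-h rodent EEG/EMG session:
a first-order Markov chain over (WAKE, NREMS, REMS) at 4-s epoch
resolution with separate light- and dark-phase transition matrices,
state-dependent band-limited EEG spectra (NREMS delta-dominant, REMS
theta-dominant, WAKE broadband), EMG tone tracking the state, sleep
spindles injected as Hann-windowed 10-15 Hz sinusoids confined to NREMS
runs, and rare high-amplitude movement artifacts.

Every stochastic element is drawn from one seeded generator in a fixed
order, so identical (config, seed) pairs give byte-identical output,
and every injected event is recorded in a :class:`SimulationTruth` for
recall/precision scoring of the downstream detectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.signal import butter, sosfiltfilt

from .errors import ValidationError
from .io import (ARTIFACT, NREM, REM, WAKE, VIGILANCE_STATES, Hypnogram,
                 Recording, write_hypnogram, write_recording)

_STATE_INDEX = {s: i for i, s in enumerate(VIGILANCE_STATES)}

# Per-epoch (4 s) transition probabilities over (W, N, R).  The study
# this emulates publishes no numeric matrices; these are illustrative
# dwell-time-realistic values -- minutes-long wake bouts (longer in the
# dark, when mice are active), 1-2 min NREMS bouts with occasional REMS
# entries, and ~1 min REMS bouts ending mostly in wake.
DEFAULT_TRANSITIONS_LIGHT = np.array([
    [0.955, 0.045, 0.000],
    [0.025, 0.955, 0.020],
    [0.055, 0.010, 0.935],
])
DEFAULT_TRANSITIONS_DARK = np.array([
    [0.990, 0.010, 0.000],
    [0.040, 0.945, 0.015],
    [0.060, 0.010, 0.930],
])

# Per-state spectral components: (center Hz, bandwidth Hz, RMS amplitude).
# NREMS is delta-dominant, REMS theta-dominant, WAKE broadband; the
# amplitudes are arbitrary units (the analysis is scale-free).
DEFAULT_STATE_SPECTRA: dict[str, list[tuple[float, float, float]]] = {
    WAKE: [(22.75, 44.5, 1.0), (7.5, 3.0, 0.6)],
    NREM: [(2.75, 4.5, 2.0), (22.75, 44.5, 0.5)],
    REM: [(7.5, 3.0, 1.8), (22.75, 44.5, 0.4)],
}

#: EMG RMS per state: high muscle tone awake, low in NREMS, atonia in REMS.
DEFAULT_EMG_LEVELS: dict[str, float] = {WAKE: 1.0, NREM: 0.25, REM: 0.08}


@dataclass
class SimulationConfig:
    """Study-condition parameters for one synthetic recording.

    Defaults mirror the emulated protocol: 23 h at 256 Hz, scored in
    4-s epochs, 12 h of light then darkness; spindles at 2 per NREMS
    minute, 10-15 Hz, 0.5-2 s, at 5x the raw NREMS background RMS.
    """

    duration_h: float = 23.0
    fs: float = 256.0
    epoch_s: float = 4.0
    lights_on_h: float = 12.0
    transition_matrix_light: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITIONS_LIGHT.copy())
    transition_matrix_dark: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITIONS_DARK.copy())
    state_spectra: dict[str, list[tuple[float, float, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_STATE_SPECTRA.items()})
    emg_levels: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EMG_LEVELS))
    spindle_rate: float = 2.0          # events per NREMS minute
    spindle_freq_range: tuple[float, float] = (10.0, 15.0)
    spindle_dur_range: tuple[float, float] = (0.5, 2.0)
    spindle_amp_gain: float = 5.0      # peak amplitude / raw NREMS background RMS
    artifact_rate: float = 0.1         # events per hour (artifacts are a sub-0.1% fraction)
    artifact_amp: float = 20.0         # multiples of EEG robust SD
    initial_state: str = WAKE

    def __post_init__(self) -> None:
        self.transition_matrix_light = np.asarray(self.transition_matrix_light, float)
        self.transition_matrix_dark = np.asarray(self.transition_matrix_dark, float)
        self.validate()

    def validate(self) -> None:
        for name, tm in (("light", self.transition_matrix_light),
                         ("dark", self.transition_matrix_dark)):
            if tm.shape != (3, 3):
                raise ValidationError(f"{name} transition matrix must be 3x3")
            if np.any(tm < 0) or np.any(np.abs(tm.sum(axis=1) - 1.0) > 1e-12):
                raise ValidationError(
                    f"{name} transition matrix rows must be probabilities summing to 1"
                )
        if self.duration_h <= 0 or self.fs <= 0 or self.epoch_s <= 0:
            raise ValidationError("duration_h, fs and epoch_s must be positive")
        spe = self.fs * self.epoch_s
        if abs(spe - round(spe)) > 1e-9:
            raise ValidationError("fs * epoch_s must be an integer number of samples")
        if self.spindle_rate < 0 or self.artifact_rate < 0:
            raise ValidationError("rates must be non-negative")
        lo, hi = self.spindle_freq_range
        if not 0 < lo < hi < self.fs / 2:
            raise ValidationError("spindle_freq_range must lie in (0, fs/2)")
        dlo, dhi = self.spindle_dur_range
        if not 0 < dlo < dhi:
            raise ValidationError("spindle_dur_range must be ordered and positive")
        if self.initial_state not in VIGILANCE_STATES:
            raise ValidationError(f"unknown initial state {self.initial_state!r}")

    @property
    def n_epochs(self) -> int:
        return int(self.duration_h * 3600.0 // self.epoch_s)

    @property
    def samples_per_epoch(self) -> int:
        return round(self.fs * self.epoch_s)

    def to_dict(self) -> dict:
        return {
            "duration_h": self.duration_h, "fs": self.fs,
            "epoch_s": self.epoch_s, "lights_on_h": self.lights_on_h,
            "transition_matrix_light": self.transition_matrix_light.tolist(),
            "transition_matrix_dark": self.transition_matrix_dark.tolist(),
            "state_spectra": {k: [list(c) for c in v]
                              for k, v in self.state_spectra.items()},
            "emg_levels": dict(self.emg_levels),
            "spindle_rate": self.spindle_rate,
            "spindle_freq_range": list(self.spindle_freq_range),
            "spindle_dur_range": list(self.spindle_dur_range),
            "spindle_amp_gain": self.spindle_amp_gain,
            "artifact_rate": self.artifact_rate,
            "artifact_amp": self.artifact_amp,
            "initial_state": self.initial_state,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        for key in ("transition_matrix_light", "transition_matrix_dark"):
            if key in data:
                data[key] = np.asarray(data[key], float)
        for key in ("spindle_freq_range", "spindle_dur_range"):
            if key in data:
                data[key] = tuple(data[key])
        if "state_spectra" in data:
            data["state_spectra"] = {
                k: [tuple(c) for c in v] for k, v in data["state_spectra"].items()
            }
        return cls(**data)


@dataclass
class SimulationTruth:
    """Ground truth of one synthetic recording.

    ``spindles`` rows are (start_s, duration_s, freq_hz); every event's
    support lies inside a NREMS epoch run.  ``realized_transition_counts``
    holds the 3x3 observed per-phase counts, recountable from labels.
    """

    labels: np.ndarray
    spindles: list[tuple[float, float, float]]
    artifact_epochs: np.ndarray
    realized_transition_counts: dict[str, np.ndarray]


def simulate_labels(config: SimulationConfig,
                    seed: int | None = None) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Simulate the per-epoch vigilance-state sequence.

    First-order Markov chain over (W, N, R); the transition matrix
    switches from the light to the dark matrix at lights-off.  A
    transition spanning the boundary is counted in the later epoch's
    phase.  Returns (labels, per-phase realized 3x3 counts).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_epochs
    epochs_light = int(config.lights_on_h * 3600.0 // config.epoch_s)

    cum = {
        "light": np.cumsum(config.transition_matrix_light, axis=1),
        "dark": np.cumsum(config.transition_matrix_dark, axis=1),
    }
    counts = {"light": np.zeros((3, 3), int), "dark": np.zeros((3, 3), int)}

    states = np.empty(n, dtype=np.int64)
    states[0] = _STATE_INDEX[config.initial_state]
    draws = rng.random(n - 1) if n > 1 else np.empty(0)
    for i in range(1, n):
        phase = "light" if i < epochs_light else "dark"
        states[i] = np.searchsorted(cum[phase][states[i - 1]], draws[i - 1],
                                    side="right")
        counts[phase][states[i - 1], states[i]] += 1

    labels = np.array(VIGILANCE_STATES, dtype="<U1")[states]
    return labels, counts


def _component_band(center: float, bandwidth: float, fs: float) -> tuple[float, float]:
    lo = max(center - bandwidth / 2.0, 0.1)
    hi = min(center + bandwidth / 2.0, 0.999 * fs / 2.0)
    return lo, hi


def _nrem_runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Maximal (start_epoch, end_epoch) runs of NREMS."""
    is_n = labels == NREM
    starts = list(np.flatnonzero(~is_n[:-1] & is_n[1:]) + 1)
    stops = list(np.flatnonzero(is_n[:-1] & ~is_n[1:]) + 1)
    if is_n[0]:
        starts.insert(0, 0)
    if is_n[-1]:
        stops.append(is_n.size)
    return list(zip(starts, stops))


def synthesize_signals(labels: np.ndarray, config: SimulationConfig,
                       seed: int | None = None) -> tuple[Recording, SimulationTruth]:
    """Render EEG/EMG signals for a label sequence and record the truth.

    EEG = state-gated sum of band-limited Gaussian noise components
    (each filtered track normalized to unit RMS, then scaled by the
    state's component amplitude) + injected spindle bursts + movement
    artifacts.  EMG is white noise whose RMS tracks the state.
    """
    config.validate()
    labels = np.asarray(labels, dtype="<U1")
    rng = np.random.default_rng(seed)
    spe = config.samples_per_epoch
    n_samples = labels.size * spe
    fs = config.fs

    sample_amp = {s: np.repeat(labels == s, spe).astype(float)
                  for s in VIGILANCE_STATES}

    # deduplicated component bands, in a fixed (state-ordered) draw order
    components: list[tuple[float, float]] = []
    for s in VIGILANCE_STATES:
        for center, bw, _amp in config.state_spectra.get(s, []):
            if (center, bw) not in components:
                components.append((center, bw))

    eeg = np.zeros(n_samples)
    for center, bw in components:
        white = rng.standard_normal(n_samples)
        sos = butter(4, _component_band(center, bw, fs), btype="bandpass",
                     fs=fs, output="sos")
        track = sosfiltfilt(sos, white)
        track /= track.std() or 1.0
        gain = np.zeros(n_samples)
        for s in VIGILANCE_STATES:
            for c2, b2, amp in config.state_spectra.get(s, []):
                if (c2, b2) == (center, bw):
                    gain += amp * sample_amp[s]
        eeg += gain * track

    emg = rng.standard_normal(n_samples)
    emg_gain = np.zeros(n_samples)
    for s in VIGILANCE_STATES:
        emg_gain += config.emg_levels.get(s, 0.0) * sample_amp[s]
    emg *= emg_gain

    # --- spindles: homogeneous Poisson over NREMS time, events that
    # would cross out of their NREMS run are rejected ---
    spindles: list[tuple[float, float, float]] = []
    runs = _nrem_runs(labels) if np.any(labels == NREM) else []
    if config.spindle_rate > 0 and runs:
        # gain is relative to the raw NREMS background amplitude, the
        # scale on which spindles visibly stand out in a trace
        nrem_mask = np.repeat(labels == NREM, spe)
        background_rms = float(np.sqrt(np.mean(eeg[nrem_mask] ** 2)))
        amplitude_scale = config.spindle_amp_gain * background_rms
        min_gap_s = 0.5  # refractory gap; spindles are discrete events
        for ep_lo, ep_hi in runs:
            run_start_s = ep_lo * config.epoch_s
            run_dur_s = (ep_hi - ep_lo) * config.epoch_s
            n_events = rng.poisson(config.spindle_rate * run_dur_s / 60.0)
            placed: list[tuple[float, float]] = []
            for _ in range(n_events):
                start = run_start_s + rng.uniform(0.0, run_dur_s)
                dur = rng.uniform(*config.spindle_dur_range)
                freq = rng.uniform(*config.spindle_freq_range)
                phase = rng.uniform(0.0, 2.0 * np.pi)
                if start + dur > run_start_s + run_dur_s:
                    continue  # would cross into a non-NREMS epoch
                if any(start < e + min_gap_s and start + dur + min_gap_s > s
                       for s, e in placed):
                    continue  # overlapping events would blur the ground truth
                placed.append((start, start + dur))
                i0 = int(round(start * fs))
                n_ev = int(round(dur * fs))
                t = np.arange(n_ev) / fs
                hann = 0.5 * (1.0 - np.cos(2.0 * np.pi * (np.arange(n_ev) + 0.5) / n_ev))
                eeg[i0:i0 + n_ev] += (amplitude_scale * hann
                                      * np.sin(2.0 * np.pi * freq * t + phase))
                spindles.append((start, dur, freq))
        spindles.sort()

    # --- movement artifacts: brief high-amplitude biphasic pulses ---
    artifact_epochs: list[int] = []
    n_art = rng.poisson(config.artifact_rate * labels.size * config.epoch_s / 3600.0)
    if n_art > 0:
        robust_sd = 1.4826 * np.median(np.abs(eeg - np.median(eeg)))
        pulse_n = int(round(0.25 * fs))
        t = np.arange(pulse_n) / fs
        pulse = np.sin(2.0 * np.pi * 8.0 * t) * np.hanning(pulse_n)
        for _ in range(n_art):
            i0 = rng.integers(0, max(n_samples - pulse_n, 1))
            eeg[i0:i0 + pulse_n] += config.artifact_amp * robust_sd * pulse[: n_samples - i0]
            artifact_epochs.extend(range(i0 // spe, min((i0 + pulse_n - 1) // spe + 1,
                                                        labels.size)))

    recording = Recording(eeg=eeg, emg=emg, fs=fs, zt_start=0.0)
    truth = SimulationTruth(
        labels=labels.copy(),
        spindles=spindles,
        artifact_epochs=np.unique(np.array(artifact_epochs, dtype=int)),
        realized_transition_counts=count_transitions(labels, config),
    )
    return recording, truth


def count_transitions(labels: np.ndarray, config: SimulationConfig) -> dict[str, np.ndarray]:
    """Recount per-phase 3x3 transition counts from a label sequence."""
    labels = np.asarray(labels, dtype="<U1")
    states = np.array([_STATE_INDEX[s] for s in labels])
    epochs_light = int(config.lights_on_h * 3600.0 // config.epoch_s)
    counts = {"light": np.zeros((3, 3), int), "dark": np.zeros((3, 3), int)}
    for i in range(1, states.size):
        phase = "light" if i < epochs_light else "dark"
        counts[phase][states[i - 1], states[i]] += 1
    return counts


def simulate_recording(config: SimulationConfig | None = None,
                       seed: int | None = None
                       ) -> tuple[Recording, Hypnogram, SimulationTruth]:
    """Full simulation: labels, signals, and the truth bundle."""
    config = config or SimulationConfig()
    seq = np.random.SeedSequence(seed)
    label_seed, signal_seed = seq.spawn(2)
    labels, _counts = simulate_labels(config, label_seed)
    recording, truth = synthesize_signals(labels, config, signal_seed)
    hypnogram = Hypnogram(labels=labels.copy(), epoch_s=config.epoch_s, zt_start=0.0)
    return recording, hypnogram, truth


def write_simulation(recording: Recording, hypnogram: Hypnogram,
                     truth: SimulationTruth, config: SimulationConfig,
                     out_dir: str | Path) -> Path:
    """Write recording.edf, labels.csv, spindles.csv and config.yaml."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_recording(recording, out_dir / "recording.edf")
    write_hypnogram(hypnogram, out_dir / "labels.csv")
    with open(out_dir / "spindles.csv", "w") as fh:
        fh.write("start_s,duration_s,freq_hz\n")
        for start, dur, freq in truth.spindles:
            fh.write(f"{start:.6f},{dur:.6f},{freq:.6f}\n")
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    return out_dir
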