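"""Sleep-spindle detection by double-thresholding the cubed RMS envelope.

Pipeline: zero-phase Butterworth band-pass (10-15 Hz) -> sliding 750 ms
RMS -> cube (sharpens the burst/background contrast) -> two thresholds
at 1.0x and 2.5x the mean cubed RMS over NREMS.  A candidate event is a
maximal region above the lower threshold that contains at least one
sample above the upper threshold; it is kept if its duration falls in
0.5-2 s and its support lies entirely within NREMS epochs.

Because both thresholds are multiples of a statistic of the signal
itself, the detected event set is invariant under rescaling the EEG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, sosfiltfilt

from .errors import NoNremsError, UndefinedMetricError, ValidationError
from .hypno import state_sample_mask
from .io import Hypnogram, NREM


@dataclass(frozen=True)
class SpindleParams:
    """Detector settings.

    band
        Spindle frequency band in Hz.
    rms_window_ms
        Length of the sliding RMS window.
    lower_k, upper_k
        Thresholds as multiples of the mean cubed RMS over NREMS.
    dur_range_s
        Accepted event duration range in seconds.
    """

    band: tuple[float, float] = (10.0, 15.0)
    rms_window_ms: float = 750.0
    lower_k: float = 1.0
    upper_k: float = 2.5
    dur_range_s: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        if not 0 < self.lower_k < self.upper_k:
            raise ValidationError("need 0 < lower_k < upper_k")
        if not 0 < self.band[0] < self.band[1]:
            raise ValidationError("band must be ordered and positive")
        if not 0 < self.dur_range_s[0] < self.dur_range_s[1]:
            raise ValidationError("dur_range_s must be ordered and positive")
        if self.rms_window_ms <= 0:
            raise ValidationError("rms_window_ms must be positive")


@dataclass
class SpindleEvent:
    """One detected spindle.

    ``normalized_amplitude`` is the peak band-passed amplitude divided
    by the mean band-passed RMS over NREMS — a unit-free measure
    comparable across animals regardless of amplifier calibration.
    """

    start_s: float
    duration_s: float
    peak_cubed_rms: float
    normalized_amplitude: float

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass
class SpindleSummary:
    """Phase-level spindle statistics (NaN medians when no events)."""

    amount: int
    density_per_min: float
    median_duration_s: float
    median_normalized_amplitude: float


def bandpass_spindle(eeg: np.ndarray, fs: float,
                     band: tuple[float, float] = (10.0, 15.0)) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass of the EEG."""
    if fs < 2.0 * band[1]:
        raise ValidationError(
            f"fs={fs} Hz too low for band {band} (need >= {2 * band[1]} Hz)"
        )
    sos = butter(4, band, btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, np.asarray(eeg, dtype=float))


def cubed_rms(filtered: np.ndarray, fs: float,
              window_ms: float = 750.0) -> np.ndarray:
    """Centered sliding-window RMS raised to the third power.

    The mean square uses reflective edge handling, so a constant signal
    ``c`` maps to ``|c|**3`` everywhere.  Homogeneous of degree 3 in the
    signal amplitude.
    """
    filtered = np.asarray(filtered, dtype=float)
    window = int(round(window_ms / 1000.0 * fs))
    if window < 1:
        raise ValidationError("RMS window shorter than one sample")
    if window > filtered.size:
        raise ValidationError(
            f"RMS window ({window} samples) longer than signal ({filtered.size})"
        )
    mean_sq = uniform_filter1d(filtered * filtered, size=window, mode="reflect")
    # tiny negative values can appear from floating-point cancellation
    return np.sqrt(np.maximum(mean_sq, 0.0)) ** 3


def detect_spindles(eeg: np.ndarray, hypnogram: Hypnogram, fs: float,
                    params: SpindleParams | None = None) -> list[SpindleEvent]:
    """Detect NREMS sleep spindles with the two-threshold envelope rule.

    The threshold baseline is the mean cubed RMS over non-artifact NREMS
    samples only, so wake-state amplitude differences cannot shift the
    detector's operating point.  Events extending beyond NREMS epochs
    are rejected rather than truncated.
    """
    params = params or SpindleParams()
    eeg = np.asarray(eeg, dtype=float)
    nrem_mask = state_sample_mask(hypnogram, fs, NREM, n_samples=eeg.size)
    if not nrem_mask.any():
        raise NoNremsError("hypnogram contains no NREMS epochs")

    filtered = bandpass_spindle(eeg, fs, params.band)
    envelope = cubed_rms(filtered, fs, params.rms_window_ms)

    baseline = float(envelope[nrem_mask].mean())
    lower = params.lower_k * baseline
    upper = params.upper_k * baseline

    above = envelope > lower
    if not above.any():
        return []
    turn_on = np.flatnonzero(~above[:-1] & above[1:]) + 1
    turn_off = np.flatnonzero(above[:-1] & ~above[1:]) + 1
    if above[0]:
        turn_on = np.concatenate(([0], turn_on))
    if above[-1]:
        turn_off = np.concatenate((turn_off, [above.size]))

    band_rms_nrem = float(np.sqrt(np.mean(filtered[nrem_mask] ** 2)))
    lo_dur, hi_dur = params.dur_range_s
    events = []
    for s, e in zip(turn_on, turn_off):
        segment = envelope[s:e]
        if segment.max() <= upper:
            continue
        duration = (e - s) / fs
        if not lo_dur <= duration <= hi_dur:
            continue
        if not nrem_mask[s:e].all():
            continue
        peak_amp = float(np.max(np.abs(filtered[s:e])))
        events.append(SpindleEvent(
            start_s=s / fs,
            duration_s=duration,
            peak_cubed_rms=float(segment.max()),
            normalized_amplitude=peak_amp / band_rms_nrem,
        ))
    return events


def spindle_stats(events: list[SpindleEvent], hypnogram: Hypnogram,
                  phase: str | None = None) -> SpindleSummary:
    """Amount, density (per NREMS minute), and median duration/amplitude
    of spindles whose onset lies in the phase."""
    from .hypno import phase_mask
    from .io import ARTIFACT

    sel = phase_mask(hypnogram, phase)
    nrem_epochs = int(np.sum(sel & (hypnogram.labels == NREM)
                             & (hypnogram.labels != ARTIFACT)))
    nrem_min = nrem_epochs * hypnogram.epoch_s / 60.0
    if nrem_min == 0:
        raise UndefinedMetricError(
            f"no NREMS time in phase {phase!r}; spindle density undefined"
        )

    in_phase = []
    for ev in events:
        epoch = int(ev.start_s // hypnogram.epoch_s)
        if 0 <= epoch < hypnogram.n_epochs and sel[epoch]:
            in_phase.append(ev)

    durations = np.array([ev.duration_s for ev in in_phase])
    amps = np.array([ev.normalized_amplitude for ev in in_phase])
    return SpindleSummary(
        amount=len(in_phase),
        density_per_min=len(in_phase) / nrem_min,
        median_duration_s=float(np.median(durations)) if in_phase else float("nan"),
        median_normalized_amplitude=float(np.median(amps)) if in_phase else float("nan"),
    )
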