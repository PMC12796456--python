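"""Recording and hypnogram containers plus file I/O.

Signals travel as EDF (European Data Format, 16-bit) — the de facto
polysomnography exchange format — with an NPZ fallback for lossless
scratch storage.  Hypnograms are plain ``epoch_index,state`` CSV.

The EDF layer implements the minimal single-record-per-second subset of
the specification (one EEG and one EMG channel by default); it is not a
general EDF+ reader.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.signal import resample_poly

from .errors import (
    ChannelNotFoundError,
    EmptyHypnogramError,
    FormatError,
    HypnogramParseError,
    UnsupportedOperationError,
    ValidationError,
)

#: Vigilance-state tokens: wake, non-REM sleep, REM sleep.
WAKE = "W"
NREM = "N"
REM = "R"
#: Epochs excluded from analysis (movement artifacts).
ARTIFACT = "A"

VIGILANCE_STATES = (WAKE, NREM, REM)
ALL_STATES = VIGILANCE_STATES + (ARTIFACT,)

#: Aliases accepted when parsing hypnogram files.
_STATE_ALIASES = {
    "W": WAKE, "WAKE": WAKE,
    "N": NREM, "NREM": NREM, "NREMS": NREM,
    "R": REM, "REM": REM, "REMS": REM,
    "A": ARTIFACT, "ART": ARTIFACT, "ARTIFACT": ARTIFACT,
}


@dataclass
class Recording:
    """One animal's EEG + EMG traces on a common sampling grid.

    Amplitudes are in arbitrary calibrated units (the analysis is
    unit-free; every statistic is either normalized or a ratio).
    ``zt_start`` anchors sample 0 on the zeitgeber clock (ZT0 = lights
    on).
    """

    eeg: np.ndarray
    emg: np.ndarray
    fs: float
    zt_start: float = 0.0

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        if self.eeg.ndim != 1 or self.emg.ndim != 1:
            raise ValidationError("eeg and emg must be 1-D arrays")
        if self.eeg.size != self.emg.size:
            raise ValidationError(
                f"eeg ({self.eeg.size}) and emg ({self.emg.size}) differ in length"
            )
        if not self.fs > 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        if self.duration_h > 24.0 + 1e-9:
            raise ValidationError(
                f"recording longer than 24 h ({self.duration_h:.2f} h)"
            )

    @property
    def n_samples(self) -> int:
        return self.eeg.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def duration_h(self) -> float:
        return self.duration_s / 3600.0

    def n_epochs(self, epoch_s: float = 4.0) -> int:
        """Number of complete epochs; a trailing partial epoch is dropped."""
        return int(self.n_samples // round(self.fs * epoch_s))


@dataclass
class Hypnogram:
    """Per-epoch vigilance labels on a fixed scoring grid (4 s default)."""

    labels: np.ndarray
    epoch_s: float = 4.0
    zt_start: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="<U1")
        if self.labels.size == 0:
            raise ValidationError("hypnogram must contain at least one epoch")
        if not self.epoch_s > 0:
            raise ValidationError("epoch_s must be positive")
        bad = set(np.unique(self.labels)) - set(ALL_STATES)
        if bad:
            raise ValidationError(f"unknown state labels: {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return self.labels.size

    @property
    def duration_h(self) -> float:
        return self.n_epochs * self.epoch_s / 3600.0

    @property
    def artifact_fraction(self) -> float:
        return float(np.mean(self.labels == ARTIFACT))

    def epoch_zt(self) -> np.ndarray:
        """Zeitgeber hour of each epoch's start."""
        return self.zt_start + np.arange(self.n_epochs) * self.epoch_s / 3600.0

    def copy(self) -> "Hypnogram":
        return replace(self, labels=self.labels.copy())


# ---------------------------------------------------------------------------
# EDF I/O
# ---------------------------------------------------------------------------

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    raw = text.encode("ascii", errors="replace")[:width]
    return raw + b" " * (width - len(raw))


def _num8(value: float) -> str:
    """Render a float into EDF's 8-character numeric fields."""
    for prec in range(6, 0, -1):
        text = f"{value:.{prec}g}"
        if len(text) <= 8:
            return text
    return f"{value:.0e}"[:8]


def write_recording(recording: Recording, path: str | Path, fmt: str | None = None) -> Path:
    """Write a recording to EDF (default) or NPZ, inferred from the suffix.

    EDF quantizes each channel to 16 bits over its own amplitude range;
    the round-trip error is bounded by (peak amplitude) / 32767.
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "npz":
        np.savez(path, eeg=recording.eeg, emg=recording.emg,
                 fs=recording.fs, zt_start=recording.zt_start)
        return path
    if fmt != "edf":
        raise UnsupportedOperationError(f"unknown recording format: {fmt!r}")

    fs_int = round(recording.fs)
    if abs(recording.fs - fs_int) > 1e-9:
        raise UnsupportedOperationError(
            "EDF writer requires an integer sampling rate; use NPZ instead"
        )
    n_records = recording.n_samples // fs_int
    if n_records * fs_int != recording.n_samples:
        warnings.warn(
            f"dropping trailing {recording.n_samples - n_records * fs_int} "
            "samples (partial final EDF record)", stacklevel=2)
    if n_records == 0:
        raise ValidationError("recording shorter than one EDF record (1 s)")

    channels = [("EEG", recording.eeg), ("EMG", recording.emg)]
    ns = len(channels)

    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad(f"Startdate X somnarch zt_start={recording.zt_start:.6f}", 80),
        _pad("01.01.00", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (ns + 1)), 8),
        _pad("", 44),
        _pad(str(n_records), 8),
        _pad("1", 8),
        _pad(str(ns), 4),
    ])

    phys_min, phys_max, digital = [], [], []
    for _, sig in channels:
        peak = float(np.max(np.abs(sig[: n_records * fs_int]))) or 1.0
        phys_min.append(-peak)
        phys_max.append(peak)
        scale = _EDF_DIG_MAX / peak
        dig = np.clip(np.round(sig[: n_records * fs_int] * scale),
                      _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")
        digital.append(dig.reshape(n_records, fs_int))

    for fld, width in [
        ([label for label, _ in channels], 16),
        (["" for _ in channels], 80),
        (["uV" for _ in channels], 8),
        ([_num8(v) for v in phys_min], 8),
        ([_num8(v) for v in phys_max], 8),
        ([str(_EDF_DIG_MIN) for _ in channels], 8),
        ([str(_EDF_DIG_MAX) for _ in channels], 8),
        (["" for _ in channels], 80),
        ([str(fs_int) for _ in channels], 8),
        (["" for _ in channels], 32),
    ]:
        header += b"".join(_pad(v, width) for v in fld)

    with open(path, "wb") as fh:
        fh.write(header)
        for rec_i in range(n_records):
            for dig in digital:
                fh.write(dig[rec_i].tobytes())
    return path


def _read_edf(path: Path) -> Recording:
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise FormatError(f"{path}: truncated EDF header")

        def fixed(offset: int, width: int) -> str:
            return head[offset:offset + width].decode("ascii", "replace").strip()

        recording_field = fixed(88, 80)
        n_records = int(fixed(236, 8))
        record_dur = float(fixed(244, 8))
        ns = int(fixed(252, 4))

        sig_head = fh.read(256 * ns)
        if len(sig_head) < 256 * ns:
            raise FormatError(f"{path}: truncated EDF signal header")

        def sig_field(offset: int, width: int) -> list[str]:
            base = offset * ns
            return [
                sig_head[base + i * width: base + (i + 1) * width]
                .decode("ascii", "replace").strip()
                for i in range(ns)
            ]

        labels = sig_field(0, 16)
        phys_min = [float(v) for v in sig_field(16 + 80 + 8, 8)]
        phys_max = [float(v) for v in sig_field(16 + 80 + 16, 8)]
        dig_min = [float(v) for v in sig_field(16 + 80 + 24, 8)]
        dig_max = [float(v) for v in sig_field(16 + 80 + 32, 8)]
        spr = [int(v) for v in sig_field(16 + 80 + 40 + 80, 8)]

        record_len = sum(spr)
        raw = np.frombuffer(fh.read(n_records * record_len * 2), dtype="<i2")
        if raw.size != n_records * record_len:
            raise FormatError(f"{path}: data shorter than header declares")

    raw = raw.reshape(n_records, record_len)
    signals = {}
    offset = 0
    for i in range(ns):
        dig = raw[:, offset:offset + spr[i]].reshape(-1).astype(float)
        offset += spr[i]
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        signals[labels[i].upper()] = phys_min[i] + (dig - dig_min[i]) * gain

    def find(name: str) -> np.ndarray:
        for label, sig in signals.items():
            if name in label:
                return sig
        raise ChannelNotFoundError(
            f"{path}: no channel labelled {name!r} (found {sorted(signals)})"
        )

    eeg, emg = find("EEG"), find("EMG")
    fs_vals = {spr[i] / record_dur for i in range(ns)}
    if len(fs_vals) != 1:
        raise FormatError(f"{path}: channels disagree on sampling rate")

    zt_start = 0.0
    if "zt_start=" in recording_field:
        try:
            zt_start = float(recording_field.split("zt_start=")[1].split()[0])
        except ValueError:
            pass
    return Recording(eeg=eeg, emg=emg, fs=fs_vals.pop(), zt_start=zt_start)


def read_recording(path: str | Path, fmt: str | None = None) -> Recording:
    """Read a recording from EDF or NPZ."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "npz":
        with np.load(path) as data:
            for key in ("eeg", "emg", "fs"):
                if key not in data:
                    raise ChannelNotFoundError(f"{path}: NPZ missing {key!r}")
            return Recording(
                eeg=data["eeg"], emg=data["emg"], fs=float(data["fs"]),
                zt_start=float(data["zt_start"]) if "zt_start" in data else 0.0,
            )
    raise UnsupportedOperationError(f"unknown recording format: {fmt!r}")


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_to(recording: Recording, target_fs: float = 256.0) -> Recording:
    """Anti-aliased decimation to ``target_fs``; upsampling is refused.

    Uses polyphase filtering; output length is ``ceil(n * target/fs)``
    (equal to ``round`` for the exact integer ratios used in practice).
    """
    if target_fs > recording.fs + 1e-12:
        raise UnsupportedOperationError(
            f"upsampling {recording.fs} -> {target_fs} Hz is not supported"
        )
    if math.isclose(target_fs, recording.fs):
        return replace(recording, eeg=recording.eeg.copy(), emg=recording.emg.copy())
    ratio = Fraction(target_fs / recording.fs).limit_denominator(10_000)
    eeg = resample_poly(recording.eeg, ratio.numerator, ratio.denominator)
    emg = resample_poly(recording.emg, ratio.numerator, ratio.denominator)
    return Recording(eeg=eeg, emg=emg, fs=target_fs, zt_start=recording.zt_start)


# ---------------------------------------------------------------------------
# Hypnogram CSV
# ---------------------------------------------------------------------------

def write_hypnogram(hypnogram: Hypnogram, path: str | Path) -> Path:
    """Write ``epoch_index,state`` CSV (single-letter state tokens)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("epoch_index,state\n")
        for i, s in enumerate(hypnogram.labels):
            fh.write(f"{i},{s}\n")
    return path


def read_hypnogram(path: str | Path, epoch_s: float = 4.0,
                   zt_start: float = 0.0) -> Hypnogram:
    """Read an ``epoch_index,state`` CSV; lossless inverse of the writer."""
    path = Path(path)
    labels: list[str] = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if lines and lines[0].lower().replace(" ", "") == "epoch_index,state":
        lines = lines[1:]
    if not lines:
        raise EmptyHypnogramError(f"{path}: no epochs")
    for row_no, line in enumerate(lines, start=1):
        parts = line.split(",")
        if len(parts) != 2:
            raise HypnogramParseError(f"{path}: row {row_no}: expected 2 fields, got {line!r}")
        token = parts[1].strip().upper()
        if token not in _STATE_ALIASES:
            raise HypnogramParseError(
                f"{path}: row {row_no}: unknown state token {parts[1].strip()!r}"
            )
        labels.append(_STATE_ALIASES[token])
    return Hypnogram(labels=np.array(labels), epoch_s=epoch_s, zt_start=zt_start)


def hypnogram_from_recording(recording: Recording, labels: np.ndarray,
                             epoch_s: float = 4.0) -> Hypnogram:
    """Attach labels to a recording's epoch grid, dropping any trailing
    labels beyond the last complete epoch."""
    n = recording.n_epochs(epoch_s)
    labels = np.asarray(labels)
    if labels.size < n:
        raise ValidationError(
            f"{labels.size} labels for {n} epochs of signal"
        )
    if labels.size > n:
        warnings.warn(f"dropping {labels.size - n} labels beyond the signal end",
                      stacklevel=2)
    return Hypnogram(labels=labels[:n], epoch_s=epoch_s, zt_start=recording.zt_start)
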