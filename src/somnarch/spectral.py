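"""Per-state EEG spectra, band powers, bootstrap CIs, and ROC-AUC
group comparison.

The spectral estimator averages Hann-windowed periodograms over the 4-s
scoring epochs of one vigilance state (Welch's method aligned with the
scoring grid), giving a 0.25 Hz frequency resolution at 256 Hz.  Each
animal's spectrum is normalized to percent of its total 0.5-45 Hz
power, removing amplifier-gain differences before any group statistic.

Group uncertainty is a percentile bootstrap over animals (the unit of
observation throughout); group separation per frequency bin or band is
the area under the ROC curve, computed through its rank-statistic
identity AUC = U / (n_A * n_B) with ties counted one half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.signal import periodogram

from .errors import NoValidEpochsError, UndefinedMetricError, ValidationError
from .hypno import phase_mask
from .io import ARTIFACT, Hypnogram

#: Frequency bands (Hz).  The table is taken literally: the gaps
#: (5-6, 9-10, 15-16, 22.75-23 Hz) belong to no band, and the shared
#: beta/gamma edge at 31.75 Hz is an integration endpoint of both.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 5.0),
    "theta": (6.0, 9.0),
    "alpha": (10.0, 15.0),
    "eta": (16.0, 22.75),
    "beta": (23.0, 31.75),
    "gamma": (31.75, 45.0),
}

#: Range over which normalized spectra integrate to 100 %.
TOTAL_POWER_RANGE = (0.5, 45.0)


@dataclass
class PSDResult:
    """Group PSD summary: pointwise median with bootstrap CI."""

    frequencies: np.ndarray
    median: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_animals: int
    n_boot: int


@dataclass
class AUCResult:
    """ROC-AUC of group A over group B with a bootstrap CI."""

    auc: float
    ci_lo: float
    ci_hi: float
    n_a: int
    n_b: int


def epoch_psd(eeg: np.ndarray, hypnogram: Hypnogram, fs: float, state: str,
              phase: str | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-epoch Hann periodograms for one state, plus their mean.

    Returns ``(frequencies, per_epoch_psd, mean_psd)`` with density
    scaling (power per Hz), one-sided, resolution ``1/epoch_s``.
    """
    eeg = np.asarray(eeg, dtype=float)
    spe = round(fs * hypnogram.epoch_s)
    n_epochs = min(hypnogram.n_epochs, eeg.size // spe)
    sel = ((hypnogram.labels[:n_epochs] == state)
           & (hypnogram.labels[:n_epochs] != ARTIFACT)
           & phase_mask(hypnogram, phase)[:n_epochs])
    if not sel.any():
        raise NoValidEpochsError(
            f"no valid {state!r} epochs in phase {phase!r}"
        )
    segments = eeg[: n_epochs * spe].reshape(n_epochs, spe)[sel]
    freqs, psd = periodogram(segments, fs=fs, window="hann",
                             detrend=False, scaling="density", axis=-1)
    return freqs, psd, psd.mean(axis=0)


def normalize_psd(psd: np.ndarray, freqs: np.ndarray,
                  total_range: tuple[float, float] = TOTAL_POWER_RANGE) -> np.ndarray:
    """Express a spectrum as percent of total power per Hz.

    Total power is the Riemann sum of the density over ``total_range``
    (inclusive), so the normalized values times the bin width sum to
    exactly 100 over that range.  Works on a single spectrum or a stack
    (last axis = frequency).
    """
    psd = np.asarray(psd, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    df = freqs[1] - freqs[0]
    mask = (freqs >= total_range[0]) & (freqs <= total_range[1])
    total = psd[..., mask].sum(axis=-1) * df
    if np.any(total <= 0):
        raise ValidationError("zero total power; cannot normalize spectrum")
    return psd / np.expand_dims(total, -1) * 100.0


def group_psd_ci(normalized_psds: np.ndarray, frequencies: np.ndarray,
                 n_boot: int = 10_000, seed: int | None = None,
                 ci: float = 95.0) -> PSDResult:
    """Pointwise group median spectrum with a percentile bootstrap CI.

    ``normalized_psds`` is (n_animals, n_freqs); animals are the
    resampling unit.  With one animal the CI is NaN.
    """
    psds = np.atleast_2d(np.asarray(normalized_psds, dtype=float))
    n_animals = psds.shape[0]
    median = np.median(psds, axis=0)
    alpha = (100.0 - ci) / 2.0
    if n_animals >= 2:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n_animals, size=(n_boot, n_animals))
        boots = np.median(psds[idx], axis=1)
        lo = np.percentile(boots, alpha, axis=0)
        hi = np.percentile(boots, 100.0 - alpha, axis=0)
    else:
        lo = hi = np.full_like(median, np.nan)
    return PSDResult(frequencies=np.asarray(frequencies), median=median,
                     ci_lo=lo, ci_hi=hi, n_animals=n_animals, n_boot=n_boot)


def band_power(psd: np.ndarray, freqs: np.ndarray,
               scheme: dict[str, tuple[float, float]] | None = None) -> dict[str, float]:
    """Trapezoidal band integrals of a spectrum over the band scheme.

    Because the printed band table leaves gaps, the band powers sum to
    slightly less than the total power.
    """
    scheme = scheme or DEFAULT_BANDS
    psd = np.asarray(psd, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    out = {}
    for name, (lo, hi) in scheme.items():
        if lo < freqs[0] or hi > freqs[-1]:
            raise ValidationError(
                f"band {name} ({lo}-{hi} Hz) outside the frequency grid "
                f"({freqs[0]}-{freqs[-1]} Hz)"
            )
        mask = (freqs >= lo) & (freqs <= hi)
        out[name] = float(np.trapezoid(psd[mask], freqs[mask]))
    return out


def _auc(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """AUC via the rank identity: (sum of A's ranks - nA(nA+1)/2) / (nA nB)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    ranks = stats.rankdata(np.concatenate([a, b]))
    u = ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0
    return float(u / (a.size * b.size))


def spectral_auc(values_a, values_b, n_boot: int = 10_000,
                 seed: int | None = None, ci: float = 95.0) -> AUCResult:
    """ROC-AUC of A over B (P[A > B] + P[A = B]/2) with bootstrap CI.

    Observations are per-animal summaries (band power at one bin, band
    integral, or any scalar metric); both groups are resampled with
    replacement for the CI.  AUC(A, B) = 1 - AUC(B, A).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    auc = _auc(a, b)
    if a.size >= 2 and b.size >= 2:
        rng = np.random.default_rng(seed)
        idx_a = rng.integers(0, a.size, size=(n_boot, a.size))
        idx_b = rng.integers(0, b.size, size=(n_boot, b.size))
        boots = np.empty(n_boot)
        for i in range(n_boot):
            boots[i] = _auc(a[idx_a[i]], b[idx_b[i]])
        alpha = (100.0 - ci) / 2.0
        lo, hi = np.percentile(boots, [alpha, 100.0 - alpha])
    else:
        lo = hi = float("nan")
    return AUCResult(auc=auc, ci_lo=float(lo), ci_hi=float(hi),
                     n_a=a.size, n_b=b.size)


def group_ttest(values_a, values_b) -> tuple[float, float]:
    """Two-sample Student's t-test (pooled variance), two-tailed.

    Degenerate zero-variance input with equal means returns (0, 1) by
    convention rather than NaN.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("need at least two observations per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def to_db(psd: np.ndarray, floor: float = 1e-300) -> np.ndarray:
    """Report-layer conversion to dB/Hz; statistics stay linear."""
    return 10.0 * np.log10(np.maximum(np.asarray(psd, dtype=float), floor))
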