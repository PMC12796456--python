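"""Sleep-architecture metrics: state proportions, bouts, transitions,
and 2-h time-course profiles with animal-level bootstrap CIs.

All metrics operate on smoothed hypnograms.  Artifact epochs are
transparent: they neither break a bout nor enter any numerator or
denominator, matching a study design where artifacts are a negligible
(<0.015 %) excluded fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NoValidEpochsError, UndefinedMetricError, ValidationError
from .hypno import phase_mask
from .io import ARTIFACT, Hypnogram, VIGILANCE_STATES


def state_proportions(hypnogram: Hypnogram, phase: str | None = None) -> dict[str, float]:
    """Fraction of non-artifact epochs spent in each vigilance state.

    Fractions sum to 1 over (W, N, R).
    """
    sel = phase_mask(hypnogram, phase)
    labels = hypnogram.labels[sel]
    labels = labels[labels != ARTIFACT]
    if labels.size == 0:
        raise NoValidEpochsError(f"no valid epochs in phase {phase!r}")
    return {s: float(np.mean(labels == s)) for s in VIGILANCE_STATES}


def bout_table(hypnogram: Hypnogram, phase: str | None = None) -> pd.DataFrame:
    """Maximal same-state runs as a table (state, start_epoch, n_epochs,
    duration_s).

    Artifact epochs inside a run do not break it and are excluded from
    ``n_epochs``; ``start_epoch`` indexes the original grid.  When a
    phase is given, bouts are clipped at the phase boundary.
    """
    sel = phase_mask(hypnogram, phase)
    idx = np.flatnonzero(sel & (hypnogram.labels != ARTIFACT))
    if idx.size == 0:
        return pd.DataFrame(columns=["state", "start_epoch", "n_epochs", "duration_s"])
    seq = hypnogram.labels[idx]
    boundaries = np.flatnonzero(seq[1:] != seq[:-1]) + 1
    edges = np.concatenate(([0], boundaries, [seq.size]))
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        rows.append({
            "state": seq[lo],
            "start_epoch": int(idx[lo]),
            "n_epochs": int(hi - lo),
            "duration_s": float((hi - lo) * hypnogram.epoch_s),
        })
    return pd.DataFrame(rows)


def median_bout_duration(bouts: pd.DataFrame, state: str) -> float:
    """Median bout duration (s) for one state; explicit error if absent."""
    durations = bouts.loc[bouts["state"] == state, "duration_s"]
    if durations.empty:
        raise UndefinedMetricError(f"no bouts of state {state!r}")
    return float(durations.median())


def mean_bout_duration(bouts: pd.DataFrame, state: str) -> float:
    """Mean bout duration (s); secondary to the median summary."""
    durations = bouts.loc[bouts["state"] == state, "duration_s"]
    if durations.empty:
        raise UndefinedMetricError(f"no bouts of state {state!r}")
    return float(durations.mean())


@dataclass
class TransitionTable:
    """Directed transition counts and per-hour rates between states.

    A transition is a label change between consecutive non-artifact
    epochs; with per-phase counting, a change straddling the light/dark
    boundary is assigned to the later epoch's phase.  Rates divide by
    the phase duration in hours.
    """

    counts: pd.DataFrame   # index from-state, columns to-state
    rates_per_h: pd.DataFrame
    phase_hours: float

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def count(self, from_state: str, to_state: str) -> int:
        return int(self.counts.loc[from_state, to_state])


def transitions(hypnogram: Hypnogram, phase: str | None = None) -> TransitionTable:
    """Count naturally occurring state transitions (W>N, N>R, ...)."""
    sel = phase_mask(hypnogram, phase)
    valid = np.flatnonzero(hypnogram.labels != ARTIFACT)
    seq = hypnogram.labels[valid]
    later_in_phase = sel[valid][1:]
    changed = (seq[1:] != seq[:-1]) & later_in_phase

    counts = pd.DataFrame(0, index=list(VIGILANCE_STATES),
                          columns=list(VIGILANCE_STATES), dtype=int)
    for i in np.flatnonzero(changed):
        counts.loc[seq[i], seq[i + 1]] += 1

    phase_hours = float(sel.sum() * hypnogram.epoch_s / 3600.0)
    rates = counts / phase_hours if phase_hours > 0 else counts * np.nan
    return TransitionTable(counts=counts, rates_per_h=rates, phase_hours=phase_hours)


def state_profile(group_hypnograms: list[Hypnogram], bin_h: float = 2.0,
                  n_boot: int = 10_000, seed: int | None = None,
                  ci: float = 95.0) -> pd.DataFrame:
    """Group time-course of state occupancy: median fraction per 2-h bin
    with a percentile bootstrap CI over animals.

    Each animal contributes, per bin, the fraction of its non-artifact
    epochs in each state (fractions sum to 1 within a bin).  The group
    statistic is the across-animal median; the CI resamples animals with
    replacement ``n_boot`` times.  With a single animal the CI columns
    are NaN.
    """
    if not group_hypnograms:
        raise ValidationError("need at least one hypnogram")
    n_animals = len(group_hypnograms)
    epoch_s = group_hypnograms[0].epoch_s
    if any(h.epoch_s != epoch_s for h in group_hypnograms):
        raise ValidationError("hypnograms disagree on epoch_s")

    n_bins = int(np.ceil(max(h.duration_h for h in group_hypnograms) / bin_h))
    fractions = np.full((n_animals, n_bins, len(VIGILANCE_STATES)), np.nan)
    for a, hyp in enumerate(group_hypnograms):
        bins = ((hyp.epoch_zt() - hyp.zt_start) / bin_h).astype(int)
        for b in range(n_bins):
            labels = hyp.labels[(bins == b) & (hyp.labels != ARTIFACT)]
            if labels.size:
                for s_i, s in enumerate(VIGILANCE_STATES):
                    fractions[a, b, s_i] = np.mean(labels == s)

    median = np.nanmedian(fractions, axis=0)
    alpha = (100.0 - ci) / 2.0
    if n_animals >= 2:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n_animals, size=(n_boot, n_animals))
        boots = np.nanmedian(fractions[idx], axis=1)  # (n_boot, n_bins, n_states)
        lo = np.nanpercentile(boots, alpha, axis=0)
        hi = np.nanpercentile(boots, 100.0 - alpha, axis=0)
    else:
        lo = hi = np.full_like(median, np.nan)

    rows = []
    for b in range(n_bins):
        for s_i, s in enumerate(VIGILANCE_STATES):
            rows.append({
                "bin_start_h": b * bin_h,
                "bin_end_h": (b + 1) * bin_h,
                "state": s,
                "median": median[b, s_i],
                "ci_lo": lo[b, s_i],
                "ci_hi": hi[b, s_i],
                "n_animals": n_animals,
            })
    return pd.DataFrame(rows)
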