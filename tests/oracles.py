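"""Independent brute-force reference implementations used as oracles.

These are deliberately written in a different style from the package
(streaming scans, explicit pair enumeration) so that agreement is
evidence of correctness rather than shared structure.
"""

from __future__ import annotations

import numpy as np

ARTIFACT = "A"


def smooth_streaming(labels, min_run=3):
    """Streaming scan of the sustained-state-change rule.

    Tracks the ongoing state and a pending candidate with a counter;
    the candidate becomes the ongoing state once seen ``min_run`` times
    in a row (artifact epochs skipped), otherwise its buffered epochs
    are relabelled to the ongoing state.
    """
    labels = list(labels)
    positions = [i for i, s in enumerate(labels) if s != ARTIFACT]
    seq = [labels[i] for i in positions]
    if not seq:
        raise ValueError("all-artifact input")

    out = []
    current = seq[0]
    pending = None
    buffer = 0
    for s in seq:
        if pending is None:
            if s == current:
                out.append(current)
            else:
                pending, buffer = s, 1
        elif s == pending:
            buffer += 1
        else:
            # pending run ended before reaching min_run
            if buffer >= min_run:
                current = pending
            out.extend([current] * buffer)
            if s == current:
                out.append(current)
                pending, buffer = None, 0
            else:
                pending, buffer = s, 1
        if pending is not None and buffer >= min_run:
            current = pending
            out.extend([current] * buffer)
            pending, buffer = None, 0
    if pending is not None:
        if buffer >= min_run:
            current = pending
        out.extend([current] * buffer)

    result = list(labels)
    for pos, s in zip(positions, out):
        result[pos] = s
    return np.array(result, dtype="<U1")


def rle_bouts(labels, epoch_s=4.0):
    """Run-length encoding of non-artifact labels: list of
    (state, n_epochs, duration_s)."""
    seq = [s for s in labels if s != ARTIFACT]
    bouts = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        bouts.append((seq[i], j - i, (j - i) * epoch_s))
        i = j
    return bouts


def pairwise_auc(values_a, values_b):
    """Exhaustive pairwise AUC: mean over all (a, b) pairs of
    1[a > b] + 0.5 * 1[a == b]."""
    total = 0.0
    for a in values_a:
        for b in values_b:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(values_a) * len(values_b))


def percentile_bootstrap_median(values, n_boot, seed, ci=95.0):
    """Reference percentile bootstrap CI for the median, resampling with
    an explicit per-replicate loop."""
    rng = np.random.default_rng(seed)
    values = np.asarray(values, dtype=float)
    n = values.size
    medians = np.empty(n_boot)
    for b in range(n_boot):
        medians[b] = np.median(values[rng.integers(0, n, n)])
    alpha = (100.0 - ci) / 2.0
    return np.percentile(medians, alpha), np.percentile(medians, 100.0 - alpha)
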