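"""PSTHs, evoked rate, trial similarity and rate-normalised RMS difference.

These response measures decompose what drives discrimination performance:
evoked rate (overall excitability), trial similarity (reproducibility of the
temporal response within a target, via split-half PSTH correlations at 25 ms
resolution), and the rate-normalised RMS difference between the two targets'
PSTHs (distinctness of the temporal response patterns, independent of mean
rate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .trains import SpikeTrain, TrialSet

__all__ = [
    "PSTH",
    "psth",
    "evoked_rate",
    "trial_similarity",
    "rate_normalized_rms",
    "correlate_measures",
]

log = logging.getLogger(__name__)

DEFAULT_BIN = 0.025  # s


@dataclass(frozen=True)
class PSTH:
    """Trial-averaged binned spike rate on the stimulus window."""

    edges: np.ndarray   # bin edges, s
    rate: np.ndarray    # Hz per bin, averaged over trials
    bin_width: float    # s


def _bin_counts(trials: list[SpikeTrain], bin_width: float, duration: float) -> np.ndarray:
    """Summed per-bin spike counts over trials.  Bins are left-closed,
    right-open; the final bin is right-closed (np.histogram convention)."""
    n_bins = max(1, int(round(duration / bin_width)))
    edges = np.linspace(0.0, duration, n_bins + 1)
    counts = np.zeros(n_bins)
    for t in trials:
        counts += np.histogram(t.times, bins=edges)[0]
    return counts


def psth(trials: list[SpikeTrain], bin_width: float = 0.020) -> PSTH:
    """Peristimulus time histogram averaged over trials (Hz)."""
    if not trials:
        raise ValueError("need at least one trial")
    T = trials[0].duration
    counts = _bin_counts(trials, bin_width, T)
    n_bins = counts.size
    edges = np.linspace(0.0, T, n_bins + 1)
    return PSTH(edges=edges, rate=counts / (len(trials) * bin_width), bin_width=bin_width)


def evoked_rate(ts: TrialSet) -> float:
    """Mean firing rate over the stimulus window across trials (Hz)."""
    if not ts.trials:
        raise ValueError("empty trial list")
    total = sum(len(t) for t in ts.trials)
    return total / (len(ts.trials) * ts.duration)


def trial_similarity(
    ts: TrialSet,
    bin_width: float = DEFAULT_BIN,
    n_repeats: int = 100,
    seed: int = 0,
) -> float:
    """Split-half reproducibility of the temporal response.

    Trials are randomly divided into two equal halves, spike times binned at
    ``bin_width`` (25 ms default), and Pearson's r computed between the two
    half-PSTHs; the mean over ``n_repeats`` random splits is returned.
    Splits with a zero-variance PSTH are excluded from the mean (logged).
    """
    n = len(ts)
    if n < 4:
        raise ValueError("trial similarity needs >= 4 trials")
    rng = np.random.default_rng(seed)
    half = n // 2
    T = ts.duration
    n_bins = max(1, int(round(T / bin_width)))
    edges = np.linspace(0.0, T, n_bins + 1)
    binned = np.stack([np.histogram(t.times, bins=edges)[0] for t in ts.trials])
    rs = []
    n_undefined = 0
    for _ in range(n_repeats):
        perm = rng.permutation(n)
        p1 = binned[perm[:half]].sum(axis=0)
        p2 = binned[perm[half : 2 * half]].sum(axis=0)
        if p1.std() == 0 or p2.std() == 0:
            n_undefined += 1
            continue
        rs.append(np.corrcoef(p1, p2)[0, 1])
    if n_undefined:
        log.info("trial_similarity: %d/%d splits had zero-variance PSTHs", n_undefined, n_repeats)
    if not rs:
        raise ValueError("all splits had zero-variance PSTHs")
    return float(np.mean(rs))


def rate_normalized_rms(
    set1: TrialSet, set2: TrialSet, bin_width: float = DEFAULT_BIN
) -> float:
    """RMS difference between the two targets' unit-sum PSTHs.

    Each target's PSTH is normalised to sum 1 over time, removing mean-rate
    differences, so the value reflects only the temporal pattern.  Requires
    at least one spike per target.
    """
    if set1.duration != set2.duration:
        raise ValueError("trial sets must share one stimulus window")
    T = set1.duration
    out = []
    for ts in (set1, set2):
        counts = _bin_counts(ts.trials, bin_width, T)
        total = counts.sum()
        if total == 0:
            raise ValueError("rate-normalised RMS undefined for an all-empty target")
        out.append(counts / total)
    p1, p2 = out
    return float(np.sqrt(np.mean((p1 - p2) ** 2)))


def correlate_measures(measures: dict[str, np.ndarray], performance: np.ndarray) -> dict[str, dict]:
    """Pearson correlation of each response measure against performance.

    ``measures`` maps a measure name to per-configuration values aligned with
    ``performance``.  Constant vectors yield an undefined r (flagged).
    """
    perf = np.asarray(performance, dtype=float)
    if perf.size < 3:
        raise ValueError("need >= 3 paired values")
    results: dict[str, dict] = {}
    for name, vals in measures.items():
        v = np.asarray(vals, dtype=float)
        if v.shape != perf.shape:
            raise ValueError(f"measure {name!r} not aligned with performance")
        if v.std() == 0 or perf.std() == 0:
            results[name] = {"r": float("nan"), "p": float("nan"), "undefined": True}
            continue
        r, p = sps.pearsonr(v, perf)
        results[name] = {"r": float(r), "p": float(p), "undefined": False}
    return results
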