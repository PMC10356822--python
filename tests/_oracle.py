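"""Independent brute-force oracle for the time-resolved spike-train metrics.

Evaluates the ISI, SPIKE and RI-SPIKE dissimilarity profiles pointwise on a
dense midpoint grid and integrates numerically.  Deliberately shares no code
with spikegrid.metrics: all local quantities (preceding/following spikes,
interspike intervals, nearest-spike offsets) are recomputed from the raw
spike arrays at every sample time.

The same edge convention is applied (auxiliary spikes at 0 and T in both
trains; an empty train is the auxiliary pair alone) since the time-resolved
quantities are otherwise undefined near the window edges.
"""

from __future__ import annotations

import numpy as np


def _aug(times, T):
    t = np.asarray(times, dtype=float)
    out = [t]
    if t.size == 0 or t[0] > 0:
        out.insert(0, np.array([0.0]))
    if t.size == 0 or t[-1] < T:
        out.append(np.array([T]))
    return np.concatenate(out)


def _local(t, spikes, other):
    """(x_P, x_F, x_ISI, dt_P, dt_F) at sample times t for one train."""
    iP = np.searchsorted(spikes, t, side="right") - 1
    tP = spikes[iP]
    tF = spikes[np.searchsorted(spikes, t, side="right")]
    near = lambda s: np.minimum(  # noqa: E731
        np.abs(s - other[np.clip(np.searchsorted(other, s) - 1, 0, other.size - 1)]),
        np.abs(s - other[np.clip(np.searchsorted(other, s), 0, other.size - 1)]),
    )
    return t - tP, tF - t, tF - tP, near(tP), near(tF)


def numeric_profiles(a_times, b_times, T, dt=2e-6):
    """Dense midpoint samples of the ISI, SPIKE and RI-SPIKE profiles.

    Returns (t, isi, spike, ri) arrays; the scalar distances are the means
    of the profile arrays (midpoint quadrature of the window-normalised
    integral).
    """
    A = _aug(a_times, T)
    B = _aug(b_times, T)
    n = int(round(T / dt))
    t = (np.arange(n) + 0.5) * dt

    xP1, xF1, x1, dP1, dF1 = _local(t, A, B)
    xP2, xF2, x2, dP2, dF2 = _local(t, B, A)

    S1 = (dP1 * xF1 + dF1 * xP1) / x1
    S2 = (dP2 * xF2 + dF2 * xP2) / x2
    mean_isi = 0.5 * (x1 + x2)

    isi = np.abs(x1 - x2) / np.maximum(x1, x2)
    spike = (S1 * x2 + S2 * x1) / (2.0 * mean_isi**2)
    ri = (S1 + S2) / (2.0 * mean_isi)
    return t, isi, spike, ri


def numeric_distances(a_times, b_times, T, dt=2e-6):
    """(isi, spike, ri_spike) scalar distances by dense numeric integration."""
    _, isi, spike, ri = numeric_profiles(a_times, b_times, T, dt)
    return float(isi.mean()), float(spike.mean()), float(ri.mean())


def random_train(rng, rate, T):
    """Homogeneous Poisson spike times on [0, T]."""
    n = rng.poisson(rate * T)
    return np.sort(rng.uniform(0.0, T, n))
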