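"""Spike-train distance family: ISI-, SPIKE-, RI-SPIKE-, spike-count and
van Rossum distances.

The time-resolved measures are computed piecewise-analytically.  Between any
two consecutive spikes of the merged pair of trains the dissimilarity profile
is linear in t (constant for the ISI profile), so the scalar distance — the
window-normalised integral of the profile — is obtained exactly from the
profile's corner values, with no discretisation.

Edge convention
---------------
Auxiliary spikes at t = 0 and t = T are added to *both* trains before
computing preceding/following spikes, interspike intervals and
nearest-spike offsets.  The time-resolved quantities are undefined before a
train's first and after its last spike, and this convention (that of the
measures' originating toolbox) closes the window; an empty train reduces to
the auxiliary pair alone.  Because both trains carry the auxiliary spikes,
the nearest-spike offsets of the auxiliary spikes themselves vanish.

The van Rossum distance filters each train with a causal unit-height
exponential kernel e^{-t/tau} and takes the L2 norm of the difference,
scaled by 1/tau.  It is evaluated through the exponential Gram identity
(1/tau) * integral of kernel_i * kernel_j over [0, inf) = exp(-|t_i-t_j|/tau) / 2,
so the integral's tail beyond the stimulus window is included exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .trains import SpikeTrain

__all__ = [
    "DissimilarityProfile",
    "DistanceMatrix",
    "isi_distance",
    "spike_distance",
    "ri_spike_distance",
    "spike_count_distance",
    "van_rossum_distance",
    "pairwise_distances",
    "dissimilarity_profile",
    "METRICS",
]


# ---------------------------------------------------------------------------
# piecewise machinery
# ---------------------------------------------------------------------------

def _augment(times: np.ndarray, duration: float) -> np.ndarray:
    """Spike times with auxiliary edge spikes at 0 and ``duration``."""
    parts = []
    if times.size == 0 or times[0] > 0.0:
        parts.append([0.0])
    parts.append(times)
    if times.size == 0 or times[-1] < duration:
        parts.append([duration])
    return np.concatenate([np.asarray(p, dtype=float) for p in parts])


def _nearest_offset(points: np.ndarray, other: np.ndarray) -> np.ndarray:
    """|point - nearest spike of other train| for each point (other sorted)."""
    idx = np.searchsorted(other, points)
    lo = np.clip(idx - 1, 0, other.size - 1)
    hi = np.clip(idx, 0, other.size - 1)
    return np.minimum(np.abs(points - other[lo]), np.abs(points - other[hi]))


def _check_pair(a: SpikeTrain, b: SpikeTrain) -> float:
    if a.duration != b.duration:
        raise ValueError(
            f"trains must share one window: {a.duration} s vs {b.duration} s"
        )
    return a.duration


def _piecewise(a: SpikeTrain, b: SpikeTrain):
    """Interval decomposition shared by the ISI/SPIKE/RI-SPIKE profiles.

    Returns ``(left_edges, right_edges, isi, s_left, s_right, x1, x2)`` where
    ``isi`` is the (piecewise-constant) ISI profile, ``s_left``/``s_right``
    are per-train timing terms S_n(t) evaluated at both interval ends
    (shape 2 x n_intervals), and ``x1``/``x2`` the per-train interspike
    intervals covering each piece.
    """
    T = _check_pair(a, b)
    aug = (_augment(a.times, T), _augment(b.times, T))
    edges = np.union1d(aug[0], aug[1])
    L, R = edges[:-1], edges[1:]
    # drop zero-measure pieces (events closer than 1 ps are indistinguishable
    # on any physiological timescale and would underflow the denominators)
    wide = (R - L) > 1e-12
    L, R = L[wide], R[wide]

    x_isi = []
    s_L, s_R = [], []
    for n, other in ((0, 1), (1, 0)):
        t = aug[n]
        tP = t[np.searchsorted(t, L, side="right") - 1]
        tF = t[np.searchsorted(t, R, side="left")]
        x = tF - tP
        dtP = _nearest_offset(tP, aug[other])
        dtF = _nearest_offset(tF, aug[other])
        # S_n(t) = (dtP * (tF - t) + dtF * (t - tP)) / x_isi, linear in t
        s_L.append((dtP * (tF - L) + dtF * (L - tP)) / x)
        s_R.append((dtP * (tF - R) + dtF * (R - tP)) / x)
        x_isi.append(x)

    x1, x2 = x_isi
    isi = np.abs(x1 - x2) / np.maximum(x1, x2)
    return L, R, isi, np.array(s_L), np.array(s_R), x1, x2


def _spike_profile_values(s: np.ndarray, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    # local rate weighting: S = (S1*x2 + S2*x1) / (2 * mean(x1,x2)^2)
    return 2.0 * (s[0] * x2 + s[1] * x1) / (x1 + x2) ** 2


def _ri_profile_values(s: np.ndarray, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    # rate weighting skipped: S_RI = (S1 + S2) / (2 * mean(x1,x2))
    return (s[0] + s[1]) / (x1 + x2)


def isi_distance(a: SpikeTrain, b: SpikeTrain) -> float:
    """ISI-distance: window-normalised integral of |x1-x2| / max(x1, x2).

    Zero for identical trains; asymptotically zero for equal constant rates
    under a global phase shift (edge pieces contribute O(period/T)).
    """
    L, R, isi, *_ = _piecewise(a, b)
    return float(np.sum(isi * (R - L)) / a.duration)


def spike_distance(a: SpikeTrain, b: SpikeTrain) -> float:
    """SPIKE-distance: timing dissimilarity weighted by local firing rates."""
    L, R, _, s_L, s_R, x1, x2 = _piecewise(a, b)
    vL = _spike_profile_values(s_L, x1, x2)
    vR = _spike_profile_values(s_R, x1, x2)
    return float(np.sum(0.5 * (vL + vR) * (R - L)) / a.duration)


def ri_spike_distance(a: SpikeTrain, b: SpikeTrain) -> float:
    """Rate-independent SPIKE-distance: the local rate weighting is skipped,
    so only relative spike timing contributes."""
    L, R, _, s_L, s_R, x1, x2 = _piecewise(a, b)
    vL = _ri_profile_values(s_L, x1, x2)
    vR = _ri_profile_values(s_R, x1, x2)
    return float(np.sum(0.5 * (vL + vR) * (R - L)) / a.duration)


def spike_count_distance(a: SpikeTrain, b: SpikeTrain) -> int:
    """Absolute difference in total spike count."""
    return abs(len(a) - len(b))


# ---------------------------------------------------------------------------
# time-resolved profiles (for inspection/plotting)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DissimilarityProfile:
    """Piecewise profile of a time-resolved dissimilarity measure.

    ``values_left[i]`` / ``values_right[i]`` are the profile limits at the two
    ends of the interval ``(breakpoints[i], breakpoints[i+1])``; the profile is
    linear within each interval (constant for kind='isi').
    """

    breakpoints: np.ndarray
    values_left: np.ndarray
    values_right: np.ndarray
    kind: str
    duration: float

    def integral(self) -> float:
        """Window-normalised integral — the scalar distance."""
        widths = np.diff(self.breakpoints)
        return float(np.sum(0.5 * (self.values_left + self.values_right) * widths) / self.duration)


def dissimilarity_profile(a: SpikeTrain, b: SpikeTrain, kind: str = "spike") -> DissimilarityProfile:
    """Time-resolved profile of kind ``'isi'``, ``'spike'`` or ``'ri_spike'``."""
    L, R, isi, s_L, s_R, x1, x2 = _piecewise(a, b)
    if kind == "isi":
        vL = vR = isi
    elif kind == "spike":
        vL = _spike_profile_values(s_L, x1, x2)
        vR = _spike_profile_values(s_R, x1, x2)
    elif kind == "ri_spike":
        vL = _ri_profile_values(s_L, x1, x2)
        vR = _ri_profile_values(s_R, x1, x2)
    else:
        raise ValueError(f"unknown profile kind {kind!r}")
    return DissimilarityProfile(
        breakpoints=np.concatenate([L, [R[-1]]]),
        values_left=np.asarray(vL, dtype=float),
        values_right=np.asarray(vR, dtype=float),
        kind=kind,
        duration=a.duration,
    )


# ---------------------------------------------------------------------------
# van Rossum
# ---------------------------------------------------------------------------

def van_rossum_distance(a: SpikeTrain, b: SpikeTrain, tau: float) -> float:
    """van Rossum distance with causal exponential kernel of time constant tau (s).

    D^2 = (1/tau) * integral (f1 - f2)^2 over [0, inf), f_i the train filtered
    with the unit-height kernel e^{-t/tau}.  Evaluated exactly over spike
    pairs: each kernel cross-term integrates to (tau/2) e^{-|dt|/tau}.
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    _check_pair(a, b)

    def gram(x: np.ndarray, y: np.ndarray) -> float:
        if x.size == 0 or y.size == 0:
            return 0.0
        return float(np.sum(np.exp(-np.abs(x[:, None] - y[None, :]) / tau)))

    ta, tb = a.times, b.times
    d2 = 0.5 * (gram(ta, ta) + gram(tb, tb) - 2.0 * gram(ta, tb))
    return float(np.sqrt(max(d2, 0.0)))


# ---------------------------------------------------------------------------
# pairwise matrices
# ---------------------------------------------------------------------------

METRICS: dict[str, Callable] = {
    "isi": isi_distance,
    "spike": spike_distance,
    "ri_spike": ri_spike_distance,
    "count": spike_count_distance,
    "van_rossum": van_rossum_distance,
}


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix over a list of trains."""

    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def pairwise_distances(
    trains: list[SpikeTrain], metric: str = "spike", tau: float | None = None
) -> DistanceMatrix:
    """All-pairs distance matrix for the named metric.

    ``tau`` (s) is required for metric='van_rossum' and ignored otherwise.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    if len(trains) < 2:
        raise ValueError("need at least 2 trains")
    if metric == "van_rossum":
        if tau is None:
            raise ValueError("metric 'van_rossum' requires tau")
        fn = lambda a, b: van_rossum_distance(a, b, tau)  # noqa: E731
    else:
        fn = METRICS[metric]
    n = len(trains)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = fn(trains[i], trains[j])
    return DistanceMatrix(values=D, metric=metric)
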