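"""Current source density estimation from laminar LFP and layer assignment.

The one-dimensional CSD is the negative second spatial difference of the
(spatially smoothed) potential along the probe's depth axis.  The granular
(thalamorecipient, L4) channel is the one with the earliest current-sink
onset after stimulus onset, where a sink onset is the first time the CSD
drops below -3 SD of its pre-stimulus values.  Layers are then assigned by
signed depth offset from the granular channel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

__all__ = [
    "LFPArray",
    "CSDProfile",
    "LayerAssignment",
    "preprocess_lfp",
    "smooth_lfp",
    "estimate_csd",
    "sink_onset_times",
    "assign_layers",
    "layer_for_offset",
]

log = logging.getLogger(__name__)

LAYERS = ("L1", "L2/3", "L4", "L5", "L6")

#: Channels per shank and contact spacing of the recording probe.
CHANNELS_PER_SHANK = 8
DEFAULT_SPACING = 100.0  # um


@dataclass(frozen=True)
class LFPArray:
    """Laminar potential: channels x samples, uniform contact spacing.

    Channel 0 is the most superficial contact; depth increases with index.
    """

    data: np.ndarray          # uV, shape (n_channels, n_samples)
    sample_rate: float        # Hz
    spacing: float = DEFAULT_SPACING  # um

    def __post_init__(self) -> None:
        d = np.atleast_2d(np.asarray(self.data, dtype=float))
        if d.shape[0] < 3:
            raise ValueError("need >= 3 channels for CSD analysis")
        object.__setattr__(self, "data", d)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.data.shape[1]) / self.sample_rate


@dataclass(frozen=True)
class CSDProfile:
    """CSD per interior channel (uV per spacing^2); channel index ``i`` of
    ``values`` corresponds to LFP channel ``i + 1``."""

    values: np.ndarray        # (n_channels - 2, n_samples)
    sample_rate: float
    spacing: float
    first_channel: int = 1    # LFP channel of values[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.shape[1]) / self.sample_rate


@dataclass(frozen=True)
class LayerAssignment:
    """Per-channel cortical layer labels and the granular channel index."""

    labels: tuple[str, ...]
    granular_channel: int
    spacing: float = DEFAULT_SPACING


def preprocess_lfp(
    raw: LFPArray,
    trials: np.ndarray | None = None,
    cutoff: float = 150.0,
    decimate: int = 8,
    dead_channels: list[int] | None = None,
) -> LFPArray:
    """Low-pass (zero-phase) at ``cutoff``, decimate, trial-average, and
    interpolate dead channels from their neighbours.

    ``trials``, if given, is a (n_trials, n_channels, n_samples) stack that is
    averaged after filtering; otherwise ``raw.data`` is used as the single
    (already averaged) sweep.  Filtering is forward-backward so that sink
    onset times are not delayed by filter phase.  Dead channels at a shank
    edge are copied from the nearest live neighbour (logged).
    """
    if raw.sample_rate <= 2 * cutoff:
        raise ValueError("raw sampling rate must exceed twice the low-pass cutoff")
    stack = trials if trials is not None else raw.data[None, :, :]
    stack = np.asarray(stack, dtype=float)
    sos = signal.butter(4, cutoff, btype="lowpass", fs=raw.sample_rate, output="sos")
    filt = signal.sosfiltfilt(sos, stack, axis=-1)
    avg = filt.mean(axis=0)[:, ::decimate]
    if dead_channels:
        n = avg.shape[0]
        live = sorted(set(range(n)) - set(dead_channels))
        if not live:
            raise ValueError("all channels marked dead")
        for c in dead_channels:
            below = [i for i in live if i < c]
            above = [i for i in live if i > c]
            if below and above:
                lo, hi = below[-1], above[0]
                w = (c - lo) / (hi - lo)
                avg[c] = (1 - w) * avg[lo] + w * avg[hi]
            else:
                nearest = above[0] if above else below[-1]
                avg[c] = avg[nearest]
                log.warning("dead channel %d at shank edge: copied channel %d", c, nearest)
    return LFPArray(data=avg, sample_rate=raw.sample_rate / decimate, spacing=raw.spacing)


def smooth_lfp(lfp: LFPArray) -> LFPArray:
    """Spatial smoothing across the shank with the (1, 2, 1)/4 kernel.

    Interior channels get (phi(z+dz) + 2 phi(z) + phi(z-dz)) / 4; edge
    channels are copied unchanged (the kernel is undefined there).
    """
    d = lfp.data
    out = d.copy()
    out[1:-1] = (d[2:] + 2.0 * d[1:-1] + d[:-2]) / 4.0
    return replace(lfp, data=out)


def estimate_csd(lfp: LFPArray) -> CSDProfile:
    """Negative second spatial difference of the potential.

    CSD(z) = -(phi(z+dz) - 2 phi(z) + phi(z-dz)) / dz^2 with dz the contact
    spacing, defined on interior channels only.  Under this sign convention
    a localised potential minimum in depth — a current sink — gives negative
    CSD, which is what the -3 SD sink-onset threshold detects
    (see :func:`sink_onset_times`).
    """
    d = lfp.data
    csd = -(d[2:] - 2.0 * d[1:-1] + d[:-2]) / lfp.spacing**2
    return CSDProfile(values=csd, sample_rate=lfp.sample_rate, spacing=lfp.spacing)


def sink_onset_times(
    csd: CSDProfile, stim_onset: float, pre_start: float = 0.0
) -> list[float | None]:
    """Per-channel sink onset: first time at/after ``stim_onset`` where the
    CSD drops below -3 SD of its pre-stimulus values.

    Channels that never cross return None; channels with zero pre-stimulus SD
    are skipped with a warning (None).
    """
    t = csd.times
    pre = (t >= pre_start) & (t < stim_onset)
    if not pre.any():
        raise ValueError("empty pre-stimulus window")
    post = t >= stim_onset
    onsets: list[float | None] = []
    for ch in range(csd.values.shape[0]):
        sd = csd.values[ch, pre].std()
        if sd == 0:
            log.warning("channel %d: zero pre-stimulus SD; sink onset undefined", ch + csd.first_channel)
            onsets.append(None)
            continue
        below = csd.values[ch, post] < -3.0 * sd
        idx = np.flatnonzero(below)
        onsets.append(float(t[post][idx[0]]) if idx.size else None)
    return onsets


def layer_for_offset(offset_um: float) -> str:
    """Layer label for a signed depth offset from the granular channel
    (positive = above / more superficial).

    The band boundaries follow the anatomical widths: L4 is the granular
    channel and the channel 100 um above; L2/3 spans 200-400 um above; L1 is
    >= 500 um above; L5 spans 100-300 um below; L6 is >= 400 um below.  Band
    cutoffs are placed midway between quoted offsets so off-grid depths fall
    to the nearest defined band.
    """
    if offset_um >= 450.0:
        return "L1"
    if offset_um >= 150.0:
        return "L2/3"
    if offset_um >= -50.0:
        return "L4"
    if offset_um >= -350.0:
        return "L5"
    return "L6"


def _granular_channel(onsets: list[float | None]) -> int:
    defined = [(t, i) for i, t in enumerate(onsets) if t is not None]
    if not defined:
        raise ValueError("no channel crossed the sink threshold; cannot assign layers")
    earliest = min(t for t, _ in defined)
    candidates = [i for t, i in defined if t == earliest]
    if len(candidates) == 1:
        return candidates[0]

    # tie: prefer the candidate whose neighbours have the earliest onsets
    def neighbour_score(i: int) -> float:
        vals = [
            onsets[j]
            for j in (i - 1, i + 1)
            if 0 <= j < len(onsets) and onsets[j] is not None
        ]
        return float(np.mean(vals)) if vals else math.inf

    return min(candidates, key=lambda i: (neighbour_score(i), i))


def assign_layers(
    onsets: list[float | None],
    spacing: float = DEFAULT_SPACING,
    first_channel: int = 1,
    n_channels: int | None = None,
) -> LayerAssignment:
    """Label every channel of a shank by its offset from the granular channel.

    ``onsets`` are per-CSD-channel sink onsets (CSD channel i = LFP channel
    i + ``first_channel``); the granular channel is the earliest onset, ties
    broken by earliest-onset neighbours.  ``n_channels`` (default: onsets
    span plus the two CSD-less edge channels) sets how many LFP channels to
    label.
    """
    gran_csd = _granular_channel(onsets)
    gran = gran_csd + first_channel
    n = n_channels if n_channels is not None else len(onsets) + 2 * first_channel
    labels = tuple(
        layer_for_offset((gran - c) * spacing) for c in range(n)
    )
    return LayerAssignment(labels=labels, granular_channel=gran, spacing=spacing)
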