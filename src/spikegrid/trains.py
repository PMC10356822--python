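"""Core containers: single spike trains and per-configuration trial ensembles.

A :class:`SpikeTrain` is an immutable, sorted array of spike times on a fixed
stimulus window ``[0, duration]``.  A :class:`TrialSet` bundles the repeated
responses (nominally 10 trials) of one unit to one target stimulus at one
spatial configuration and optogenetic condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["SpikeTrain", "SceneConfig", "TrialSet", "DEFAULT_DURATION"]

#: Stimulus window length in seconds used throughout the analysis.
DEFAULT_DURATION = 3.0

#: Azimuthal speaker locations (degrees); negative = ipsilateral to the
#: recorded right hemisphere.
TARGET_LOCATIONS = (-90, 0, 45, 90)
MASKER_LOCATIONS = ("none", -90, 0, 45, 90)


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (s) on the stimulus window ``[0, duration]``."""

    times: np.ndarray
    duration: float = DEFAULT_DURATION

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float).ravel()
        if t.size and np.any(np.diff(t) < 0):
            t = np.sort(t)
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if t.size and (t[0] < 0 or t[-1] > self.duration):
            raise ValueError(
                f"spike times must lie in [0, {self.duration}]: "
                f"range [{t[0]}, {t[-1]}]"
            )
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def count(self) -> int:
        return int(self.times.size)

    @property
    def rate(self) -> float:
        """Mean firing rate over the window (Hz)."""
        return self.times.size / self.duration


@dataclass(frozen=True)
class SceneConfig:
    """One speaker configuration: target location, masker location, and the
    degradation the masker imposes on envelope locking.

    ``masker_loc`` is ``"none"`` for clean (target-alone) trials, in which
    case ``masker_strength`` must be 0.  ``masker_strength`` in [0, 1] scales
    down the envelope-following gain; ``masker_baseline`` (Hz) is additive
    unmodulated drive from the masker noise.
    """

    target_loc: int
    masker_loc: int | str = "none"
    masker_strength: float = 0.0
    masker_baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.target_loc not in TARGET_LOCATIONS:
            raise ValueError(f"target_loc must be one of {TARGET_LOCATIONS}")
        if self.masker_loc not in MASKER_LOCATIONS:
            raise ValueError(f"masker_loc must be one of {MASKER_LOCATIONS}")
        if not 0.0 <= self.masker_strength <= 1.0:
            raise ValueError("masker_strength must be in [0, 1]")
        if self.masker_baseline < 0:
            raise ValueError("masker_baseline must be >= 0")
        if self.is_clean and (self.masker_strength != 0 or self.masker_baseline != 0):
            raise ValueError("clean configurations must have zero masker effect")

    @property
    def is_clean(self) -> bool:
        return self.masker_loc == "none"


@dataclass
class TrialSet:
    """Trial ensemble of one unit for one target at one configuration."""

    unit_id: str
    condition: str  # "control" | "laser"
    target_id: int  # 1 | 2
    scene: SceneConfig
    trials: list[SpikeTrain] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.condition not in ("control", "laser"):
            raise ValueError("condition must be 'control' or 'laser'")
        if self.target_id not in (1, 2):
            raise ValueError("target_id must be 1 or 2")
        durations = {t.duration for t in self.trials}
        if len(durations) > 1:
            raise ValueError("all trials must share one stimulus window")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def duration(self) -> float:
        return self.trials[0].duration if self.trials else DEFAULT_DURATION

    @property
    def n_empty(self) -> int:
        """Number of trials with zero spikes (drives the exclusion rule)."""
        return sum(1 for t in self.trials if len(t) == 0)


def as_trains(times_list: Sequence[Sequence[float]], duration: float = DEFAULT_DURATION) -> list[SpikeTrain]:
    """Convenience: wrap raw time sequences as :class:`SpikeTrain` objects."""
    return [SpikeTrain(np.asarray(t, dtype=float), duration) for t in times_list]
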