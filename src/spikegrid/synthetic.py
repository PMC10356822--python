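"""Synthetic spike trains and laminar LFPs with the statistical structure the
analysis pipeline assumes.

The generator emulates auditory-cortex single-unit responses in a spatial
cocktail-party paradigm: targets are noise tokens modulated by speech-like
envelopes (slow 2-10 Hz modulations), units follow the envelope with some
gain, onset latency, per-spike timing jitter and per-spike reliability, and a
competing masker degrades envelope locking in a configuration-dependent way.
An optogenetic-suppression condition is modelled phenomenologically as an
elevated unmodulated rate, earlier onset, and increased timing jitter
(reduced reproducibility).

Spike trains are drawn from an inhomogeneous Poisson process by thinning,
with rate

    lambda(t) = baseline + masker_baseline
                + gain * (1 - masker_strength) * envelope(t - onset_latency)

followed by, in fixed order: reliability thinning (each spike kept with
probability ``reliability``), Gaussian timing jitter (``jitter_sd``),
refractory enforcement by deletion, and clipping to the stimulus window.
Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .trains import DEFAULT_DURATION, MASKER_LOCATIONS, TARGET_LOCATIONS, SceneConfig, SpikeTrain

__all__ = [
    "StimulusEnvelope",
    "ResponseModel",
    "SuppressionEffect",
    "DEFAULT_MODEL",
    "DEFAULT_SUPPRESSION",
    "generate_envelope",
    "generate_trial_set",
    "apply_suppression",
    "generate_lfp",
    "default_masker_strength",
    "scene_for",
]


@dataclass(frozen=True)
class StimulusEnvelope:
    """Normalised amplitude envelope of one target stimulus."""

    samples: np.ndarray  # amplitudes in [0, 1]
    sample_rate: float   # Hz
    duration: float      # s

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if np.any(s < 0):
            raise ValueError("envelope samples must be non-negative")
        object.__setattr__(self, "samples", s)

    def value_at(self, t: np.ndarray) -> np.ndarray:
        """Envelope amplitude at times ``t`` (s); zero outside [0, duration]."""
        t = np.asarray(t, dtype=float)
        grid = np.arange(self.samples.size) / self.sample_rate
        v = np.interp(t, grid, self.samples, left=0.0, right=0.0)
        return np.where((t < 0) | (t > self.duration), 0.0, v)


@dataclass(frozen=True)
class ResponseModel:
    """Phenomenological single-unit response parameters.

    baseline_rate : Hz, envelope-independent drive
    gain          : Hz per unit envelope amplitude
    onset_latency : s, response delay relative to the stimulus
    jitter_sd     : s, SD of per-spike Gaussian timing jitter
    reliability   : probability each driven spike is emitted
    refractory    : s, minimum interspike interval (enforced by deletion)
    """

    baseline_rate: float = 2.0
    gain: float = 25.0
    onset_latency: float = 0.015
    jitter_sd: float = 0.003
    reliability: float = 0.85
    refractory: float = 0.002

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.gain < 0:
            raise ValueError("rates must be non-negative")
        if self.onset_latency < 0 or self.jitter_sd < 0 or self.refractory < 0:
            raise ValueError("time constants must be non-negative")
        if not 0.0 <= self.reliability <= 1.0:
            raise ValueError("reliability must be in [0, 1]")


@dataclass(frozen=True)
class SuppressionEffect:
    """Phenomenological effect of suppressing PV interneurons: elevated rate,
    earlier onset, reduced spike-timing reproducibility."""

    rate_multiplier: float = 1.5
    added_baseline: float = 4.0   # Hz
    jitter_multiplier: float = 3.0
    latency_shift: float = -0.005  # s; negative = earlier onset

    def __post_init__(self) -> None:
        if self.rate_multiplier < 1 or self.jitter_multiplier < 1:
            raise ValueError("rate_multiplier and jitter_multiplier must be >= 1")
        if self.added_baseline < 0:
            raise ValueError("added_baseline must be >= 0")


DEFAULT_MODEL = ResponseModel()
DEFAULT_SUPPRESSION = SuppressionEffect()


def apply_suppression(model: ResponseModel, effect: SuppressionEffect) -> ResponseModel:
    """Response model under optogenetic suppression of inhibition."""
    return replace(
        model,
        baseline_rate=model.baseline_rate * effect.rate_multiplier + effect.added_baseline,
        jitter_sd=model.jitter_sd * effect.jitter_multiplier,
        onset_latency=max(0.0, model.onset_latency + effect.latency_shift),
    )


def generate_envelope(
    duration: float = DEFAULT_DURATION,
    band: tuple[float, float] = (2.0, 10.0),
    seed: int = 0,
    sample_rate: float = 1000.0,
) -> StimulusEnvelope:
    """Speech-like amplitude envelope: band-limited Gaussian noise,
    Hilbert-rectified and peak-normalised.

    The band defaults to 2-10 Hz, the range of the slow modulations of
    natural speech envelopes.  The result is deterministic in ``seed``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    lo, hi = band
    if not 0 < lo < hi < sample_rate / 2:
        raise ValueError(f"band must satisfy 0 < lo < hi < Nyquist, got {band}")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    noise = rng.standard_normal(n)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=sample_rate, output="sos")
    narrow = signal.sosfiltfilt(sos, noise)
    env = np.abs(signal.hilbert(narrow))
    peak = env.max()
    if peak > 0:
        env = env / peak
    return StimulusEnvelope(samples=env, sample_rate=sample_rate, duration=duration)


def matched_envelope_pair(
    duration: float = DEFAULT_DURATION,
    band: tuple[float, float] = (2.0, 10.0),
    seed: int = 0,
    rel_tol: float = 0.02,
    sample_rate: float = 1000.0,
) -> tuple[StimulusEnvelope, StimulusEnvelope]:
    """Two distinct envelope tokens with matched mean amplitude.

    Emulates level-equalised target stimuli: both tokens drive the same
    expected spike count, so target identity is carried by temporal pattern
    rather than overall rate.  The second token is searched over seeds until
    its mean is within ``rel_tol`` of the first's.  Deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    env1 = generate_envelope(duration, band, int(rng.integers(2**31)), sample_rate)
    m1 = env1.samples.mean()
    for _ in range(2000):
        env2 = generate_envelope(duration, band, int(rng.integers(2**31)), sample_rate)
        if abs(env2.samples.mean() - m1) <= rel_tol * m1 and not np.array_equal(
            env2.samples, env1.samples
        ):
            return env1, env2
    raise RuntimeError("no mean-matched envelope found; loosen rel_tol")


def _thin_refractory(times: np.ndarray, refractory: float) -> np.ndarray:
    if refractory <= 0 or times.size < 2:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory:
            kept.append(t)
    return np.asarray(kept)


def generate_trial_set(
    envelope: StimulusEnvelope,
    model: ResponseModel,
    scene: SceneConfig,
    n_trials: int = 10,
    seed: int = 0,
) -> list[SpikeTrain]:
    """Simulate the trial ensemble of one unit for one target/configuration.

    The envelope-locked component is a *frozen* master pattern, drawn once
    per trial set from an inhomogeneous Poisson process with rate
    ``gain * (1 - masker_strength) * envelope(t - onset_latency)`` (by
    thinning against the peak rate).  Each trial then applies, in fixed
    order: per-spike deletion with probability ``1 - reliability``, Gaussian
    timing jitter (``jitter_sd``), superposition of independent background
    spikes at rate ``baseline_rate + masker_baseline`` (homogeneous
    Poisson, fresh per trial), refractory enforcement by deletion, and
    clipping to the window (spikes jittered outside [0, T] are dropped).

    Sharing the master pattern across trials is what gives the ensemble its
    trial-to-trial reproducibility: reliability and jitter degrade the
    repeatable stimulus-locked structure, while the background adds
    stimulus-independent variability.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    T = envelope.duration
    eff_gain = model.gain * (1.0 - scene.masker_strength)
    noise_rate = model.baseline_rate + scene.masker_baseline
    assert eff_gain >= 0 and noise_rate >= 0, "negative instantaneous rate"
    rng = np.random.default_rng(seed)

    # Master pattern: fixed count at the rate integral's expectation, spike
    # locations i.i.d. proportional to the (latency-shifted) envelope.  Fixing
    # the count removes spurious across-target spike-count cues that a raw
    # Poisson draw would freeze into the pattern; per-trial counts still vary
    # through reliability and the background process.
    master = np.empty(0)
    if eff_gain > 0:
        grid = np.arange(int(round(T * envelope.sample_rate))) / envelope.sample_rate
        weight = envelope.value_at(grid - model.onset_latency)
        n_master = int(round(eff_gain * T * weight.mean()))
        placed: list[np.ndarray] = []
        n_left = n_master
        while n_left > 0:
            cand = rng.uniform(0.0, T, 4 * n_left + 16)
            acc = cand[rng.uniform(size=cand.size) < envelope.value_at(cand - model.onset_latency)]
            placed.append(acc[:n_left])
            n_left -= min(n_left, acc.size)
        if placed:
            master = np.sort(np.concatenate(placed))

    trials: list[SpikeTrain] = []
    for _ in range(n_trials):
        times = master
        if model.reliability < 1.0:
            times = times[rng.uniform(size=times.size) < model.reliability]
        if model.jitter_sd > 0:
            times = times + rng.normal(0.0, model.jitter_sd, times.size)
        if noise_rate > 0:
            background = rng.uniform(0.0, T, rng.poisson(noise_rate * T))
            times = np.concatenate([times, background])
        times = np.sort(times)
        times = _thin_refractory(times, model.refractory)
        times = times[(times >= 0.0) & (times <= T)]
        trials.append(SpikeTrain(times, T))
    return trials


# ---------------------------------------------------------------------------
# spatial masker phenomenology
# ---------------------------------------------------------------------------

def default_masker_strength(target_loc: int, masker_loc: int | str) -> float:
    """Stipulated per-configuration degradation of envelope locking.

    Co-located target/masker configurations and maskers on the ipsilateral
    side (-90 deg) are assigned the strongest degradation; degradation
    otherwise falls with angular target-masker separation.  This reproduces
    the qualitative structure of measured spatial grids (hotspots at spatially
    separated configurations) without claiming a mechanistic model.
    """
    if masker_loc == "none":
        return 0.0
    sep = abs(target_loc - masker_loc)
    strength = float(np.clip(0.85 - 0.3 * sep / 180.0, 0.2, 0.95))
    if masker_loc == -90 and target_loc != -90:
        strength = max(strength, 0.75)
    return strength


def scene_for(target_loc: int, masker_loc: int | str = "none") -> SceneConfig:
    """SceneConfig with the default degradation table applied."""
    s = default_masker_strength(target_loc, masker_loc)
    baseline = 5.0 * s if masker_loc != "none" else 0.0
    return SceneConfig(
        target_loc=target_loc,
        masker_loc=masker_loc,
        masker_strength=s,
        masker_baseline=baseline,
    )


def all_scenes() -> list[SceneConfig]:
    """The 4 clean + 16 masked speaker configurations of the paradigm."""
    scenes = [scene_for(t) for t in TARGET_LOCATIONS]
    scenes += [
        scene_for(t, m)
        for t in TARGET_LOCATIONS
        for m in MASKER_LOCATIONS
        if m != "none"
    ]
    return scenes


# ---------------------------------------------------------------------------
# whole-dataset simulation
# ---------------------------------------------------------------------------

def _random_unit_model(rng: np.random.Generator) -> ResponseModel:
    """Heterogeneous unit parameters within realistic cortical ranges."""
    return ResponseModel(
        baseline_rate=float(rng.uniform(1.0, 4.0)),
        gain=float(rng.uniform(15.0, 35.0)),
        onset_latency=float(rng.uniform(0.010, 0.025)),
        jitter_sd=float(rng.uniform(0.002, 0.005)),
        reliability=float(rng.uniform(0.70, 0.95)),
        refractory=0.002,
    )


def simulate_unit(
    unit_id: str,
    envelopes: tuple[StimulusEnvelope, StimulusEnvelope],
    model: ResponseModel,
    scenes: list[SceneConfig],
    conditions: tuple[str, ...] = ("control", "laser"),
    effect: SuppressionEffect = DEFAULT_SUPPRESSION,
    n_trials: int = 10,
    seed: int = 0,
) -> list["TrialSet"]:
    """All trial sets of one unit: every scene x target x condition."""
    from .trains import TrialSet

    rng = np.random.default_rng(seed)
    out: list[TrialSet] = []
    for condition in conditions:
        m = model if condition == "control" else apply_suppression(model, effect)
        for scene in scenes:
            for target_id in (1, 2):
                trial_seed = int(rng.integers(2**31))
                trials = generate_trial_set(
                    envelopes[target_id - 1], m, scene, n_trials=n_trials, seed=trial_seed
                )
                out.append(
                    TrialSet(
                        unit_id=unit_id,
                        condition=condition,
                        target_id=target_id,
                        scene=scene,
                        trials=trials,
                    )
                )
    return out


def simulate_dataset(
    n_units: int = 5,
    seed: int = 0,
    scenes: list[SceneConfig] | None = None,
    conditions: tuple[str, ...] = ("control", "laser"),
    effect: SuppressionEffect = DEFAULT_SUPPRESSION,
    n_trials: int = 10,
    duration: float = DEFAULT_DURATION,
) -> list["TrialSet"]:
    """Simulate a whole recording session: ``n_units`` heterogeneous units
    responding to two speech-envelope targets across speaker configurations
    and optogenetic conditions.  Deterministic in ``seed``."""
    rng = np.random.default_rng(seed)
    env1, env2 = matched_envelope_pair(duration=duration, seed=int(rng.integers(2**31)))
    if scenes is None:
        scenes = all_scenes()
    dataset = []
    for u in range(n_units):
        model = _random_unit_model(rng)
        dataset.extend(
            simulate_unit(
                unit_id=f"unit{u:03d}",
                envelopes=(env1, env2),
                model=model,
                scenes=scenes,
                conditions=conditions,
                effect=effect,
                n_trials=n_trials,
                seed=int(rng.integers(2**31)),
            )
        )
    return dataset


# ---------------------------------------------------------------------------
# laminar LFP fixture generator
# ---------------------------------------------------------------------------

def generate_lfp(
    n_channels: int,
    spacing: float,
    profile,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_rate: float = 1000.0,
    duration: float = 1.0,
):
    """Multichannel LFP with channel-c potential ``profile(c * spacing)``
    plus Gaussian noise.

    ``profile`` maps depth (um) to either a scalar (constant in time) or a
    waveform; it may optionally accept ``(depth, t)`` with ``t`` the sample
    time vector.  Returns an :class:`~spikegrid.csd.LFPArray`.
    """
    from .csd import LFPArray  # local import to avoid a cycle

    if n_channels < 3:
        raise ValueError("CSD estimation needs at least 3 channels")
    rng = np.random.default_rng(seed)
    n_samp = int(round(duration * sample_rate))
    t = np.arange(n_samp) / sample_rate
    data = np.empty((n_channels, n_samp))
    for c in range(n_channels):
        z = c * spacing
        try:
            v = profile(z, t)
        except TypeError:
            v = profile(z)
        data[c] = np.broadcast_to(np.asarray(v, dtype=float), (n_samp,))
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, data.shape)
    return LFPArray(data=data, sample_rate=sample_rate, spacing=spacing)
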