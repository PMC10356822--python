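"""Synthetic generators: determinism, rate calibration, suppression arithmetic."""

import numpy as np
import pytest
from scipy import signal

from spikegrid import (
    ResponseModel,
    SceneConfig,
    SuppressionEffect,
    apply_suppression,
    estimate_csd,
    generate_envelope,
    generate_lfp,
    generate_trial_set,
    ri_spike_distance,
    scene_for,
    simulate_dataset,
    smooth_lfp,
)

from conftest import T

CLEAN = SceneConfig(target_loc=0)


# ---------------------------------------------------------------------------
# stimulus envelope
# ---------------------------------------------------------------------------

def test_envelope_normalisation_and_range():
    env = generate_envelope(duration=3.0, band=(2, 10), seed=1)
    assert env.samples.max() == pytest.approx(1.0)
    assert env.samples.min() >= 0.0
    assert env.samples.size == pytest.approx(3.0 * env.sample_rate, abs=1)


def test_envelope_deterministic_in_seed():
    e1 = generate_envelope(seed=7)
    e2 = generate_envelope(seed=7)
    e3 = generate_envelope(seed=8)
    assert np.array_equal(e1.samples, e2.samples)
    assert not np.array_equal(e1.samples, e3.samples)


def test_envelope_spectral_power_in_modulation_band():
    """Speech-envelope surrogate: dominant spectral power at slow (<12 Hz)
    modulation frequencies, across seeds."""
    for seed in range(25):
        env = generate_envelope(band=(2, 10), seed=seed)
        f, p = signal.periodogram(env.samples, fs=env.sample_rate)
        frac = p[f < 12.0].sum() / p.sum()
        assert frac > 0.8


def test_envelope_band_validation():
    with pytest.raises(ValueError):
        generate_envelope(band=(10, 2))
    with pytest.raises(ValueError):
        generate_envelope(band=(0, 10))
    with pytest.raises(ValueError):
        generate_envelope(duration=-1.0)


# ---------------------------------------------------------------------------
# trial generation
# ---------------------------------------------------------------------------

def test_zero_rate_gives_empty_trains():
    env = generate_envelope(seed=0)
    model = ResponseModel(baseline_rate=0.0, gain=0.0)
    trials = generate_trial_set(env, model, CLEAN, n_trials=5, seed=0)
    assert all(len(t) == 0 for t in trials)


def test_trains_sorted_and_in_window():
    env = generate_envelope(seed=0)
    trials = generate_trial_set(env, ResponseModel(), CLEAN, n_trials=20, seed=3)
    for t in trials:
        assert np.all(np.diff(t.times) >= 0)
        assert t.times.size == 0 or (t.times[0] >= 0 and t.times[-1] <= T)


def test_poisson_rate_calibration():
    """baseline 10 Hz, gain 0, reliability 1 over 3 s: mean count within
    3 SE of the analytic expectation of 30."""
    env = generate_envelope(seed=0)
    model = ResponseModel(baseline_rate=10.0, gain=0.0, reliability=1.0, jitter_sd=0.0, refractory=0.0)
    trials = generate_trial_set(env, model, CLEAN, n_trials=1000, seed=11)
    counts = np.array([len(t) for t in trials])
    se = np.sqrt(30.0 / 1000)
    assert abs(counts.mean() - 30.0) < 3 * se


def test_reliability_thins_locked_component():
    """Reliability 0.5 halves the frozen envelope-locked pattern: per-trial
    mean count is half the master count (same seed -> same master)."""
    env = generate_envelope(seed=0)
    kw = dict(baseline_rate=0.0, gain=30.0, jitter_sd=0.0, refractory=0.0)
    full = generate_trial_set(env, ResponseModel(reliability=1.0, **kw), CLEAN, 1, seed=5)
    n_master = len(full[0])
    half = generate_trial_set(env, ResponseModel(reliability=0.5, **kw), CLEAN, 800, seed=5)
    counts = [len(t) for t in half]
    se = np.sqrt(n_master * 0.25 / 800)
    assert abs(np.mean(counts) - 0.5 * n_master) < 3 * se


def test_full_masker_strength_removes_modulation():
    """masker_strength = 1 leaves only the baseline process: mean counts of
    masked and baseline-only trains agree within Poisson error."""
    env = generate_envelope(seed=0)
    model = ResponseModel(baseline_rate=8.0, gain=30.0, reliability=1.0, jitter_sd=0.0, refractory=0.0)
    masked = SceneConfig(target_loc=0, masker_loc=90, masker_strength=1.0)
    base_model = ResponseModel(baseline_rate=8.0, gain=0.0, reliability=1.0, jitter_sd=0.0, refractory=0.0)
    c_masked = np.mean([len(t) for t in generate_trial_set(env, model, masked, 600, seed=1)])
    c_base = np.mean([len(t) for t in generate_trial_set(env, base_model, CLEAN, 600, seed=2)])
    se = np.sqrt(2 * 24.0 / 600)
    assert abs(c_masked - c_base) < 3 * se


def test_trial_set_deterministic_in_seed():
    env = generate_envelope(seed=0)
    t1 = generate_trial_set(env, ResponseModel(), CLEAN, 5, seed=9)
    t2 = generate_trial_set(env, ResponseModel(), CLEAN, 5, seed=9)
    assert all(np.array_equal(a.times, b.times) for a, b in zip(t1, t2))


def test_refractory_enforced():
    env = generate_envelope(seed=0)
    model = ResponseModel(baseline_rate=80.0, gain=0.0, jitter_sd=0.0, reliability=1.0, refractory=0.005)
    for t in generate_trial_set(env, model, CLEAN, 20, seed=4):
        if len(t) > 1:
            assert np.min(np.diff(t.times)) >= 0.005


# ---------------------------------------------------------------------------
# suppression effect
# ---------------------------------------------------------------------------

def test_suppression_identity():
    m = ResponseModel(baseline_rate=5.0, jitter_sd=0.002, onset_latency=0.02)
    assert apply_suppression(m, SuppressionEffect(1.0, 0.0, 1.0, 0.0)) == m


def test_suppression_arithmetic():
    m = ResponseModel(baseline_rate=5.0, jitter_sd=0.002, onset_latency=0.02)
    out = apply_suppression(m, SuppressionEffect(2.0, 3.0, 3.0, -0.005))
    assert out.baseline_rate == pytest.approx(13.0)  # 5*2 + 3
    assert out.jitter_sd == pytest.approx(0.006)
    assert out.onset_latency == pytest.approx(0.015)
    assert out.gain == m.gain


def test_suppression_latency_clipped_at_zero():
    m = ResponseModel(onset_latency=0.003)
    out = apply_suppression(m, SuppressionEffect(latency_shift=-0.05))
    assert out.onset_latency == 0.0


def test_suppression_effect_validation():
    with pytest.raises(ValueError):
        SuppressionEffect(rate_multiplier=0.5)
    with pytest.raises(ValueError):
        SuppressionEffect(jitter_multiplier=0.9)


# ---------------------------------------------------------------------------
# jitter -> timing-distance ordering
# ---------------------------------------------------------------------------

def test_jitter_increases_ri_spike_distance():
    """Mean RI-SPIKE-distance between same-target trials rises strictly with
    the generator's timing jitter (200 replicate pairs per level)."""
    env = generate_envelope(seed=2)
    means = []
    for i, jitter in enumerate([0.001, 0.008, 0.03]):
        model = ResponseModel(baseline_rate=1.0, gain=30.0, jitter_sd=jitter, reliability=0.9)
        trials = generate_trial_set(env, model, CLEAN, n_trials=400, seed=100 + i)
        d = [ri_spike_distance(trials[2 * k], trials[2 * k + 1]) for k in range(200)]
        means.append(np.mean(d))
    assert means[0] < means[1] < means[2]


# ---------------------------------------------------------------------------
# scenes and full-dataset simulation
# ---------------------------------------------------------------------------

def test_scene_validation():
    with pytest.raises(ValueError):
        SceneConfig(target_loc=30)
    with pytest.raises(ValueError):
        SceneConfig(target_loc=0, masker_strength=0.5)  # clean but degraded
    assert scene_for(0).masker_strength == 0.0
    colocated = scene_for(45, 45)
    separated = scene_for(45, -90)
    assert colocated.masker_strength > 0.5
    assert separated.masker_strength > 0.5  # ipsilateral masker is also strong


def test_simulate_dataset_shape_and_determinism():
    scenes = [scene_for(0), scene_for(0, 90)]
    d1 = simulate_dataset(n_units=2, seed=3, scenes=scenes, n_trials=4)
    d2 = simulate_dataset(n_units=2, seed=3, scenes=scenes, n_trials=4)
    # 2 units x 2 conditions x 2 scenes x 2 targets
    assert len(d1) == 16
    assert {s.condition for s in d1} == {"control", "laser"}
    for a, b in zip(d1, d2):
        assert all(np.array_equal(x.times, y.times) for x, y in zip(a.trials, b.trials))


# ---------------------------------------------------------------------------
# LFP generator
# ---------------------------------------------------------------------------

def test_lfp_linear_profile_has_zero_csd():
    lfp = generate_lfp(8, 100.0, profile=lambda z: 3.0 * z + 7.0, noise_sd=0.0, seed=0)
    csd = estimate_csd(lfp)
    assert np.allclose(csd.values, 0.0)


def test_lfp_quadratic_profile_closed_form_csd():
    lfp = generate_lfp(8, 100.0, profile=lambda z: z**2, noise_sd=0.0, seed=0)
    csd = estimate_csd(lfp)
    assert np.allclose(csd.values, -2.0)


def test_lfp_deterministic_and_needs_three_channels():
    l1 = generate_lfp(4, 100.0, profile=lambda z: z, noise_sd=1.0, seed=5)
    l2 = generate_lfp(4, 100.0, profile=lambda z: z, noise_sd=1.0, seed=5)
    assert np.array_equal(l1.data, l2.data)
    with pytest.raises(ValueError):
        generate_lfp(2, 100.0, profile=lambda z: z)


def test_lfp_time_varying_profile():
    lfp = generate_lfp(
        5, 100.0, profile=lambda z, t: np.sin(2 * np.pi * 5 * t) * z, seed=0
    )
    assert lfp.data.shape == (5, 1000)
    assert smooth_lfp(lfp).data.shape == (5, 1000)
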