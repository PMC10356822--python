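# Methods

`spikegrid` analyses single-unit spike trains recorded (or simulated) in a
spatial "cocktail party" paradigm: two amplitude-modulated target stimuli,
optionally accompanied by a competing noise masker, are presented from
speakers on the azimuthal plane (−90°, 0°, 45°, 90°; negative = ipsilateral
to the recorded hemisphere), 10 trials per target per configuration over a
3 s stimulus window, with and without optogenetic suppression of cortical
inhibition.  This note documents the models, the numerical choices, and what
the synthetic generator does and does not emulate.

## Spike-train distances

All time-resolved measures are defined through local quantities of each
train at time *t*: the preceding and following spikes `t_P`, `t_F`, the
offsets `x_P = t − t_P`, `x_F = t_F − t`, the current interspike interval
`x_ISI = t_F − t_P`, and the distances `Δt_P`, `Δt_F` from `t_P`/`t_F` to the
nearest spike of the other train.  The per-train timing term is

    S_n(t) = (Δt_P x_F + Δt_F x_P) / x_ISI ,

a linear interpolation between the nearest-spike offsets of the bracketing
spikes.  With `⟨x,y⟩ = (x+y)/2`:

- **ISI-distance** profile `I(t) = |x_ISI¹ − x_ISI²| / max(x_ISI¹, x_ISI²)` —
  instantaneous-rate dissimilarity only.
- **RI-SPIKE-distance** profile `(S₁ + S₂) / (2⟨x_ISI¹, x_ISI²⟩)` — relative
  spike timing only (the local rate weighting is skipped).
- **SPIKE-distance** profile `(S₁ x_ISI² + S₂ x_ISI¹) / (2⟨x_ISI¹, x_ISI²⟩²)`
  — timing weighted by local rate.

The scalar distance is the window-normalised integral `(1/T)∫₀ᵀ profile dt`.
Between consecutive spikes of the merged pair, every profile is linear
(constant for ISI) in *t*, so the integral is evaluated *exactly* from the
profile's corner values — no sampling error.  Independent dense numeric
integration exists only in the test suite, where the piecewise values are
required to agree with it to 1e-3 relative.

**Edge convention.** The local quantities are undefined before a train's
first and after its last spike.  Auxiliary spikes at *t* = 0 and *t* = T are
added to both trains (the convention of the metrics' originating toolbox);
an empty train reduces to the auxiliary pair alone.  Consequences worth
knowing: identical trains give exactly 0; equal-rate phase-shifted periodic
pairs give an ISI-distance that is only *asymptotically* zero (edge pieces
contribute O(period/T)); and profiles stay within [0, 1].  Pieces narrower
than 1 ps are dropped to keep the denominators away from underflow.

**van Rossum distance.** Each train is filtered with a causal unit-height
exponential kernel `e^{−t/τ}` and `D = sqrt((1/τ)∫₀^∞ (f₁−f₂)²)`.  The
integral is evaluated analytically over spike pairs via
`(1/τ)∫ kernel_i kernel_j = ½ e^{−|t_i−t_j|/τ}`, with the upper limit at
infinity, so the tail beyond the stimulus window is included exactly and the
single-spike identities (`sqrt(1 − e^{−Δ/τ})` for an offset pair, `sqrt(1/2)`
against silence) hold to machine precision.  τ sets the decoding timescale:
ms-scale τ reads a spike-timing code, hundreds of ms a rate code.

## Template-matching discrimination

For two 10-trial ensembles (one per target), every ordered template pair
(one trial from each target; 100 pairs) defines one iteration: both
templates are removed from the pool, each of the remaining 18 trials is
assigned to the target with the nearer template under the chosen metric,
and the iteration value is the fraction assigned correctly.  Performance is
the mean over iterations × 100%.  Equidistant templates credit 0.5 — the
deterministic, unbiased tie rule, which pins two limits used as acceptance
checks: statistically identical targets average 50% (chance) and identical
trains give exactly 50%, while deterministic distinct patterns give exactly
100%.  The template-pair enumeration is lexicographic, so results are
bit-reproducible; the full pairwise distance matrix is computed once and
indexed per iteration.

## Spatial grids, null distributions, hotspots

One grid per unit × condition holds performance per (target location,
masker location) cell.  The chance reference for a cell is built *within*
target: each target's 10 trials are split at random into two 5-trial
pseudo-classes which are template-matched against each other; iteration
values are pooled over both targets and (by default) 100 random splits.
Odd trial counts drop one random trial per split.  A cell is a **hotspot**
when performance ≥ 70%, Welch's t-test against the null gives P < 0.05, and
Cohen's d ≥ 1, computed with the standard additive pooled SD

    d = (x̄₁ − x̄₀) / sqrt(((n₁−1)s₁² + (n₀−1)s₀²)/(n₁+n₀−2)).

Cells where either target has ≥ 3 zero-spike trials are excluded outright.
Laser-only hotspots are flagged *emergent* and kept out of the main set.
Sub-threshold cells (chance < performance < 70%) can be banded by effect
size (0.2–0.5, 0.5–0.8, > 0.8) for secondary analyses.  Control-vs-laser
contrasts use paired t-tests with the paired effect size mean(diff)/SD(diff);
zero-variance differences are reported as degenerate rather than through the
t machinery.

## Response measures

All use left-closed right-open PSTH bins (final bin closed), 25 ms default.
*Evoked rate* is total spikes / (trials × window).  *Trial similarity* is
the mean Pearson correlation between the PSTHs of two random half-splits of
a target's trials (100 splits; splits with a zero-variance PSTH are excluded
from the mean rather than scored 0, avoiding bias toward zero for sparse
units).  The *rate-normalised RMS difference* compares the two targets'
unit-sum PSTHs, so it reflects temporal-pattern separation independent of
mean rate.  Each measure can be correlated (Pearson) with per-cell
performance.

## Decoding timescale

Performance is computed with the van Rossum metric on the coarse grid
τ ∈ {1, 2, 4, …, 256} ms, then a 1 ms-step fine search runs between the
coarse-grid neighbours of the coarse maximum (clipped to [1, 256] ms — the
cheapest faithful bracket, since the coarse profile is smooth in τ).  Ties
resolve to the smallest τ: claiming a fine timescale should require the
least smoothing.  A globally flat profile returns 1 ms with a `flat` flag.

## CSD and layer assignment

Laminar LFPs (8 channels per shank, 100 µm spacing, channel 0 most
superficial) are zero-phase low-passed at 150 Hz (forward–backward
filtering, so onset latencies are not delayed), decimated ×8,
trial-averaged, and dead channels are linearly interpolated from same-shank
neighbours (edge channels copy their nearest live neighbour).  Spatial
smoothing uses the (1, 2, 1)/4 kernel on interior channels; edges are
copied.  The CSD is the negated second spatial difference
`−(φ(z+Δz) − 2φ(z) + φ(z−Δz))/Δz²`, defined on interior channels; under
this convention a current sink is *negative*, and a channel's sink onset is
the first post-stimulus time its CSD drops below −3 SD of its pre-stimulus
CSD (channels with zero pre-stimulus SD are skipped).  The granular (L4)
channel is the earliest sink onset, ties broken by the candidate whose
neighbours have the earliest mean onset.  Layers follow anatomical offsets
from the granular channel: L4 = granular and 100 µm above; L2/3 = 200–400 µm
above; L1 ≥ 500 µm above; L5 = 100–300 µm below; L6 ≥ 400 µm below.  Band
cutoffs are placed midway between quoted offsets (e.g. ≥ 450 µm → L1), so
off-grid depths fall to the nearest defined band; on the native 100 µm grid
the quoted table is reproduced exactly.

## Synthetic data: what it emulates, and what it does not

The generator exists so every pipeline stage is testable without
recordings.  Target envelopes are band-limited (2–10 Hz, the modulation band
of natural speech envelopes) Gaussian noise, Hilbert-rectified and
peak-normalised — a surrogate with the right modulation statistics, not
speech.  `simulate_dataset` pairs two tokens with mean amplitudes matched
within 2%, emulating level-equalised stimuli.

A unit's response to one target at one configuration is a **frozen master
pattern** plus noise: the master's spike count is fixed at the expectation
of the envelope-driven rate `gain·(1 − masker_strength)·env(t − latency)`
and its spikes placed i.i.d. proportional to that rate; each trial then
deletes master spikes with probability 1 − reliability, jitters the
survivors (Gaussian, `jitter_sd`), superimposes an independent homogeneous
background at `baseline_rate + masker_baseline`, enforces the refractory
period by deletion, and clips to the window — in that fixed order, so runs
are reproducible.  Freezing the master gives the ensemble its
trial-to-trial reproducibility (the dial the analysis measures); fixing its
count removes a spurious across-target count cue that a raw Poisson draw
would freeze into every unit, keeping count-based discrimination at chance
as observed in the units this emulates.  The gain = 0 case degenerates to a
plain per-trial Poisson process, which is what the rate-calibration
contract checks.

Defaults (stipulated, not fitted — the source recordings are not public):
baseline 2 Hz, gain 25 Hz per unit envelope, onset latency 15 ms, jitter
3 ms, reliability 0.85, refractory 2 ms; heterogeneous units draw from
realistic ranges around these.  The masker degrades envelope locking by a
per-configuration strength (co-located and ipsilateral-masker
configurations strongest, falling with angular separation) and adds
unmodulated background — phenomenology chosen to reproduce the qualitative
spatial-grid structure, not a mechanistic acoustic model.  Suppression of
inhibition is modelled as baseline × 1.5 + 4 Hz, jitter × 3, onset 5 ms
earlier: elevated rate, earlier onset, reduced timing reproducibility.

Passing tests on these data therefore show that the *analysis* behaves
correctly and that the directional effects (masker degradation, suppression
deficits carried by timing rather than count) follow from the stated
response phenomenology.  They do not validate the generator against real
cortical dynamics: no adaptation, no correlated noise across trials or
units, no acoustic waveform synthesis, no biophysical circuit model.

## Problem sizes and tolerances

Piecewise integration is exact; the oracle comparison tolerance (1e-3
relative, 50 seeded pairs at 5 µs sampling) is set by the oracle's
discretisation, not the implementation.  van Rossum closed forms are
checked to 1e-9.  Simulation-based checks use 100–200 replicates (chance
limit 200 datasets; suppression directions 100 units; null calibration 200
fixtures), sizes at which the relevant standard errors are a fraction of
the asserted margins.  Grid/pipeline runs default to 100 null splits per
target; the bundled smoke runs use fewer, which only widens the null's
sampling error.
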