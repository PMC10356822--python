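# spikegrid

Spike-train discriminability analysis for spatial "cocktail party"
experiments in auditory cortex — and anywhere else two stimuli must be told
apart from single-trial spike timing.

A recorded unit answers 10 trials per target stimulus at each speaker
configuration (target location × masker location), with and without
optogenetic suppression of inhibition.  `spikegrid` turns those trial
ensembles into:

- **Spike-train distances** — ISI-distance, SPIKE-distance, rate-independent
  (RI-)SPIKE-distance, spike-count distance, and the van Rossum distance
  `D = sqrt((1/τ)∫(f₁−f₂)²)` with a causal exponential kernel.  The
  time-resolved profiles are piecewise linear between spikes and are
  integrated exactly (no discretisation).
- **Template-matching discriminability** — nearest-template classification
  over all 100 template pairs; 50% = chance, 100% = perfect separation.
- **Spatial grids and hotspots** — performance per configuration, tested
  against a within-target null; a hotspot needs performance ≥ 70%,
  P < 0.05, and Cohen's d ≥ 1.
- **Response measures** — evoked rate, split-half trial similarity, and the
  rate-normalised RMS difference between target PSTHs (25 ms bins).
- **Decoding timescale** — performance swept over τ = 1…256 ms with a 1 ms
  fine search for the optimum.
- **Laminar CSD** — current source density as the negated second spatial
  difference of the smoothed LFP, sink-onset detection at −3 SD, and layer
  labels (L1–L6) relative to the granular channel.
- **Synthetic data** — speech-envelope-driven model units with tunable
  reliability, jitter, masker degradation and a suppression condition, so
  the whole pipeline is testable without recordings.

## Worked example

Sweep the decoding timescale for one synthetic unit
(`examples/04_decoding_timescale.py`):

```sh
$ python examples/04_decoding_timescale.py
tau (ms)   performance (%)
      1     85.1
      2     96.4
      4     99.9
      8    100.0
     16    100.0
     32    100.0
     64    100.0
    128     99.8
    256     98.3

optimal tau: 5 ms (fine 1 ms search in [4, 16] ms; peak performance 100.0%)
```

Performance is % of trials assigned to the correct target; it peaks once the
kernel is wide enough to bridge the unit's spike-timing jitter and declines
as long kernels smooth away the envelope-following structure.  The other
examples cover the distance family (`01`), spatial grids with hotspot
statistics (`02`), the decomposition of a suppression deficit across metrics
(`03`), and CSD-based layer assignment (`05`).

A minimal API tour:

```python
import spikegrid as sg

dataset = sg.simulate_dataset(n_units=3, seed=0)          # trial ensembles
grid = sg.build_spatial_grid(dataset, "unit000", "control")
sg.annotate_grid(grid, dataset)                           # p, d, hotspot flags
print(grid.table)
```

There is also a thin CLI (`spikegrid simulate|discriminate|hotspots|
measures|decode-time|csd|run-all`) over the same functions, reading and
writing a flat CSV spike table (`# spikegrid table duration=3.0` header; one
row per spike, sentinel rows for empty trials).

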