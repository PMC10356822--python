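"""Decompose how suppressing inhibition degrades discrimination.

Simulates 25 units in control and suppressed ("laser") conditions at one
clean configuration and compares template-matching performance under each
distance metric, plus trial similarity.  Timing- and rate-modulation-based
codes degrade; total spike count carries no information in either condition.
"""

import numpy as np

from spikegrid import (
    SceneConfig,
    TrialSet,
    apply_suppression,
    generate_trial_set,
    paired_comparison,
    template_match,
    trial_similarity,
)
from spikegrid.synthetic import DEFAULT_SUPPRESSION, ResponseModel, matched_envelope_pair

CLEAN = SceneConfig(target_loc=45)
env1, env2 = matched_envelope_pair(seed=2)
rng = np.random.default_rng(1)

perf = {m: {"control": [], "laser": []} for m in ("spike", "isi", "ri_spike", "count")}
sim = {"control": [], "laser": []}
for _ in range(25):
    model = ResponseModel(
        baseline_rate=rng.uniform(1, 4), gain=rng.uniform(15, 35),
        jitter_sd=rng.uniform(0.002, 0.005), reliability=rng.uniform(0.7, 0.95),
    )
    for cond in ("control", "laser"):
        m = model if cond == "control" else apply_suppression(model, DEFAULT_SUPPRESSION)
        s1 = TrialSet("u", cond, 1, CLEAN, generate_trial_set(env1, m, CLEAN, 10, seed=int(rng.integers(2**31))))
        s2 = TrialSet("u", cond, 2, CLEAN, generate_trial_set(env2, m, CLEAN, 10, seed=int(rng.integers(2**31))))
        for metric in perf:
            perf[metric][cond].append(template_match(s1, s2, metric=metric).percent)
        sim[cond].append(0.5 * (trial_similarity(s1, seed=0) + trial_similarity(s2, seed=0)))

print(f"{'metric':<10} {'control':>8} {'laser':>8} {'paired p':>10} {'d':>6}")
for metric, vals in perf.items():
    res = paired_comparison(vals["control"], vals["laser"])
    print(f"{metric:<10} {np.mean(vals['control']):8.1f} {np.mean(vals['laser']):8.1f} "
          f"{res['p']:10.2e} {res['d']:6.2f}")
res = paired_comparison(sim["control"], sim["laser"])
print(f"{'trial sim':<10} {np.mean(sim['control']):8.2f} {np.mean(sim['laser']):8.2f} "
      f"{res['p']:10.2e} {res['d']:6.2f}")
print("\nPerformance is % correct (50 = chance); count-based performance stays "
      "near chance, so the suppression deficit is carried by timing and rate dynamics.")
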