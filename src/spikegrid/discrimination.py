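"""Template-matching classification of spike trains and spatial grids.

Neural discriminability between the two target stimuli is estimated by a
nearest-template classifier: in each iteration one trial per target serves
as that target's template, every remaining trial is assigned to the target
whose template lies nearer under the chosen spike-train metric, and the
iteration's value is the fraction of correctly assigned trials.  All n x n
ordered template pairs are enumerated (100 iterations for the nominal 10
trials per target) and performance is the mean over iterations, in percent:
~100% for perfectly separable targets, ~50% at chance.

Ties (both templates equidistant) credit 0.5 — deterministic and unbiased.
Template trials are excluded from the matched pool in their own iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import pairwise_distances
from .trains import SceneConfig, TrialSet

__all__ = [
    "PerformanceDistribution",
    "SpatialGrid",
    "template_match",
    "match_performance_from_matrix",
    "build_spatial_grid",
]

log = logging.getLogger(__name__)

GRID_COLUMNS = [
    "target_loc", "masker_loc", "performance", "d", "p", "hotspot", "excluded",
]


@dataclass(frozen=True)
class PerformanceDistribution:
    """Per-iteration correct-classification fractions of one template match."""

    iterations: np.ndarray  # values in [0, 1], one per template pair

    def __post_init__(self) -> None:
        v = np.asarray(self.iterations, dtype=float)
        object.__setattr__(self, "iterations", v)

    @property
    def percent(self) -> float:
        """Mean performance in percent on [0, 100]."""
        return float(np.mean(self.iterations) * 100.0)

    @property
    def mean(self) -> float:
        return float(np.mean(self.iterations))

    @property
    def std(self) -> float:
        return float(np.std(self.iterations, ddof=1))

    @property
    def n(self) -> int:
        return int(self.iterations.size)


def match_performance_from_matrix(
    D: np.ndarray, idx1: np.ndarray, idx2: np.ndarray
) -> np.ndarray:
    """Iteration values of the template-matching classifier, given a
    precomputed full distance matrix and the two classes' train indices.

    One iteration per ordered template pair (i from class 1, j from class 2),
    enumerated lexicographically so results are bit-reproducible.  Within an
    iteration both templates are excluded from the matched pool; each
    remaining train scores 1 if strictly nearer to its own template, 0.5 on a
    tie, 0 otherwise.
    """
    idx1 = np.asarray(idx1, dtype=int)
    idx2 = np.asarray(idx2, dtype=int)
    n1, n2 = idx1.size, idx2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 trials per class")
    n_matched = (n1 - 1) + (n2 - 1)
    vals = np.empty(n1 * n2)
    k = 0
    for a, i in enumerate(idx1):
        d1 = np.delete(D[idx1, i], a)  # class-1 trials (minus template) vs own template
        for b, j in enumerate(idx2):
            d2 = np.delete(D[idx1, j], a)
            c = np.sum(d1 < d2) + 0.5 * np.sum(d1 == d2)
            e1 = np.delete(D[idx2, i], b)
            e2 = np.delete(D[idx2, j], b)
            c += np.sum(e2 < e1) + 0.5 * np.sum(e2 == e1)
            vals[k] = c / n_matched
            k += 1
    return vals


def template_match(
    set1: TrialSet, set2: TrialSet, metric: str = "spike", tau: float | None = None
) -> PerformanceDistribution:
    """Discriminability of two targets by nearest-template classification.

    ``tau`` (s) applies to metric='van_rossum' only.  Distances are computed
    once over all trains of both sets and reused across iterations.
    """
    if set1.target_id == set2.target_id:
        raise ValueError("template matching needs two distinct targets")
    if len(set1) != len(set2):
        raise ValueError("trial counts must match between targets")
    if len(set1) < 2:
        raise ValueError("need at least 2 trials per target")
    if set1.duration != set2.duration:
        raise ValueError("trial sets must share one stimulus window")
    trains = list(set1.trials) + list(set2.trials)
    D = pairwise_distances(trains, metric=metric, tau=tau).values
    n = len(set1)
    vals = match_performance_from_matrix(D, np.arange(n), np.arange(n, 2 * n))
    return PerformanceDistribution(iterations=vals)


# ---------------------------------------------------------------------------
# spatial grids
# ---------------------------------------------------------------------------

@dataclass
class SpatialGrid:
    """Per-configuration discriminability of one unit in one condition.

    ``table`` has one row per (target_loc, masker_loc) configuration with
    columns performance (%), d, p, hotspot, excluded; the statistical columns
    are NaN until the grid is annotated against a null distribution
    (:func:`spikegrid.stats.annotate_grid`).
    """

    unit_id: str
    condition: str
    metric: str
    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=GRID_COLUMNS))
    distributions: dict = field(default_factory=dict)  # config key -> PerformanceDistribution

    def cell(self, target_loc: int, masker_loc) -> pd.Series:
        t = self.table
        m = (t.target_loc == target_loc) & (t.masker_loc == str(masker_loc))
        if not m.any():
            raise KeyError(f"no grid cell for target {target_loc}, masker {masker_loc}")
        return t[m].iloc[0]

    @property
    def clean(self) -> pd.DataFrame:
        return self.table[self.table.masker_loc == "none"]

    @property
    def masked(self) -> pd.DataFrame:
        return self.table[self.table.masker_loc != "none"]


def _config_key(scene: SceneConfig) -> tuple:
    return (scene.target_loc, str(scene.masker_loc))


def build_spatial_grid(
    dataset: list[TrialSet],
    unit_id: str,
    condition: str,
    metric: str = "spike",
    tau: float | None = None,
) -> SpatialGrid:
    """Assemble the per-configuration performance grid for one unit/condition.

    Configurations where either target has >= 3 zero-spike trials are flagged
    excluded and carry no performance; configurations missing one target are
    skipped with a warning.
    """
    from .stats import exclusion_filter  # late import: stats depends on us

    sets = [
        s for s in dataset if s.unit_id == unit_id and s.condition == condition
    ]
    by_config: dict[tuple, dict[int, TrialSet]] = {}
    for s in sets:
        by_config.setdefault(_config_key(s.scene), {})[s.target_id] = s

    rows = []
    dists: dict[tuple, PerformanceDistribution] = {}
    for key in sorted(by_config, key=lambda k: (k[0], k[1])):
        pair = by_config[key]
        if len(pair) < 2:
            log.warning("configuration %s missing one target; cell skipped", key)
            continue
        s1, s2 = pair[1], pair[2]
        excluded = exclusion_filter(s1, s2)
        row = {
            "target_loc": key[0],
            "masker_loc": key[1],
            "performance": np.nan,
            "d": np.nan,
            "p": np.nan,
            "hotspot": False,
            "excluded": excluded,
        }
        if not excluded:
            perf = template_match(s1, s2, metric=metric, tau=tau)
            dists[key] = perf
            row["performance"] = perf.percent
        rows.append(row)
    table = pd.DataFrame(rows, columns=GRID_COLUMNS)
    return SpatialGrid(
        unit_id=unit_id, condition=condition, metric=metric,
        table=table, distributions=dists,
    )
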