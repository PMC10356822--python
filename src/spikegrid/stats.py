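"""Null distributions, effect sizes, hotspot detection and paired comparisons.

A grid configuration is a *hotspot* when (1) mean template-matching
performance is at least 70%, (2) the performance distribution differs
significantly (P < 0.05) from a within-target null built by classifying
trials of the same target against each other (which should sit at chance),
and (3) Cohen's d between the performance and null distributions is at
least 1.  Configurations where either target has >= 3 zero-spike trials are
excluded from analysis outright.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .discrimination import (
    PerformanceDistribution,
    SpatialGrid,
    match_performance_from_matrix,
)
from .metrics import pairwise_distances
from .trains import TrialSet

__all__ = [
    "EffectSizeSample",
    "HotspotRecord",
    "PERFORMANCE_THRESHOLD",
    "P_THRESHOLD",
    "D_THRESHOLD",
    "cohens_d",
    "exclusion_filter",
    "null_performance_distribution",
    "detect_hotspots",
    "hotspot_flag",
    "annotate_grid",
    "group_low_performance",
    "paired_comparison",
]

log = logging.getLogger(__name__)

PERFORMANCE_THRESHOLD = 70.0  # %
P_THRESHOLD = 0.05
D_THRESHOLD = 1.0
EXCLUSION_EMPTY_TRIALS = 3


@dataclass(frozen=True)
class EffectSizeSample:
    """Summary statistics of a test and a reference (null) distribution."""

    mean1: float
    sd1: float
    n1: int
    mean0: float
    sd0: float
    n0: int

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n0 < 2:
            raise ValueError("need n >= 2 in both samples")
        if self.sd1 < 0 or self.sd0 < 0:
            raise ValueError("standard deviations must be non-negative")


def cohens_d(s: EffectSizeSample) -> float:
    """Cohen's d with pooled standard deviation.

    d = (mean1 - mean0) / sqrt(((n1-1) sd1^2 + (n0-1) sd0^2) / (n1+n0-2));
    positive when the test mean exceeds the reference mean.  Zero pooled
    variance yields signed infinity (0 for equal means) with a warning.
    """
    pooled_var = ((s.n1 - 1) * s.sd1**2 + (s.n0 - 1) * s.sd0**2) / (s.n1 + s.n0 - 2)
    if pooled_var == 0:
        log.warning("zero pooled variance in Cohen's d")
        diff = s.mean1 - s.mean0
        return 0.0 if diff == 0 else math.copysign(math.inf, diff)
    return (s.mean1 - s.mean0) / math.sqrt(pooled_var)


def cohens_d_from_samples(x1: np.ndarray, x0: np.ndarray) -> float:
    """Cohen's d computed from two raw samples."""
    x1 = np.asarray(x1, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    return cohens_d(
        EffectSizeSample(
            mean1=float(np.mean(x1)), sd1=float(np.std(x1, ddof=1)), n1=x1.size,
            mean0=float(np.mean(x0)), sd0=float(np.std(x0, ddof=1)), n0=x0.size,
        )
    )


def exclusion_filter(set1: TrialSet, set2: TrialSet) -> bool:
    """True when either target has >= 3 trials with zero spikes, i.e. the
    configuration is excluded to avoid unstable performance estimates."""
    return (
        set1.n_empty >= EXCLUSION_EMPTY_TRIALS
        or set2.n_empty >= EXCLUSION_EMPTY_TRIALS
    )


def null_performance_distribution(
    set1: TrialSet,
    set2: TrialSet,
    metric: str = "spike",
    tau: float | None = None,
    n_splits: int = 100,
    seed: int = 0,
) -> PerformanceDistribution:
    """Chance-level reference: classify trials *within* each target.

    For each of ``n_splits`` random splits, each target's trials are divided
    into two equal pseudo-classes which are template-matched against each
    other; iteration values are pooled across both targets and all splits.
    Odd trial counts drop one random trial per split (logged once).
    """
    rng = np.random.default_rng(seed)
    vals: list[np.ndarray] = []
    for ts in (set1, set2):
        n = len(ts)
        if n < 4:
            raise ValueError("null distribution needs >= 4 trials per target")
        half = n // 2
        if n % 2:
            log.info("odd trial count %d: one random trial dropped per split", n)
        D = pairwise_distances(ts.trials, metric=metric, tau=tau).values
        for _ in range(n_splits):
            perm = rng.permutation(n)
            vals.append(
                match_performance_from_matrix(D, perm[:half], perm[half : 2 * half])
            )
    return PerformanceDistribution(iterations=np.concatenate(vals))


# ---------------------------------------------------------------------------
# hotspot detection
# ---------------------------------------------------------------------------

@dataclass
class HotspotRecord:
    """Hotspot decision for one grid configuration."""

    config: tuple  # (target_loc, masker_loc)
    performance: float  # %
    p: float
    d: float
    excluded: bool
    hotspot: bool
    emergent: bool = False  # above threshold only under laser
    incomplete: bool = False  # null distribution unavailable


def hotspot_flag(performance: float, p: float, d: float, excluded: bool) -> bool:
    """The hotspot criterion as a pure function of its four inputs."""
    return (
        performance >= PERFORMANCE_THRESHOLD
        and p < P_THRESHOLD
        and d >= D_THRESHOLD
        and not excluded
    )


def compare_to_null(
    perf: PerformanceDistribution, null: PerformanceDistribution
) -> tuple[float, float]:
    """(p, d) of the performance distribution against its null.

    Welch's two-sample t-test on the iteration-level values; Cohen's d with
    pooled SD (positive = above chance).
    """
    import warnings

    with warnings.catch_warnings():
        # all-equal iteration values (e.g. perfect separability) trip scipy's
        # catastrophic-cancellation warning; the Welch p is still well defined
        warnings.simplefilter("ignore", RuntimeWarning)
        t = sps.ttest_ind(perf.iterations, null.iterations, equal_var=False)
    d = cohens_d_from_samples(perf.iterations, null.iterations)
    return float(t.pvalue), float(d)


def detect_hotspots(
    cells: list[dict],
) -> list[HotspotRecord]:
    """Apply the three hotspot criteria plus the exclusion rule.

    Each input dict needs keys ``config``, ``excluded`` and, unless excluded,
    ``performance`` (a :class:`PerformanceDistribution`) and ``null``
    (same, or None -> record flagged incomplete).
    """
    records = []
    for cell in cells:
        cfg = cell["config"]
        if cell.get("excluded", False):
            records.append(HotspotRecord(cfg, math.nan, math.nan, math.nan, True, False))
            continue
        perf: PerformanceDistribution = cell["performance"]
        null = cell.get("null")
        if null is None:
            records.append(
                HotspotRecord(cfg, perf.percent, math.nan, math.nan, False, False, incomplete=True)
            )
            continue
        p, d = compare_to_null(perf, null)
        records.append(
            HotspotRecord(cfg, perf.percent, p, d, False, hotspot_flag(perf.percent, p, d, False))
        )
    return records


def annotate_grid(
    grid: SpatialGrid,
    dataset: list[TrialSet],
    n_splits: int = 100,
    seed: int = 0,
) -> SpatialGrid:
    """Fill a spatial grid's p, d and hotspot columns against per-cell nulls."""
    by_config: dict[tuple, dict[int, TrialSet]] = {}
    for s in dataset:
        if s.unit_id == grid.unit_id and s.condition == grid.condition:
            by_config.setdefault((s.scene.target_loc, str(s.scene.masker_loc)), {})[s.target_id] = s
    for i, row in grid.table.iterrows():
        key = (row.target_loc, row.masker_loc)
        if row.excluded or key not in grid.distributions:
            continue
        pair = by_config[key]
        null = null_performance_distribution(
            pair[1], pair[2], metric=grid.metric, n_splits=n_splits, seed=seed
        )
        p, d = compare_to_null(grid.distributions[key], null)
        grid.table.loc[i, ["p", "d"]] = (p, d)
        grid.table.loc[i, "hotspot"] = hotspot_flag(row.performance, p, d, False)
    return grid


def flag_emergent(control: list[HotspotRecord], laser: list[HotspotRecord]) -> list[HotspotRecord]:
    """Mark laser-condition hotspots whose configuration is not a control
    hotspot as emergent (kept separate from the main hotspot set)."""
    control_hot = {r.config for r in control if r.hotspot}
    for r in laser:
        if r.hotspot and r.config not in control_hot:
            r.emergent = True
    return laser


def group_low_performance(records: list[HotspotRecord]) -> dict[int, list[HotspotRecord]]:
    """Partition sub-threshold configurations (chance < performance < 70%)
    into three effect-size bands: (1) 0.2 <= d < 0.5, (2) 0.5 <= d <= 0.8,
    (3) d > 0.8."""
    groups: dict[int, list[HotspotRecord]] = {1: [], 2: [], 3: []}
    for r in records:
        if r.excluded or not (50.0 < r.performance < PERFORMANCE_THRESHOLD):
            continue
        if 0.2 <= r.d < 0.5:
            groups[1].append(r)
        elif 0.5 <= r.d <= 0.8:
            groups[2].append(r)
        elif r.d > 0.8:
            groups[3].append(r)
    return groups


def paired_comparison(control_values, laser_values) -> dict:
    """Paired t-test of control vs laser values at matched configurations.

    Returns t, p and Cohen's d of the paired differences
    (mean(diff)/SD(diff), positive when control exceeds laser).  Zero
    difference variance is flagged degenerate: identical vectors give
    t=0, p=1, d=0; a constant non-zero shift gives infinite t and d.
    """
    x = np.asarray(control_values, dtype=float)
    y = np.asarray(laser_values, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length paired vectors with n >= 3")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0:
        m = diff.mean()
        if m == 0:
            return {"t": 0.0, "p": 1.0, "d": 0.0, "n": x.size, "degenerate": True}
        inf = math.copysign(math.inf, m)
        return {"t": inf, "p": 0.0, "d": inf, "n": x.size, "degenerate": True}
    res = sps.ttest_rel(x, y)
    return {
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "d": float(diff.mean() / sd),
        "n": int(x.size),
        "degenerate": False,
    }
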