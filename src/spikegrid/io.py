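"""Canonical tabular spike format and run configuration.

The spike table is a flat, diffable CSV: one row per spike, plus one
sentinel row (empty ``spike_time``) per zero-spike trial so that empty
trials survive a round trip.  The stimulus window length is declared once in
a ``# duration=...`` header line.

Columns: unit_id, condition, target_id, target_loc, masker_loc, trial,
spike_time.  ``masker_loc`` is ``none`` for clean trials; angles are degrees
azimuth, negative = ipsilateral to the recorded hemisphere.
"""

from __future__ import annotations

import io as _io
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .trains import DEFAULT_DURATION, SceneConfig, SpikeTrain, TrialSet

__all__ = ["RunConfig", "load_config", "write_spike_table", "read_spike_table"]

_COLUMNS = ["unit_id", "condition", "target_id", "target_loc", "masker_loc", "trial", "spike_time"]


@dataclass
class RunConfig:
    """Pipeline configuration with the analysis' standard thresholds."""

    metric: str = "spike"
    tau_ms: float | None = None          # van Rossum tau for metric='van_rossum'
    bin_ms: float = 25.0                 # PSTH resolution for response measures
    performance_threshold: float = 70.0  # % ; hotspot criterion 1
    p_threshold: float = 0.05            # hotspot criterion 2
    d_threshold: float = 1.0             # hotspot criterion 3
    n_null_splits: int = 100
    seed: int = 0
    laser_lead_ms: float = 50.0          # laser onset before sound onset (metadata)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """RunConfig from a YAML (or JSON — YAML superset) file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def write_spike_table(dataset: list[TrialSet], path: str | Path, seed: int | None = None) -> None:
    """Write trial sets as the canonical flat spike table."""
    rows = []
    duration = dataset[0].duration if dataset else DEFAULT_DURATION
    for ts in dataset:
        if ts.duration != duration:
            raise ValueError("all trial sets must share one stimulus window")
        for trial_i, train in enumerate(ts.trials, start=1):
            base = (
                ts.unit_id, ts.condition, ts.target_id,
                ts.scene.target_loc, str(ts.scene.masker_loc), trial_i,
            )
            if len(train) == 0:
                rows.append(base + (np.nan,))  # sentinel: trial exists, no spikes
            else:
                rows.extend(base + (t,) for t in train.times)
    df = pd.DataFrame(rows, columns=_COLUMNS)
    header = f"# spikegrid table duration={duration}"
    if seed is not None:
        header += f" seed={seed}"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def _parse_header(line: str) -> dict:
    meta = {}
    for token in line.lstrip("#").split():
        if "=" in token:
            k, v = token.split("=", 1)
            meta[k] = v
    return meta


def read_spike_table(path: str | Path) -> list[TrialSet]:
    """Read a spike table back into validated trial sets.

    Malformed rows (out-of-window spike times, bad condition labels) raise
    with 1-based file line numbers.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        rest = fh.read()
    if not first.startswith("#"):
        raise ValueError(f"{path}: missing '# spikegrid table ...' header line")
    meta = _parse_header(first)
    duration = float(meta.get("duration", DEFAULT_DURATION))
    df = pd.read_csv(_io.StringIO(rest), dtype={"masker_loc": str})
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    # data starts at file line 3 (header comment + csv header)
    lines = df.index + 3
    bad_cond = ~df.condition.isin(["control", "laser"])
    if bad_cond.any():
        raise ValueError(f"{path}: invalid condition at line {lines[bad_cond][0]}")
    spikes = df.spike_time
    bad_t = spikes.notna() & ((spikes < 0) | (spikes > duration))
    if bad_t.any():
        raise ValueError(
            f"{path}: spike_time outside [0, {duration}] at line {lines[bad_t][0]}"
        )

    out: list[TrialSet] = []
    group_cols = ["unit_id", "condition", "target_id", "target_loc", "masker_loc"]
    for key, g in df.groupby(group_cols, sort=True):
        unit_id, condition, target_id, target_loc, masker_loc = key
        scene = SceneConfig(
            target_loc=int(target_loc),
            masker_loc="none" if masker_loc == "none" else int(masker_loc),
        )
        trials = []
        for _, gt in g.groupby("trial", sort=True):
            times = gt.spike_time.dropna().to_numpy(dtype=float)
            trials.append(SpikeTrain(np.sort(times), duration))
        out.append(
            TrialSet(
                unit_id=str(unit_id),
                condition=str(condition),
                target_id=int(target_id),
                scene=scene,
                trials=trials,
            )
        )
    return out
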