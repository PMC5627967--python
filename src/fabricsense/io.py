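"""Reading and writing trial CSVs, dataset manifests and configs.

One trial is one CSV file: a ``time_s`` column (seconds, 6 decimals) plus
one column per sensor with accelerations in standard gravities; a dataset
directory holds the trial files and a ``manifest.json`` recording labels,
seeds and the apparatus configuration, so an analysis can be reproduced
from the files alone.  The dialect is pinned: comma separator, dot decimal,
regardless of locale.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .apparatus import (ApparatusConfig, FabricSpec, MotionSignal,
                        PendulumSpec, SensorSpec, Trial)
from .dynamics import Dataset

__all__ = [
    "write_trial_csv",
    "read_trial_csv",
    "write_dataset",
    "read_dataset",
    "config_to_dict",
    "config_from_dict",
    "load_config",
]


class ParseError(ValueError):
    """Malformed trial CSV or manifest."""


def write_trial_csv(trial: Trial, path: str | Path) -> Path:
    """Write one trial as ``time_s,<sensor>,...`` with one row per sample."""
    path = Path(path)
    ids = list(trial.signals)
    first = trial.signals[ids[0]]
    cols = {"time_s": np.round(first.times, 6)}
    for sid in ids:
        cols[sid] = trial.signals[sid].samples
    df = pd.DataFrame(cols)
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def read_trial_csv(path: str | Path, sample_rate: float | None = None
                   ) -> dict[str, MotionSignal]:
    """Read a trial CSV back into per-sensor signals.

    The sample rate is inferred from the time column unless given.  Raises
    :class:`ParseError` naming the offending line for malformed input.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=",")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.columns[0] != "time_s" or len(df.columns) < 2:
        raise ParseError(f"{path}: line 1: header must start with 'time_s' "
                         f"followed by sensor columns, got {list(df.columns)}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            for i, v in enumerate(df[col]):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise ParseError(f"{path}: line {i + 2}: non-numeric "
                                     f"value {v!r} in column {col!r}") from None
            raise ParseError(f"{path}: column {col!r} is not numeric")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ParseError(f"{path}: need at least two samples")
    if sample_rate is None:
        sample_rate = 1.0 / np.median(np.diff(t))
        sample_rate = float(round(sample_rate))
    return {c: MotionSignal(c, sample_rate, df[c].to_numpy())
            for c in df.columns[1:]}


# -- configs ----------------------------------------------------------------

def config_to_dict(config: ApparatusConfig) -> dict:
    return dataclasses.asdict(config)


def config_from_dict(d: Mapping) -> ApparatusConfig:
    pend = PendulumSpec(**d.get("pendulum", {}))
    fab = FabricSpec(**d.get("fabric", {}))
    sensors = tuple(SensorSpec(**s) for s in d.get("sensors", ()))
    extra = {k: d[k] for k in ("sample_rate", "duration") if k in d}
    return ApparatusConfig(pendulum=pend, fabric=fab, sensors=sensors, **extra)


def load_config(path: str | Path) -> ApparatusConfig:
    """Load an apparatus config from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ParseError(f"{path}: expected a mapping of config fields")
    return config_from_dict(data)


# -- datasets ---------------------------------------------------------------

def _trial_filename(trial: Trial, index: int) -> str:
    return f"{trial.label}_{index:02d}.csv"


def write_dataset(dataset: Dataset, directory: str | Path) -> Path:
    """Write all trials plus a JSON manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    counters: dict[str, int] = {}
    for trial in dataset.trials:
        idx = counters.get(trial.label, 0)
        counters[trial.label] = idx + 1
        fname = _trial_filename(trial, idx)
        write_trial_csv(trial, directory / fname)
        entries.append({"file": fname, "label": trial.label,
                        "seed": trial.seed,
                        "tip_load": trial.config.pendulum.tip_load})
    manifest = {
        "master_seed": dataset.master_seed,
        "config": config_to_dict(dataset.trials[0].config)
        if dataset.trials else None,
        "trials": entries,
    }
    mpath = directory / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def read_dataset(directory: str | Path) -> Dataset:
    """Rebuild a Dataset from a directory written by :func:`write_dataset`."""
    directory = Path(directory)
    mpath = directory / "manifest.json"
    if not mpath.exists():
        raise ParseError(f"no manifest.json in {directory}")
    manifest = json.loads(mpath.read_text())
    base = config_from_dict(manifest["config"])
    ds = Dataset(master_seed=manifest.get("master_seed"))
    for entry in manifest["trials"]:
        signals = read_trial_csv(directory / entry["file"],
                                 sample_rate=base.sample_rate)
        cfg = base.with_tip_load(entry.get("tip_load", 0.0))
        ds.trials.append(Trial(label=entry["label"], signals=signals,
                               config=cfg, seed=entry.get("seed", -1)))
    return ds
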