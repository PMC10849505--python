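"""File round-trips: event tables (CSV), activity (HDF5/CSV), configs (YAML)."""

from __future__ import annotations

import dataclasses
import json
from io import StringIO
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .schedule import EVENT_COLUMNS, ProtocolConfig
from .simulate import ActivityMatrix, GeneratorConfig


def write_events(events: pd.DataFrame, path) -> None:
    events[EVENT_COLUMNS].to_csv(path, index=False)


def add_presentation_index(events: pd.DataFrame) -> pd.DataFrame:
    """Recompute the global presentation counter on element/gray rows."""
    ev = events.copy()
    stim = ev["kind"].isin(["element", "gray"])
    keys = ev.loc[stim].groupby(["sequence", "trial"])["onset_ms"].transform("min")
    order = {k: i for i, k in enumerate(sorted(keys.unique()))}
    ev["presentation"] = -1
    ev.loc[stim, "presentation"] = keys.map(order).astype(int)
    return ev


def read_events(path) -> pd.DataFrame:
    ev = pd.read_csv(path, keep_default_na=False,
                     dtype={"sequence": str, "element": str, "kind": str})
    return add_presentation_index(ev)


def write_activity(activity: ActivityMatrix, path) -> None:
    """ActivityMatrix to HDF5 (datasets: activity, frame_rate, cell_meta,
    ground_truth)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("activity", data=activity.values, compression="gzip")
        f.attrs["frame_rate"] = activity.frame_rate
        f.attrs["day"] = activity.day
        f.create_dataset("cell_meta",
                         data=activity.cell_meta.to_json().encode())
        if activity.ground_truth is not None:
            f.create_dataset("ground_truth",
                             data=activity.ground_truth.to_json().encode())


def read_activity(path) -> ActivityMatrix:
    with h5py.File(path, "r") as f:
        values = f["activity"][...]
        meta = pd.read_json(StringIO(f["cell_meta"][()].decode()))
        gt = (pd.read_json(StringIO(f["ground_truth"][()].decode()))
              if "ground_truth" in f else None)
        return ActivityMatrix(values=values,
                              frame_rate=float(f.attrs["frame_rate"]),
                              cell_meta=meta, day=str(f.attrs.get("day", "")),
                              ground_truth=gt)


def write_activity_csv(activity: ActivityMatrix, path) -> None:
    """Plain-text fallback: one row per cell, columns are frames."""
    pd.DataFrame(activity.values).to_csv(path, index=False)


def write_response_matrix_csv(resp, path) -> None:
    lab = resp.labels[["sequence", "element", "position", "block", "trial"]]
    df = pd.concat([lab.reset_index(drop=True),
                    pd.DataFrame(resp.values,
                                 columns=[f"cell{i}" for i in
                                          range(resp.values.shape[1])])], axis=1)
    df.to_csv(path, index=False)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def save_config(config, path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(config)))


def load_protocol_config(path) -> ProtocolConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    if "sequences" in data:
        data["sequences"] = tuple(data["sequences"])
    return ProtocolConfig(**data)


def load_generator_config(path) -> GeneratorConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return GeneratorConfig(**data)


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_to_plain(obj), indent=2, default=str))
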