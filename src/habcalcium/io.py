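"""Delimited-text readers and writers for the pipeline's domain objects.

Traces are CSV tables with rows = neurons (first column ``neuron_id``,
remaining columns frames), with a JSON sidecar (``<stem>.meta.json``)
recording the frame rate, generating config and seed. Geometry, events and
ground-truth tables are plain CSV. Behavior tracks are CSV with a ``#``
metadata header (arena size, view, track id). All writers embed enough
metadata to reconstruct the objects exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import BehaviorTrack, NeuronGeometry, SchemaError, StimulusProtocol, TraceMatrix

__all__ = [
    "write_traces", "read_traces",
    "write_geometry", "read_geometry",
    "write_events", "read_events",
    "write_track", "read_track",
    "check_ids",
]


def _meta_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_traces(path, traces: TraceMatrix, config=None, seed=None) -> None:
    path = Path(path)
    df = pd.DataFrame(traces.data)
    df.insert(0, "neuron_id", traces.neuron_ids)
    df.to_csv(path, index=False)
    meta = {"frame_rate": traces.frame_rate, "config": _jsonable(config), "seed": seed}
    _meta_path(path).write_text(json.dumps(meta, indent=1))


def read_traces(path) -> TraceMatrix:
    path = Path(path)
    meta = json.loads(_meta_path(path).read_text())
    df = pd.read_csv(path)
    if "neuron_id" not in df.columns:
        raise SchemaError(f"{path.name}: missing 'neuron_id' column")
    return TraceMatrix(
        df.drop(columns="neuron_id").to_numpy(dtype=float),
        frame_rate=float(meta["frame_rate"]),
        neuron_ids=df["neuron_id"].to_numpy(),
    )


def write_geometry(path, geometry: NeuronGeometry) -> None:
    geometry.table.to_csv(Path(path), index=False)


def read_geometry(path) -> NeuronGeometry:
    return NeuronGeometry(pd.read_csv(Path(path)))


def write_events(path, protocol: StimulusProtocol) -> None:
    protocol.events.to_csv(Path(path), index=False)


def read_events(path) -> StimulusProtocol:
    df = pd.read_csv(Path(path))
    for i, onsets in enumerate(np.diff(df["onset_s"].to_numpy(dtype=float))):
        if onsets <= 0:
            raise SchemaError(f"{Path(path).name}: non-increasing onset at row {i + 1}")
    return StimulusProtocol(df)


def write_track(path, track: BehaviorTrack) -> None:
    path = Path(path)
    header = (
        f"# arena_w_mm={track.arena_w_mm}\n"
        f"# arena_h_mm={track.arena_h_mm}\n"
        f"# view={track.view}\n"
        f"# track_id={track.track_id}\n"
    )
    body = pd.DataFrame({"t_s": track.t_s, "x_mm": track.x_mm, "y_mm": track.y_mm})
    path.write_text(header + body.to_csv(index=False))
    ev_path = path.with_suffix(".events.csv")
    track.events.to_csv(ev_path, index=False)


def read_track(path) -> BehaviorTrack:
    path = Path(path)
    meta = {}
    with path.open() as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        if not line.startswith("#"):
            break
        key, _, val = line[1:].strip().partition("=")
        meta[key.strip()] = val.strip()
        n_header += 1
    required = {"arena_w_mm", "arena_h_mm", "view"}
    if not required <= set(meta):
        raise SchemaError(f"{path.name}: metadata header missing {sorted(required - set(meta))}")
    df = pd.read_csv(path, skiprows=n_header)
    if not {"t_s", "x_mm", "y_mm"} <= set(df.columns):
        raise SchemaError(f"{path.name}: needs columns t_s, x_mm, y_mm")
    ev_path = path.with_suffix(".events.csv")
    events = pd.read_csv(ev_path) if ev_path.exists() else None
    return BehaviorTrack(
        t_s=df["t_s"].to_numpy(dtype=float),
        x_mm=df["x_mm"].to_numpy(dtype=float),
        y_mm=df["y_mm"].to_numpy(dtype=float),
        arena_w_mm=float(meta["arena_w_mm"]),
        arena_h_mm=float(meta["arena_h_mm"]),
        view=meta["view"],
        events=events,
        track_id=int(meta.get("track_id", 0)),
    )


def check_ids(traces: TraceMatrix, geometry: NeuronGeometry) -> None:
    """Cross-check that the geometry covers exactly the traced neurons."""
    t_ids = set(np.asarray(traces.neuron_ids).tolist())
    g_ids = set(geometry.neuron_ids.tolist())
    if t_ids != g_ids:
        missing = sorted(t_ids - g_ids)[:5]
        extra = sorted(g_ids - t_ids)[:5]
        raise SchemaError(
            f"trace/geometry neuron_id mismatch (missing from geometry: {missing}, "
            f"extra in geometry: {extra})"
        )
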