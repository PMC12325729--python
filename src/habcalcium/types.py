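"""Core domain containers shared across the pipeline.

Conventions
-----------
* Traces are stored as ``(n_neurons, n_frames)`` float arrays; time is the
  second axis and the public time unit is seconds.
* Neuron coordinates are micrometres: x runs anterior->posterior, y is
  mediolateral with the midline near the population mean, and z is
  dorsoventral depth increasing ventrally with 0 at the dorsal-most neuron.
* Behavioral positions are millimetres; in side view ``y`` is measured
  upward from the arena floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "ProtocolError",
    "SchemaError",
    "GeometryError",
    "TraceMatrix",
    "DffMatrix",
    "StimulusProtocol",
    "NeuronGeometry",
    "BehaviorTrack",
]


class ConfigError(ValueError):
    """Invalid analysis or simulation configuration."""


class ProtocolError(ValueError):
    """Stimulus/drug event table inconsistent with the recording."""


class SchemaError(ValueError):
    """Input table violates the documented schema (columns, IDs, ordering)."""


class GeometryError(ValueError):
    """ROI masks or coordinates are geometrically invalid."""


def _as_2d_float(data) -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise SchemaError(f"expected a 2-D neurons x frames matrix, got shape {arr.shape}")
    return arr


@dataclass
class TraceMatrix:
    """Raw ROI fluorescence, neurons x frames, in arbitrary units."""

    data: np.ndarray
    frame_rate: float
    neuron_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = _as_2d_float(self.data)
        if not np.all(np.isfinite(self.data)):
            raise SchemaError("fluorescence matrix contains non-finite values")
        if self.data.shape[1] < 2:
            raise SchemaError("a trace needs at least 2 frames")
        if not self.frame_rate > 0:
            raise ConfigError(f"frame rate must be > 0, got {self.frame_rate}")
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.data.shape[0])
        else:
            self.neuron_ids = np.asarray(self.neuron_ids)
            if self.neuron_ids.shape != (self.data.shape[0],):
                raise SchemaError("neuron_ids length must match the number of rows")
            if len(np.unique(self.neuron_ids)) != len(self.neuron_ids):
                raise SchemaError("neuron_ids must be unique")

    @property
    def n_neurons(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def frame_times(self) -> np.ndarray:
        """Frame-start times in seconds (0-based frame indexing)."""
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class DffMatrix:
    """dF/F in percent, same shape as its source TraceMatrix.

    ``mode`` records how the baseline F0 was estimated: ``"trial_prestim"``
    (per-event 5 s pre-onset mean; frames outside trial segments are NaN) or
    ``"moving_window"`` (centered 6 min sliding mean, truncated at the edges).
    ``valid`` flags neurons whose baseline stayed positive everywhere it was
    used; invalid neurons carry NaN rows and are excluded downstream.
    """

    data: np.ndarray
    frame_rate: float
    mode: str
    neuron_ids: np.ndarray | None = None
    params: dict = field(default_factory=dict)
    valid: np.ndarray | None = None
    smoothing: dict | None = None

    def __post_init__(self) -> None:
        self.data = _as_2d_float(self.data)
        if self.mode not in ("trial_prestim", "moving_window"):
            raise ConfigError(f"unknown dF/F mode {self.mode!r}")
        if not self.frame_rate > 0:
            raise ConfigError("frame rate must be > 0")
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.data.shape[0])
        else:
            self.neuron_ids = np.asarray(self.neuron_ids)
        if self.valid is None:
            self.valid = np.ones(self.data.shape[0], dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def n_neurons(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def with_data(self, data: np.ndarray, **meta) -> "DffMatrix":
        out = replace(self, data=data)
        for k, v in meta.items():
            setattr(out, k, v)
        return out


MODALITIES = ("light", "vibration", "both", "odor", "microstim", "drug_on", "drug_off")


@dataclass
class StimulusProtocol:
    """Ordered stimulus/drug/micro-stimulation events.

    ``events`` has columns ``onset_s``, ``duration_s``, ``modality``.
    Onsets are strictly increasing and every event must fit inside the
    recording it is applied to (checked against a duration on demand).
    """

    events: pd.DataFrame

    def __post_init__(self) -> None:
        ev = pd.DataFrame(self.events)
        required = {"onset_s", "duration_s", "modality"}
        missing = required - set(ev.columns)
        if missing:
            raise SchemaError(f"event table missing columns {sorted(missing)}")
        onsets = ev["onset_s"].to_numpy(dtype=float)
        if np.any(np.diff(onsets) <= 0):
            bad = int(np.argmax(np.diff(onsets) <= 0)) + 1
            raise SchemaError(f"event onsets must be strictly increasing (row {bad})")
        if np.any(ev["duration_s"].to_numpy(dtype=float) < 0):
            raise SchemaError("event durations must be >= 0")
        unknown = set(ev["modality"]) - set(MODALITIES)
        if unknown:
            raise SchemaError(f"unknown modalities {sorted(unknown)}")
        self.events = ev.reset_index(drop=True)

    def of(self, modality: str) -> pd.DataFrame:
        return self.events[self.events["modality"] == modality].reset_index(drop=True)

    def onsets(self, modality: str) -> np.ndarray:
        return self.of(modality)["onset_s"].to_numpy(dtype=float)

    def check_within(self, duration_s: float) -> None:
        ends = self.events["onset_s"] + self.events["duration_s"]
        if (self.events["onset_s"] < 0).any() or (ends > duration_s).any():
            raise ProtocolError(
                f"events extend outside the {duration_s:.1f} s recording"
            )

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class NeuronGeometry:
    """3-D neuron positions in micrometres with optional ensemble labels."""

    table: pd.DataFrame  # neuron_id, x_um, y_um, z_um [, ensemble]

    def __post_init__(self) -> None:
        t = pd.DataFrame(self.table)
        required = {"neuron_id", "x_um", "y_um", "z_um"}
        missing = required - set(t.columns)
        if missing:
            raise SchemaError(f"geometry table missing columns {sorted(missing)}")
        if t["neuron_id"].duplicated().any():
            raise SchemaError("neuron_ids must be unique")
        coords = t[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            raise SchemaError("coordinates must be finite")
        self.table = t.reset_index(drop=True)

    @property
    def neuron_ids(self) -> np.ndarray:
        return self.table["neuron_id"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) array of x, y, z in micrometres."""
        return self.table[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)

    @property
    def n_neurons(self) -> int:
        return len(self.table)

    @property
    def ensemble(self) -> np.ndarray | None:
        if "ensemble" in self.table.columns:
            return self.table["ensemble"].to_numpy()
        return None

    def depth_um(self) -> np.ndarray:
        """Dorsoventral depth from the dorsal-most neuron (>= 0)."""
        z = self.table["z_um"].to_numpy(dtype=float)
        return z - z.min()

    def pairwise_distances(self) -> np.ndarray:
        from scipy.spatial.distance import squareform, pdist

        return squareform(pdist(self.positions))


@dataclass
class BehaviorTrack:
    """Timestamped 2-D positions in a calibrated arena.

    In side view ``y_mm`` is height above the arena floor. Events carry a
    time and a kind (``vibration``, ``dark_on``, ``light_on``, ``tank_entry``).
    """

    t_s: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    arena_w_mm: float
    arena_h_mm: float
    view: str = "side"
    events: pd.DataFrame | None = None
    track_id: int = 0

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        if not (len(self.t_s) == len(self.x_mm) == len(self.y_mm)):
            raise SchemaError("t, x, y must have equal length")
        if np.any(np.diff(self.t_s) <= 0):
            raise SchemaError("timestamps must be strictly increasing")
        if self.view not in ("side", "top"):
            raise ConfigError(f"view must be 'side' or 'top', got {self.view!r}")
        eps = 1e-9
        if (
            self.x_mm.min() < -eps
            or self.x_mm.max() > self.arena_w_mm + eps
            or self.y_mm.min() < -eps
            or self.y_mm.max() > self.arena_h_mm + eps
        ):
            raise SchemaError("positions fall outside the arena bounds")
        if self.events is None:
            self.events = pd.DataFrame(columns=["time_s", "kind"])
        else:
            ev = pd.DataFrame(self.events)
            if not {"time_s", "kind"} <= set(ev.columns):
                raise SchemaError("behavior events need 'time_s' and 'kind' columns")
            self.events = ev.reset_index(drop=True)

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0])

    def event_times(self, kind: str) -> np.ndarray:
        ev = self.events
        return ev.loc[ev["kind"] == kind, "time_s"].to_numpy(dtype=float)

    def window_mask(self, t0: float, t1: float) -> np.ndarray:
        return (self.t_s >= t0) & (self.t_s < t1)
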