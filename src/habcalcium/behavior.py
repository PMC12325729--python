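"""Quantification of tracked swimming behavior.

Positions are millimetres; in side view the y coordinate is height above
the arena floor, so "distance from bottom" is y itself and its normalised
variant is y divided by the arena height. Speed is the summed x-y path
length in 1 s bins. Stimulus-locked depth change and light/dark speed
change are expressed as post/baseline fractions, so diving and slowing give
values below 1.
"""

from __future__ import annotations

import warnings

import numpy as np

from .stats import TestResult, rank_test
from .types import BehaviorTrack, ConfigError, ProtocolError

__all__ = [
    "position_pdf",
    "group_average_pdf",
    "distance_from_bottom",
    "depth_change_fraction",
    "speed_series",
    "distance_change_fraction",
    "sustained_metric",
    "compare_sustained",
]


def position_pdf(track: BehaviorTrack, grid_shape: tuple = (20, 20),
                 window_s: tuple = (0.0, 120.0)) -> np.ndarray:
    """2-D occupancy density over the window, normalised to sum to 1."""
    t0, t1 = window_s
    mask = track.window_mask(t0, t1)
    if mask.sum() == 0:
        raise ProtocolError(f"window {window_s} contains no samples")
    h, _, _ = np.histogram2d(
        track.x_mm[mask], track.y_mm[mask], bins=grid_shape,
        range=[[0, track.arena_w_mm], [0, track.arena_h_mm]],
    )
    return h / h.sum()


def group_average_pdf(pdfs: list[np.ndarray]) -> np.ndarray:
    """Group-average occupancy density (mean of per-fish PDFs; sums to 1)."""
    return np.mean(np.stack(pdfs), axis=0)


def distance_from_bottom(track: BehaviorTrack, window_s: tuple | None = None,
                         normalized: bool = False):
    """Height above the arena floor (side view only).

    Returns (times, series, window mean). ``normalized`` divides by the
    arena height, mapping the floor to 0 and the surface to 1.
    """
    if track.view != "side":
        raise ConfigError("distance from bottom requires a side-view track")
    series = track.y_mm / track.arena_h_mm if normalized else track.y_mm
    if window_s is None:
        mask = np.ones_like(series, dtype=bool)
    else:
        mask = track.window_mask(*window_s)
        if mask.sum() == 0:
            raise ProtocolError(f"window {window_s} contains no samples")
    return track.t_s, series, float(series[mask].mean())


def depth_change_fraction(
    track: BehaviorTrack,
    pre_s: float = 2.0,
    post_window_s: tuple = (0.0, 30.0),
    event_kind: str = "vibration",
    direction: str = "post_over_pre",
) -> dict:
    """Stimulus-locked change in height above the floor.

    For each event the mean height over ``post_window_s`` (relative to the
    event) is divided by the mean over the ``pre_s`` seconds before it
    (``direction='post_over_pre'``, the default, so diving gives values
    below 1; ``'pre_over_post'`` flips the ratio). Events whose pre-window
    mean is 0 are skipped and logged. Returns per-event fractions and their
    mean.
    """
    if direction not in ("post_over_pre", "pre_over_post"):
        raise ConfigError("direction must be 'post_over_pre' or 'pre_over_post'")
    if track.view != "side":
        raise ConfigError("depth change requires a side-view track")
    events = track.event_times(event_kind)
    if events.size == 0:
        raise ProtocolError(f"no {event_kind!r} events in the track")
    if events.max() + post_window_s[1] > track.t_s[-1] + 1e-9:
        raise ProtocolError("an event's post window extends beyond the recording")
    fractions = []
    for ev in events:
        pre = track.window_mask(ev - pre_s, ev)
        post = track.window_mask(ev + post_window_s[0], ev + post_window_s[1])
        pre_mean = track.y_mm[pre].mean()
        post_mean = track.y_mm[post].mean()
        if pre_mean == 0:
            warnings.warn(f"event at {ev:.1f} s: pre-window mean depth is 0; skipped",
                          stacklevel=2)
            continue
        frac = post_mean / pre_mean if direction == "post_over_pre" else pre_mean / post_mean
        fractions.append(frac)
    fractions = np.asarray(fractions)
    return {
        "per_event": fractions,
        "mean": float(fractions.mean()) if fractions.size else float("nan"),
        "n_events": int(fractions.size),
    }


def speed_series(track: BehaviorTrack, bin_s: float = 1.0):
    """Swimming distance in x-y per time bin.

    Each step's Euclidean length is assigned to the bin containing the
    step's start sample. Returns (bin start times, distances).
    """
    if bin_s <= 0:
        raise ConfigError("bin width must be > 0")
    steps = np.hypot(np.diff(track.x_mm), np.diff(track.y_mm))
    t0 = track.t_s[0]
    idx = np.floor((track.t_s[:-1] - t0) / bin_s).astype(int)
    nb = int(np.floor((track.t_s[-1] - t0) / bin_s)) + 1
    dist = np.bincount(idx, weights=steps, minlength=nb)
    return t0 + np.arange(nb) * bin_s, dist


def distance_change_fraction(
    bin_times: np.ndarray,
    distances: np.ndarray,
    transition_time_s: float,
    baseline_s: float = 5.0,
):
    """Swimming distance per bin normalised to the pre-transition baseline.

    The baseline is the mean bin distance over the ``baseline_s`` seconds
    before the transition; every post-transition bin is divided by it.
    Returns (times relative to the transition, fractions).
    """
    bin_times = np.asarray(bin_times, dtype=float)
    distances = np.asarray(distances, dtype=float)
    base = (bin_times >= transition_time_s - baseline_s) & (bin_times < transition_time_s)
    if base.sum() == 0:
        raise ConfigError("no baseline bins before the transition")
    baseline = distances[base].mean()
    post = bin_times >= transition_time_s
    if baseline == 0:
        warnings.warn("zero swimming distance in the baseline; fractions undefined",
                      stacklevel=2)
        return bin_times[post] - transition_time_s, np.full(post.sum(), np.nan)
    return bin_times[post] - transition_time_s, distances[post] / baseline


def sustained_metric(times: np.ndarray, series: np.ndarray, window_s: tuple) -> float:
    """Mean of a metric time series over the assay's sustained window."""
    times = np.asarray(times, dtype=float)
    series = np.asarray(series, dtype=float)
    mask = (times >= window_s[0]) & (times < window_s[1])
    if mask.sum() == 0:
        raise ProtocolError(f"sustained window {window_s} outside the series")
    return float(np.nanmean(series[mask]))


def compare_sustained(group_a, group_b, sided: str = "two_sided") -> TestResult:
    """Rank-sum comparison of per-fish sustained-window means between groups."""
    return rank_test(np.asarray(group_a, float), np.asarray(group_b, float),
                     paired=False, sided=sided)
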