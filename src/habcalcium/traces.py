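"""Raw fluorescence -> dF/F, smoothing, and trial-locked response averages.

Two baseline modes are supported, matching the two recording regimes:

* ``trial_prestim`` — for stimulation recordings, each trial is normalised
  to the mean fluorescence of the 5 s immediately preceding stimulus onset;
* ``moving_window`` — for spontaneous/drug recordings, the baseline is a
  6 min sliding mean around each frame (truncated at the recording edges).

dF/F is reported in percent. Frames are 0-based and assigned to windows by
their start time; the response window is half-open, (onset, onset + 10 s].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .types import (
    ConfigError,
    DffMatrix,
    GeometryError,
    ProtocolError,
    SchemaError,
    StimulusProtocol,
    TraceMatrix,
)

__all__ = ["extract_roi_traces", "dff", "smooth", "trial_average", "TrialAverage"]

STIM_MODALITIES = ("light", "vibration", "both", "odor", "microstim")


def extract_roi_traces(movie: np.ndarray, labels: np.ndarray, frame_rate: float,
                       neuron_ids=None) -> TraceMatrix:
    """Average the pixels of each labelled ROI per frame.

    ``labels`` is an integer image (0 = background, k = neuron k-1 in row
    order unless ``neuron_ids`` maps labels explicitly).
    """
    movie = np.asarray(movie, dtype=float)
    labels = np.asarray(labels)
    if movie.ndim != 3 or labels.shape != movie.shape[1:]:
        raise SchemaError("movie must be (frames, H, W) with a matching label image")
    present = np.unique(labels)
    present = present[present > 0]
    if present.size == 0:
        raise GeometryError("label image contains no ROIs")
    n = int(present.max())
    if not np.array_equal(present, np.arange(1, n + 1)):
        missing = sorted(set(range(1, n + 1)) - set(present.tolist()))
        raise GeometryError(f"empty mask for label(s) {missing}")
    if neuron_ids is not None and len(neuron_ids) != n:
        raise SchemaError("neuron_ids length does not match the number of ROI labels")
    flat = labels.ravel()
    counts = np.bincount(flat, minlength=n + 1)[1:]
    sums = np.vstack([
        np.bincount(flat, weights=frame.ravel(), minlength=n + 1)[1:]
        for frame in movie
    ])
    return TraceMatrix((sums / counts).T, frame_rate, neuron_ids)


def _moving_baseline(data: np.ndarray, frame_rate: float, window_min: float) -> np.ndarray:
    win = int(round(window_min * 60.0 * frame_rate))
    if win < 1:
        raise ConfigError("moving window shorter than one frame")
    if win > data.shape[1]:
        raise ConfigError(
            f"recording ({data.shape[1]} frames) shorter than the {window_min} min window"
        )
    df = pd.DataFrame(data.T)
    return df.rolling(win, center=True, min_periods=1).mean().to_numpy().T


def dff(
    traces: TraceMatrix,
    mode: str,
    protocol: StimulusProtocol | None = None,
    baseline_s: float = 5.0,
    window_min: float = 6.0,
    trial_post_s: float = 30.0,
) -> DffMatrix:
    """Fractional fluorescence change relative to baseline, in percent.

    Trial mode fills only the trial segments [-baseline_s, +trial_post_s]
    around each stimulus onset (other frames are NaN); moving mode covers
    the full recording. Neurons whose baseline is <= 0 anywhere it is used
    are flagged invalid (NaN rows) and counted in ``params['n_invalid']``.
    """
    data = traces.data
    times = traces.frame_times()
    valid = np.ones(traces.n_neurons, dtype=bool)

    if mode == "moving_window":
        f0 = _moving_baseline(data, traces.frame_rate, window_min)
        bad = (f0 <= 0).any(axis=1)
        out = np.full_like(data, np.nan)
        ok = ~bad
        out[ok] = 100.0 * (data[ok] - f0[ok]) / f0[ok]
        valid = ok
        params = {"window_min": window_min, "n_invalid": int(bad.sum())}
    elif mode == "trial_prestim":
        if protocol is None:
            raise ConfigError("trial mode requires a StimulusProtocol")
        out = np.full_like(data, np.nan)
        n_dropped = 0
        stim = protocol.events[protocol.events["modality"].isin(STIM_MODALITIES)]
        if stim.empty:
            raise ProtocolError("protocol contains no stimulus events")
        for onset in stim["onset_s"].to_numpy(dtype=float):
            base_mask = (times >= onset - baseline_s) & (times < onset)
            seg_mask = (times >= onset - baseline_s) & (times <= onset + trial_post_s)
            if onset - baseline_s < -1e-9 or base_mask.sum() == 0:
                n_dropped += 1
                warnings.warn(
                    f"trial at {onset:.1f} s too close to recording start; dropped",
                    stacklevel=2,
                )
                continue
            f0 = data[:, base_mask].mean(axis=1)
            bad = f0 <= 0
            valid &= ~bad
            with np.errstate(divide="ignore", invalid="ignore"):
                seg = 100.0 * (data[:, seg_mask] - f0[:, None]) / f0[:, None]
            seg[bad] = np.nan
            out[:, seg_mask] = seg
        out[~valid] = np.nan
        params = {
            "baseline_s": baseline_s,
            "trial_post_s": trial_post_s,
            "n_dropped_trials": n_dropped,
            "n_invalid": int((~valid).sum()),
        }
    else:
        raise ConfigError(f"unknown dF/F mode {mode!r}")

    return DffMatrix(
        out, traces.frame_rate, mode="moving_window" if mode == "moving_window" else "trial_prestim",
        neuron_ids=traces.neuron_ids, params=params, valid=valid,
    )


def smooth(dff_mat: DffMatrix, kernel_sd_s: float) -> DffMatrix:
    """Per-neuron Gaussian smoothing (unit-sum kernel, reflective edges).

    NaN segments are handled by normalised convolution so trial-mode
    matrices smooth within, not across, their defined segments.
    """
    if kernel_sd_s < 0:
        raise ConfigError("kernel SD must be >= 0")
    if kernel_sd_s == 0:
        return dff_mat.with_data(dff_mat.data.copy(), smoothing={"kernel_sd_s": 0.0})
    sd = kernel_sd_s * dff_mat.frame_rate
    data = dff_mat.data
    finite = np.isfinite(data)
    filled = np.where(finite, data, 0.0)
    num = gaussian_filter1d(filled, sd, axis=1, mode="reflect")
    den = gaussian_filter1d(finite.astype(float), sd, axis=1, mode="reflect")
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = num / den
    sm[~finite] = np.nan
    return dff_mat.with_data(sm, smoothing={"kernel_sd_s": kernel_sd_s})


@dataclass
class TrialAverage:
    """Trial-aligned average for one modality.

    ``avg_trace`` is neurons x segment-frames on the relative time grid
    ``rel_times_s`` (0 = first frame at/after onset). ``response`` is the
    mean dF/F over the half-open response window (onset, onset+window], and
    ``mu_b`` / ``sigma_b`` are the mean and SD of the 5 s pre-onset baseline
    of the averaged trace — the statistics the threshold classifier uses.
    ``response_per_trial`` (neurons x trials) supports per-trial analysis.
    """

    avg_trace: np.ndarray
    rel_times_s: np.ndarray
    response: np.ndarray
    mu_b: np.ndarray
    sigma_b: np.ndarray
    n_trials: int
    neuron_ids: np.ndarray
    response_per_trial: np.ndarray
    modality: str
    post_window_s: float
    baseline_s: float


def trial_average(
    dff_mat: DffMatrix,
    protocol: StimulusProtocol,
    modality: str,
    post_window_s: float = 10.0,
    baseline_s: float = 5.0,
) -> TrialAverage:
    """Align trials of one modality at stimulus onset and average them.

    The response amplitude R is the mean of the averaged trace over
    (onset, onset + post_window_s]; the baseline statistics come from
    [-baseline_s, 0). Trials whose segment is not fully inside the
    recording are dropped with a warning.
    """
    onsets = protocol.onsets(modality)
    if onsets.size == 0:
        raise ProtocolError(f"no events of modality {modality!r}")
    fr = dff_mat.frame_rate
    pre_n = int(round(baseline_s * fr))
    post_n = int(np.floor(post_window_s * fr + 1e-9))
    segs = []
    for onset in onsets:
        i0 = int(np.ceil(onset * fr - 1e-9))  # first frame starting at/after onset
        lo, hi = i0 - pre_n, i0 + post_n + 1
        if lo < 0 or hi > dff_mat.n_frames:
            warnings.warn(f"trial at {onset:.1f} s truncated by the recording; dropped",
                          stacklevel=2)
            continue
        segs.append(dff_mat.data[:, lo:hi])
    if not segs:
        raise ProtocolError(f"no complete trials for modality {modality!r}")
    stack = np.stack(segs)  # trials x neurons x frames
    avg = stack.mean(axis=0)
    rel = (np.arange(-pre_n, post_n + 1)) / fr
    resp_mask = (rel > 0) & (rel <= post_window_s + 1e-9)
    base_mask = rel < 0
    response = avg[:, resp_mask].mean(axis=1)
    mu_b = avg[:, base_mask].mean(axis=1)
    sigma_b = avg[:, base_mask].std(axis=1, ddof=0)
    per_trial = stack[:, :, resp_mask].mean(axis=2).T  # neurons x trials
    return TrialAverage(
        avg_trace=avg,
        rel_times_s=rel,
        response=response,
        mu_b=mu_b,
        sigma_b=sigma_b,
        n_trials=stack.shape[0],
        neuron_ids=np.asarray(dff_mat.neuron_ids),
        response_per_trial=per_trial,
        modality=modality,
        post_window_s=post_window_s,
        baseline_s=baseline_s,
    )
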