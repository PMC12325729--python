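"""Threshold and rank-test classification of evoked, drug, and
micro-stimulation responses.

The sensory rule follows the standard deviation criterion: a neuron is
excited when its trial-averaged response R exceeds the baseline mean plus
``k_exc`` baseline SDs (default 2), and inhibited when R falls below the
baseline mean minus ``k_inh`` SDs (default 1). Excitation is checked first;
with positive thresholds the two conditions are mutually exclusive.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .stats import rank_test
from .traces import TrialAverage, trial_average
from .types import ConfigError, DffMatrix, NeuronGeometry, ProtocolError, SchemaError, StimulusProtocol

__all__ = [
    "classify_sensory",
    "labels_from_trial_average",
    "fraction_responders",
    "classify_modality_combination",
    "classify_drug_affected",
    "shuffle_null_fraction",
    "classify_microstim",
    "microstim_distance_contrast",
]


def labels_from_trial_average(ta: TrialAverage, k_exc: float = 2.0, k_inh: float = 1.0) -> pd.DataFrame:
    """Apply the SD-threshold rule to precomputed trial-average statistics."""
    r, mu, sd = ta.response, ta.mu_b, ta.sigma_b
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} neuron(s) with flat baseline classified by sign",
            stacklevel=2,
        )
    excited = r > mu + k_exc * sd
    inhibited = ~excited & (r < mu - k_inh * sd)
    label = np.where(excited, "excited", np.where(inhibited, "inhibited", "none"))
    return pd.DataFrame(
        {
            "neuron_id": ta.neuron_ids,
            "modality": ta.modality,
            "label": label,
            "R": r,
            "mu_b": mu,
            "sigma_b": sd,
            "k_exc": k_exc,
            "k_inh": k_inh,
            "degenerate": degenerate,
        }
    )


def classify_sensory(
    dff_mat: DffMatrix,
    protocol: StimulusProtocol,
    modality: str,
    k_exc: float = 2.0,
    k_inh: float = 1.0,
    window_s: float = 10.0,
    baseline_s: float = 5.0,
) -> pd.DataFrame:
    """Excited / inhibited / none per neuron for one stimulus modality.

    ``k_exc`` is sweepable (the robustness analysis uses 1-4 SD); excited
    sets are nested across increasing thresholds by construction.
    """
    ta = trial_average(dff_mat, protocol, modality, post_window_s=window_s, baseline_s=baseline_s)
    return labels_from_trial_average(ta, k_exc=k_exc, k_inh=k_inh)


def fraction_responders(labels: pd.DataFrame, fish_ids) -> tuple[pd.DataFrame, dict]:
    """Per-fish excited/inhibited percentages; fish are the replication unit.

    Returns (per-fish table, summary dict with mean +/- SEM across fish).
    """
    if len(labels) == 0:
        raise SchemaError("empty label table")
    fish_ids = np.asarray(fish_ids)
    if fish_ids.shape[0] != len(labels):
        raise SchemaError("fish_ids must assign every neuron to exactly one fish")
    df = labels.assign(fish=fish_ids)
    rows = []
    for fish, grp in df.groupby("fish"):
        n = len(grp)
        if n == 0:  # pragma: no cover - groupby never yields empty groups
            warnings.warn(f"fish {fish} has no neurons; excluded", stacklevel=2)
            continue
        rows.append(
            {
                "fish": fish,
                "n_neurons": n,
                "pct_excited": 100.0 * (grp["label"] == "excited").mean(),
                "pct_inhibited": 100.0 * (grp["label"] == "inhibited").mean(),
            }
        )
    per_fish = pd.DataFrame(rows)
    nf = len(per_fish)
    summary = {}
    for col in ("pct_excited", "pct_inhibited"):
        vals = per_fish[col].to_numpy()
        summary[col] = {
            "mean": float(vals.mean()),
            "sem": float(vals.std(ddof=1) / np.sqrt(nf)) if nf > 1 else float("nan"),
            "n_fish": nf,
        }
    return per_fish, summary


def classify_modality_combination(labels_vib: pd.DataFrame, labels_light: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Combine per-modality labels into N / V / L / M classes.

    M = excited to both vibration and light; V / L = excited to exactly one;
    N = excited to neither. Unimodal = V + L and multimodal = M, expressed
    as fractions of responders.
    """
    lv = labels_vib.set_index("neuron_id")
    ll = labels_light.set_index("neuron_id")
    if not lv.index.equals(ll.index):
        raise SchemaError("label tables must cover the same neurons in the same order")
    ev = (lv["label"] == "excited").to_numpy()
    el = (ll["label"] == "excited").to_numpy()
    combo = np.where(ev & el, "M", np.where(ev, "V", np.where(el, "L", "N")))
    out = pd.DataFrame({"neuron_id": lv.index.to_numpy(), "combo": combo})
    n_resp = int((combo != "N").sum())
    fractions = {
        "unimodal": float(np.isin(combo, ["V", "L"]).sum() / n_resp) if n_resp else float("nan"),
        "multimodal": float((combo == "M").sum() / n_resp) if n_resp else float("nan"),
        "n_responders": n_resp,
    }
    return out, fractions


def classify_drug_affected(
    dff_moving: DffMatrix,
    baseline_window_s: tuple,
    drug_window_s: tuple,
    k_up: float = 2.0,
    k_down: float = 1.0,
) -> pd.DataFrame:
    """Drug-affected neurons from moving-window dF/F.

    Up-modulated: drug-window mean exceeds the baseline-window mean plus
    ``k_up`` baseline SDs (the antagonist criterion); down-modulated: below
    the mean minus ``k_down`` SDs (the agonist criterion). Windows are in
    seconds from recording start and must not overlap.
    """
    if dff_moving.mode != "moving_window":
        raise ConfigError("drug classification expects moving-window dF/F")
    b0, b1 = baseline_window_s
    d0, d1 = drug_window_s
    if max(b0, d0) < min(b1, d1):
        raise ConfigError("baseline and drug windows overlap")
    times = dff_moving.frame_times()
    bmask = (times >= b0) & (times < b1)
    dmask = (times >= d0) & (times < d1)
    if bmask.sum() == 0 or dmask.sum() == 0:
        raise ConfigError("a window contains no frames")
    mu = dff_moving.data[:, bmask].mean(axis=1)
    sd = dff_moving.data[:, bmask].std(axis=1, ddof=0)
    drug_mean = dff_moving.data[:, dmask].mean(axis=1)
    up = drug_mean > mu + k_up * sd
    down = ~up & (drug_mean < mu - k_down * sd)
    direction = np.where(up, "up", np.where(down, "down", "none"))
    direction = np.where(np.isfinite(drug_mean) & np.isfinite(mu), direction, "none")
    return pd.DataFrame(
        {
            "neuron_id": dff_moving.neuron_ids,
            "direction": direction,
            "drug_mean": drug_mean,
            "mu_b": mu,
            "sigma_b": sd,
            "k_up": k_up,
            "k_down": k_down,
        }
    )


def _affected_fraction(data, times, baseline_window_s, drug_window_s, direction, k_up, k_down):
    b0, b1 = baseline_window_s
    d0, d1 = drug_window_s
    bmask = (times >= b0) & (times < b1)
    dmask = (times >= d0) & (times < d1)
    mu = data[:, bmask].mean(axis=1)
    sd = data[:, bmask].std(axis=1, ddof=0)
    dm = data[:, dmask].mean(axis=1)
    if direction == "up":
        hit = dm > mu + k_up * sd
    else:
        hit = dm < mu - k_down * sd
    return float(np.mean(hit[np.isfinite(dm) & np.isfinite(mu)]))


def shuffle_null_fraction(
    dff_moving: DffMatrix,
    baseline_window_s: tuple,
    drug_window_s: tuple,
    direction: str = "up",
    n_shuffles: int = 1000,
    seed: int = 0,
    k_up: float = 2.0,
    k_down: float = 1.0,
) -> dict:
    """Chance level of the drug-affected fraction by circular rotation.

    Each shuffle rotates every neuron's trace by an independent uniform
    offset (preserving autocorrelation, destroying event alignment) and
    recomputes the affected fraction. Returns the observed fraction, the
    null distribution, and the chance level (null mean).
    """
    if n_shuffles < 100:
        raise ConfigError("need at least 100 shuffles for a usable null")
    if direction not in ("up", "down"):
        raise ConfigError("direction must be 'up' or 'down'")
    data = dff_moving.data
    times = dff_moving.frame_times()
    n, t = data.shape
    need = max(baseline_window_s[1], drug_window_s[1])
    if times[-1] < need - 1.0 / dff_moving.frame_rate:
        raise ConfigError("recording shorter than the analysis windows")
    observed = _affected_fraction(data, times, baseline_window_s, drug_window_s,
                                  direction, k_up, k_down)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    rows = np.arange(n)[:, None]
    base_idx = np.arange(t)[None, :]
    for s in range(n_shuffles):
        offs = rng.integers(0, t, size=n)[:, None]
        rolled = data[rows, (base_idx + offs) % t]
        null[s] = _affected_fraction(rolled, times, baseline_window_s, drug_window_s,
                                     direction, k_up, k_down)
    return {
        "observed": observed,
        "null": null,
        "chance_level": float(null.mean()),
        "n_shuffles": n_shuffles,
    }


def classify_microstim(
    dff_mat: DffMatrix,
    protocol: StimulusProtocol,
    pre_window_s: float = 5.0,
    post_window_s: float = 2.0,
    alpha: float = 0.05,
    stim_neuron=None,
) -> tuple[pd.DataFrame, bool]:
    """Followers of single-cell micro-stimulation by paired signed-rank test.

    Per event, the median dF/F of the pre-stimulation window and of the
    first ``post_window_s`` seconds post-stimulation are computed; the
    paired medians are compared across events with a two-sided signed-rank
    test. Significant neurons are excited or inhibited by the sign of the
    median post-pre difference. If ``stim_neuron`` is given it is excluded
    from the follower table and must itself test excited for the recording
    to be admitted (second return value).
    """
    onsets = protocol.onsets("microstim")
    if onsets.size < 6:
        raise ProtocolError("need at least 6 micro-stimulation events")
    times = dff_mat.frame_times()
    pre_meds, post_meds = [], []
    for onset in onsets:
        pre = (times >= onset - pre_window_s) & (times < onset)
        post = (times > onset) & (times <= onset + post_window_s)
        if pre.sum() == 0 or post.sum() == 0:
            raise ProtocolError(f"event at {onset:.1f} s has an empty analysis window")
        pre_meds.append(np.median(dff_mat.data[:, pre], axis=1))
        post_meds.append(np.median(dff_mat.data[:, post], axis=1))
    pre_m = np.stack(pre_meds, axis=1)   # neurons x events
    post_m = np.stack(post_meds, axis=1)

    rows = []
    for i, nid in enumerate(np.asarray(dff_mat.neuron_ids)):
        res = rank_test(post_m[i], pre_m[i], paired=True, sided="two_sided")
        diff_med = float(np.median(post_m[i] - pre_m[i]))
        if res.undefined or not res.p_value < alpha:
            label = "none"
        elif diff_med > 0:
            label = "excited"
        elif diff_med < 0:
            label = "inhibited"
        else:
            label = "none"
        rows.append({"neuron_id": nid, "label": label, "p_value": res.p_value,
                     "median_diff": diff_med, "n_events": len(onsets)})
    table = pd.DataFrame(rows)
    admitted = True
    if stim_neuron is not None:
        row = table[table["neuron_id"] == stim_neuron]
        if row.empty:
            raise SchemaError(f"stim_neuron {stim_neuron!r} not in the trace matrix")
        admitted = row["label"].iloc[0] == "excited"
        if not admitted:
            warnings.warn("stimulated neuron not significantly excited; recording rejected",
                          stacklevel=2)
        table = table[table["neuron_id"] != stim_neuron].reset_index(drop=True)
    return table, admitted


def microstim_distance_contrast(
    labels: pd.DataFrame,
    geometry: NeuronGeometry,
    stim_neuron,
    sided: str = "two_sided",
) -> dict:
    """Mean 3-D distance of excited vs inhibited followers to the stimulated
    neuron, with a rank-sum comparison when both groups are populated."""
    geo = geometry.table.set_index("neuron_id")
    if stim_neuron not in geo.index:
        raise SchemaError(f"stim_neuron {stim_neuron!r} not in geometry")
    origin = geo.loc[stim_neuron, ["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    merged = labels.merge(geometry.table, on="neuron_id")
    coords = merged[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    dist = np.linalg.norm(coords - origin, axis=1)
    d_exc = dist[merged["label"].to_numpy() == "excited"]
    d_inh = dist[merged["label"].to_numpy() == "inhibited"]
    out = {
        "mean_dist_excited_um": float(d_exc.mean()) if d_exc.size else float("nan"),
        "mean_dist_inhibited_um": float(d_inh.mean()) if d_inh.size else float("nan"),
        "n_excited": int(d_exc.size),
        "n_inhibited": int(d_inh.size),
        "test": None,
    }
    if d_exc.size and d_inh.size:
        out["test"] = rank_test(d_exc, d_inh, paired=False, sided=sided)
    else:
        warnings.warn("a follower group is empty; rank-sum comparison skipped", stacklevel=2)
    return out
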