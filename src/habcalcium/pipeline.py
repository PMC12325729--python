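"""End-to-end simulate-and-analyse pipeline.

`run_pipeline` generates a synthetic dataset, runs dF/F conversion,
response classification, the multisensory interaction analysis, the
spatial/correlation analyses and the behavioral metrics, and returns (and
optionally writes) a machine-readable summary embedding the resolved
configuration and seed. Identical config + seed give identical summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np

from . import behavior as beh
from . import classify as cl
from . import multisensory as ms
from . import spatial as sp
from . import synthetic as syn
from . import traces as tr
from .io import _jsonable, write_events, write_geometry, write_traces

__all__ = ["run_pipeline", "config_hash"]


def config_hash(config) -> str:
    blob = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: syn.SimConfig | None = None, seed: int = 0,
                 out_dir=None, n_behavior_tracks: int = 6) -> dict:
    """Simulate one fish and run every analysis stage on it."""
    if config is None:
        config = syn.SimConfig(seed=seed)
    else:
        config = dataclasses.replace(config, seed=seed)
    config.validate()

    geometry = syn.generate_population(config)
    protocol = syn.default_evoked_protocol()
    traces, truth = syn.simulate_evoked(geometry, protocol, config)

    dff_trial = tr.dff(traces, "trial_prestim", protocol)
    labels = {
        m: cl.classify_sensory(dff_trial, protocol, m)
        for m in ("light", "vibration")
    }
    fish = np.zeros(len(labels["light"]), dtype=int)
    per_fish = {m: cl.fraction_responders(lab, fish)[0] for m, lab in labels.items()}
    combo, combo_frac = cl.classify_modality_combination(
        labels["vibration"], labels["light"]
    )

    ta = {
        m: tr.trial_average(dff_trial, protocol, m)
        for m in ("light", "vibration", "both")
    }
    records = ms.interaction_index(
        ta["light"].response, ta["vibration"].response, ta["both"].response,
        neuron_ids=ta["light"].neuron_ids,
    )
    cats = ms.category_fractions(records)

    spont_cfg = dataclasses.replace(config, seed=config.seed + 1)
    spont_traces, _ = syn.simulate_spontaneous(geometry, spont_cfg)
    dff_spont = tr.dff(spont_traces, "moving_window")
    corr = sp.pairwise_correlation(dff_spont)
    profile = sp.correlation_vs_distance(corr, geometry, bin_width_um=10.0)
    dorsomedial = sp.select_dorsomedial(geometry)
    division = sp.split_dorsal_ventral(geometry)

    tracks = []
    for i in range(n_behavior_tracks):
        track, _ = syn.simulate_behavior("vibration", seed=seed, track_id=i)
        tracks.append(track)
    dive = [beh.depth_change_fraction(t)["mean"] for t in tracks]

    summary = {
        "seed": seed,
        "config_hash": config_hash(config),
        "config": _jsonable(config),
        "classify": {
            m: {
                "pct_excited": float(per_fish[m]["pct_excited"].iloc[0]),
                "pct_inhibited": float(per_fish[m]["pct_inhibited"].iloc[0]),
            }
            for m in per_fish
        },
        "modality_combination": combo_frac,
        "multisensory": {
            f"pct_{c}": float(cats[f"pct_{c}"].iloc[0]) for c in ms.CATEGORIES
        },
        "spatial": {
            "n_dorsomedial": int(len(dorsomedial)),
            "pct_dorsal": float((division["division"] == "dorsal").mean() * 100),
            "profile_first_bin_r": float(profile.mean_r[np.isfinite(profile.mean_r)][0]),
        },
        "behavior": {"mean_depth_change_fraction": float(np.mean(dive))},
    }
    summary["multisensory"]["n_undefined"] = int(cats["n_undefined"].iloc[0])

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_traces(out / "traces.csv", traces, config=config, seed=seed)
        write_geometry(out / "geometry.csv", geometry)
        write_events(out / "events.csv", protocol)
        truth.neurons.to_csv(out / "ground_truth_neurons.csv", index=False)
        records.to_csv(out / "interaction_records.csv", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
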