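#!/usr/bin/env python
"""Simulate a cohort of fish with known ground truth.

Writes, per fish, the raw trace matrix, neuron geometry, event table and
ground-truth table under results/simulated/, plus behavior tracks for the
three assays. Later analysis steps read these files, so the whole chain
exercises the text-based interchange format.
"""

import dataclasses
from pathlib import Path

from habcalcium import SimConfig
from habcalcium import io as hio
from habcalcium import synthetic as syn

OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"
N_FISH = 7
BASE_SEED = 2025


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    protocol = syn.default_evoked_protocol()
    hio.write_events(OUT / "events.csv", protocol)
    for fish in range(N_FISH):
        cfg = SimConfig(seed=BASE_SEED + fish)
        geo = syn.generate_population(cfg)
        traces, truth = syn.simulate_evoked(geo, protocol, cfg)
        spont, _ = syn.simulate_spontaneous(geo, cfg)
        hio.write_traces(OUT / f"fish{fish}_traces.csv", traces, config=cfg, seed=cfg.seed)
        hio.write_traces(OUT / f"fish{fish}_spont.csv", spont, config=cfg, seed=cfg.seed)
        hio.write_geometry(OUT / f"fish{fish}_geometry.csv", geo)
        truth.neurons.to_csv(OUT / f"fish{fish}_truth.csv", index=False)
        for assay in ("novel_tank", "vibration", "light_dark"):
            track, tgt = syn.simulate_behavior(assay, seed=cfg.seed, track_id=fish)
            hio.write_track(OUT / f"fish{fish}_{assay}.csv", track)
            tgt.tracks.to_csv(OUT / f"fish{fish}_{assay}_truth.csv", index=False)
        print(f"fish {fish}: {cfg.n_neurons} neurons, "
              f"{traces.n_frames} frames at {cfg.frame_rate} Hz")
    print(f"wrote cohort of {N_FISH} fish to {OUT}")


if __name__ == "__main__":
    main()
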