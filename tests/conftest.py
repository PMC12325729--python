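import dataclasses

import numpy as np
import pandas as pd
import pytest

from habcalcium import NeuronGeometry, SimConfig
from habcalcium import synthetic as syn
from habcalcium import traces as tr


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_neurons=60, duration_s=300.0, seed=11)


@pytest.fixture(scope="session")
def evoked_dataset():
    """Moderate evoked dataset shared across classification tests."""
    cfg = SimConfig(n_neurons=200, seed=21)
    geo = syn.generate_population(cfg)
    prot = syn.default_evoked_protocol()
    traces, truth = syn.simulate_evoked(geo, prot, cfg)
    dff = tr.dff(traces, "trial_prestim", prot)
    return {"config": cfg, "geometry": geo, "protocol": prot,
            "traces": traces, "truth": truth, "dff": dff}


@pytest.fixture
def line_geometry():
    """Neurons on a line, single ensemble, for distance-decay checks."""
    n = 40
    return NeuronGeometry(pd.DataFrame({
        "neuron_id": np.arange(n),
        "x_um": np.linspace(0, 120, n),
        "y_um": np.zeros(n),
        "z_um": np.zeros(n),
        "ensemble": np.zeros(n, dtype=int),
    }))


def make_config(**kw) -> SimConfig:
    return dataclasses.replace(SimConfig(), **kw)


def binomial_interval(p: float, n: int, z: float = 1.96) -> tuple:
    """Central 95% normal-approximation interval for a binomial fraction."""
    half = z * np.sqrt(p * (1 - p) / n)
    return p - half, p + half
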