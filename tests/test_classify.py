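"""Excitation/inhibition thresholds, drug-affected detection, shuffle null,
and micro-stimulation follower classification."""

import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest

from habcalcium import ConfigError, NeuronGeometry, SchemaError, SimConfig, StimulusProtocol
from habcalcium import classify as cl
from habcalcium import synthetic as syn
from habcalcium import traces as tr
from habcalcium.traces import TrialAverage

from conftest import binomial_interval


def make_ta(r, mu=None, sd=None, modality="light"):
    r = np.asarray(r, dtype=float)
    mu = np.zeros_like(r) if mu is None else np.asarray(mu, float)
    sd = np.ones_like(r) if sd is None else np.asarray(sd, float)
    n = r.size
    return TrialAverage(
        avg_trace=np.zeros((n, 2)), rel_times_s=np.array([-1.0, 1.0]),
        response=r, mu_b=mu, sigma_b=sd, n_trials=8,
        neuron_ids=np.arange(n), response_per_trial=np.tile(r[:, None], (1, 8)),
        modality=modality, post_window_s=10.0, baseline_s=5.0,
    )


class TestSensoryRule:
    def test_direct_rule(self):
        # mu=0, sigma=5, R=20 -> excited (20 > 0 + 2*5)
        lab = cl.labels_from_trial_average(make_ta([20.0], [0.0], [5.0]))
        assert lab["label"].iloc[0] == "excited"

    def test_boundary_interior_is_none(self):
        lab = cl.labels_from_trial_average(make_ta([0.0], [0.0], [5.0]))
        assert lab["label"].iloc[0] == "none"

    def test_inhibited_rule(self):
        lab = cl.labels_from_trial_average(make_ta([-6.0], [0.0], [5.0]))
        assert lab["label"].iloc[0] == "inhibited"

    def test_flat_baseline_flagged_and_classified_by_sign(self):
        with pytest.warns(UserWarning, match="flat baseline"):
            lab = cl.labels_from_trial_average(make_ta([3.0, -3.0], [0.0, 0.0], [0.0, 0.0]))
        assert lab["degenerate"].all()
        assert lab["label"].tolist() == ["excited", "inhibited"]

    def test_excited_sets_nested_across_thresholds(self, evoked_dataset):
        d, prot = evoked_dataset["dff"], evoked_dataset["protocol"]
        sets = {}
        for k in (1, 2, 3, 4):
            lab = cl.classify_sensory(d, prot, "light", k_exc=k)
            sets[k] = set(lab.loc[lab["label"] == "excited", "neuron_id"])
        assert sets[4] <= sets[3] <= sets[2] <= sets[1]

    def test_label_exclusive_exhaustive(self, evoked_dataset):
        lab = cl.classify_sensory(evoked_dataset["dff"], evoked_dataset["protocol"], "vibration")
        assert set(lab["label"]) <= {"excited", "inhibited", "none"}
        assert len(lab) == evoked_dataset["config"].n_neurons


class TestFractions:
    def test_counting(self):
        lab = pd.DataFrame({
            "neuron_id": range(10), "modality": "light",
            "label": ["excited"] * 3 + ["inhibited"] + ["none"] * 6,
        })
        per_fish, summary = cl.fraction_responders(lab, np.zeros(10, int))
        assert per_fish["pct_excited"].iloc[0] == pytest.approx(30.0)
        assert per_fish["pct_inhibited"].iloc[0] == pytest.approx(10.0)

    def test_empty_labels_is_error(self):
        with pytest.raises(SchemaError):
            cl.fraction_responders(pd.DataFrame(columns=["label"]), [])

    def test_recovery_within_binomial_interval(self, evoked_dataset):
        lab = cl.classify_sensory(evoked_dataset["dff"], evoked_dataset["protocol"], "light")
        cfg = evoked_dataset["config"]
        fe, fi = cfg.responder_fractions["light"]
        lo, hi = binomial_interval(fe, cfg.n_neurons)
        assert lo <= (lab["label"] == "excited").mean() <= hi
        lo, hi = binomial_interval(fi, cfg.n_neurons)
        assert lo <= (lab["label"] == "inhibited").mean() <= hi


class TestModalityCombination:
    @pytest.mark.parametrize("ev,el,expected", [
        ("excited", "excited", "M"), ("excited", "none", "V"),
        ("none", "excited", "L"), ("none", "inhibited", "N"),
    ])
    def test_rules(self, ev, el, expected):
        lv = pd.DataFrame({"neuron_id": [0], "label": [ev]})
        ll = pd.DataFrame({"neuron_id": [0], "label": [el]})
        out, _ = cl.classify_modality_combination(lv, ll)
        assert out["combo"].iloc[0] == expected

    def test_mismatched_sets_error(self):
        lv = pd.DataFrame({"neuron_id": [0, 1], "label": ["none", "none"]})
        ll = pd.DataFrame({"neuron_id": [0, 2], "label": ["none", "none"]})
        with pytest.raises(SchemaError):
            cl.classify_modality_combination(lv, ll)

    def test_overlap_recovery(self):
        cfg = SimConfig(n_neurons=400, seed=31, multimodal_frac=0.15)
        geo = syn.generate_population(cfg)
        prot = syn.default_evoked_protocol()
        traces, truth = syn.simulate_evoked(geo, prot, cfg)
        d = tr.dff(traces, "trial_prestim", prot)
        lv = cl.classify_sensory(d, prot, "vibration")
        ll = cl.classify_sensory(d, prot, "light")
        out, frac = cl.classify_modality_combination(lv, ll)
        true_m = ((truth.neurons["class_light"] == "excited")
                  & (truth.neurons["class_vibration"] == "excited")).mean()
        assert true_m == pytest.approx(0.15, abs=1e-9)
        lo, hi = binomial_interval(0.15, 400)
        assert lo <= (out["combo"] == "M").mean() <= hi


def drug_dff(n_neurons=80, n_up=0, shift_sd=0.0, seed=0, duration_s=1500.0, fs=2.0,
             noise_sd=2.0):
    """Stationary dF/F noise with an optional shift (in baseline SDs) confined
    to the drug window, built directly on the dF/F scale."""
    rng = np.random.default_rng(seed)
    nf = int(duration_s * fs)
    data = rng.normal(0, noise_sd, size=(n_neurons, nf))
    t = np.arange(nf) / fs
    if n_up:
        in_drug = (t >= DRUG_WIN[0]) & (t < DRUG_WIN[1])
        data[:n_up, in_drug] += shift_sd * noise_sd
    from habcalcium import DffMatrix
    return DffMatrix(data, fs, mode="moving_window")


BASE_WIN = (480.0, 780.0)   # 5 min before wash-in
DRUG_WIN = (780.0, 1080.0)  # minute 13-18


class TestDrugAffected:
    def test_step_increase_is_up(self):
        d = drug_dff(n_neurons=5, n_up=5, shift_sd=3.0, seed=1)
        lab = cl.classify_drug_affected(d, BASE_WIN, DRUG_WIN)
        assert (lab["direction"] == "up").all()

    def test_null_population_mostly_none(self):
        d = drug_dff(n_neurons=100, seed=2)
        lab = cl.classify_drug_affected(d, BASE_WIN, DRUG_WIN)
        assert (lab["direction"] == "none").mean() > 0.9

    def test_overlapping_windows_error(self):
        d = drug_dff(n_neurons=3, seed=3)
        with pytest.raises(ConfigError):
            cl.classify_drug_affected(d, (480.0, 800.0), DRUG_WIN)

    def test_forty_percent_up_recovered(self):
        cfg = SimConfig(n_neurons=200, seed=33, duration_s=1500.0,
                        responder_fractions={}, drug_fractions={"up": 0.4, "down": 0.0},
                        amp_drug=0.6)
        geo = syn.generate_population(cfg)
        prot = syn.default_drug_protocol()
        traces, truth = syn.simulate_evoked(geo, prot, cfg, duration_s=1500.0)
        d = tr.dff(traces, "moving_window")
        lab = cl.classify_drug_affected(d, BASE_WIN, DRUG_WIN)
        lo, hi = binomial_interval(0.4, 200)
        assert lo <= (lab["direction"] == "up").mean() <= hi


class TestShuffleNull:
    def test_determinism(self):
        d = drug_dff(n_neurons=20, seed=4, duration_s=1500.0)
        a = cl.shuffle_null_fraction(d, BASE_WIN, DRUG_WIN, n_shuffles=100, seed=5)
        b = cl.shuffle_null_fraction(d, BASE_WIN, DRUG_WIN, n_shuffles=100, seed=5)
        np.testing.assert_array_equal(a["null"], b["null"])

    def test_stationary_noise_within_null_interval(self):
        d = drug_dff(n_neurons=100, seed=6, duration_s=1500.0)
        res = cl.shuffle_null_fraction(d, BASE_WIN, DRUG_WIN, n_shuffles=300, seed=7)
        lo, hi = np.percentile(res["null"], [2.5, 97.5])
        assert lo <= res["observed"] <= hi

    def test_strong_effect_exceeds_null(self):
        d = drug_dff(n_neurons=50, n_up=20, shift_sd=5.0, seed=8, duration_s=1500.0)
        res = cl.shuffle_null_fraction(d, BASE_WIN, DRUG_WIN, n_shuffles=1000, seed=9)
        assert res["observed"] > res["null"].max()


def microstim_protocol(n_events=8, start=30.0, isi=60.0):
    return StimulusProtocol(pd.DataFrame(
        [{"onset_s": start + i * isi, "duration_s": 0.1, "modality": "microstim"}
         for i in range(n_events)]))


class TestMicrostim:
    def test_zero_differences_is_none(self):
        from habcalcium import TraceMatrix
        f = np.full((2, 1200), 100.0)
        prot = microstim_protocol(6)
        d = tr.dff(TraceMatrix(f, 3.0), "trial_prestim", prot)
        lab, admitted = cl.classify_microstim(d, prot)
        assert (lab["label"] == "none").all()

    def test_six_events_all_positive_exact_p(self):
        # oracle: enumerate all 2^6 sign assignments of the rank sum
        ranks = np.arange(1, 7)
        stats = [sum(r for r, s in zip(ranks, signs) if s > 0)
                 for signs in itertools.product([-1, 1], repeat=6)]
        observed = ranks.sum()
        p_exact = np.mean([min(s, 21 - s) <= min(observed, 21 - observed)
                           for s in stats])
        assert p_exact == pytest.approx(2 / 64)

        from habcalcium import TraceMatrix
        fs = 3.0
        prot = microstim_protocol(6)
        nf = int(400 * fs)
        f = np.full((1, nf), 100.0)
        t = np.arange(nf) / fs
        for i, o in enumerate(prot.onsets("microstim")):
            f[0, (t > o) & (t <= o + 2.0)] = 100.0 * (1 + 0.1 * (1 + 0.01 * i))
        d = tr.dff(TraceMatrix(f, fs), "trial_prestim", prot)
        lab, _ = cl.classify_microstim(d, prot)
        assert lab["p_value"].iloc[0] == pytest.approx(2 / 64)
        assert lab["label"].iloc[0] == "excited"

    def test_generated_inhibited_follower(self):
        cfg = SimConfig(n_neurons=40, seed=35,
                        responder_fractions={"microstim": (0.3, 0.3)},
                        trial_jitter=0.0, noise_sd=1.0)
        geo = syn.generate_population(cfg)
        prot = microstim_protocol(8)
        traces, truth = syn.simulate_evoked(geo, prot, cfg)
        d = tr.dff(traces, "trial_prestim", prot)
        lab, _ = cl.classify_microstim(d, prot)
        merged = lab.merge(truth.neurons[["neuron_id", "class_microstim"]], on="neuron_id")
        inh = merged[merged["class_microstim"] == "inhibited"]
        assert (inh["label"] == "inhibited").mean() > 0.9

    def test_recording_rejected_if_stim_neuron_silent(self):
        from habcalcium import TraceMatrix
        rng = np.random.default_rng(36)
        prot = microstim_protocol(6)
        f = 100.0 + rng.normal(0, 1.0, size=(3, 1200))
        d = tr.dff(TraceMatrix(f, 3.0), "trial_prestim", prot)
        with pytest.warns(UserWarning, match="rejected"):
            lab, admitted = cl.classify_microstim(d, prot, stim_neuron=0)
        assert not admitted
        assert 0 not in set(lab["neuron_id"])

    def test_too_few_events(self):
        from habcalcium import TraceMatrix, ProtocolError
        f = np.full((1, 900), 100.0)
        prot = microstim_protocol(4)
        d = tr.dff(TraceMatrix(f, 3.0), "trial_prestim", prot)
        with pytest.raises(ProtocolError):
            cl.classify_microstim(d, prot)


class TestMicrostimDistance:
    def test_three_four_five(self):
        geo = NeuronGeometry(pd.DataFrame({
            "neuron_id": [0, 1], "x_um": [0.0, 3.0], "y_um": [0.0, 4.0],
            "z_um": [0.0, 0.0]}))
        lab = pd.DataFrame({"neuron_id": [1], "label": ["excited"]})
        with pytest.warns(UserWarning, match="empty"):
            out = cl.microstim_distance_contrast(lab, geo, stim_neuron=0)
        assert out["mean_dist_excited_um"] == pytest.approx(5.0)

    def test_ring_construction(self):
        n = 21
        ang = np.linspace(0, 2 * np.pi, n - 1, endpoint=False)
        geo = NeuronGeometry(pd.DataFrame({
            "neuron_id": np.arange(n),
            "x_um": np.r_[0.0, np.cos(ang[:10]) * 10, np.cos(ang[10:]) * 50],
            "y_um": np.r_[0.0, np.sin(ang[:10]) * 10, np.sin(ang[10:]) * 50],
            "z_um": np.zeros(n)}))
        lab = pd.DataFrame({
            "neuron_id": np.arange(1, n),
            "label": ["excited"] * 10 + ["inhibited"] * 10})
        out = cl.microstim_distance_contrast(lab, geo, stim_neuron=0)
        assert out["mean_dist_excited_um"] == pytest.approx(10.0)
        assert out["mean_dist_inhibited_um"] == pytest.approx(50.0)
        assert out["test"].p_value < 0.01
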