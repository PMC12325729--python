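"""Correlation matrices, pair significance, correlation-distance profiles,
response-vector similarity, and anatomical subsetting."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import curve_fit

from habcalcium import ConfigError, DffMatrix, NeuronGeometry, SchemaError, SimConfig
from habcalcium import spatial as sp
from habcalcium import synthetic as syn


def geometry_from(x, y=None, z=None):
    n = len(x)
    return NeuronGeometry(pd.DataFrame({
        "neuron_id": np.arange(n),
        "x_um": np.asarray(x, float),
        "y_um": np.zeros(n) if y is None else np.asarray(y, float),
        "z_um": np.zeros(n) if z is None else np.asarray(z, float),
    }))


class TestPairwiseCorrelation:
    def test_self_negation_and_hand_value(self):
        a = np.array([1.0, 2.0, 3.0])
        data = np.vstack([a, -a, [1.0, 2.0, 4.0]])
        corr = sp.pairwise_correlation(data)
        assert corr[0, 0] == pytest.approx(1.0)
        assert corr[0, 1] == pytest.approx(-1.0)
        # hand computation of Pearson r for (1,2,3) vs (1,2,4)
        assert corr[0, 2] == pytest.approx(0.9819805060619657)
        np.testing.assert_allclose(corr, corr.T)

    def test_zero_variance_flagged(self):
        data = np.vstack([np.ones(10), np.arange(10.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = sp.pairwise_correlation(data)
        assert np.isnan(corr[0, 1]) and corr[1, 1] == 1.0

    def test_affine_invariance(self):
        rng = np.random.default_rng(7)
        data = rng.normal(size=(5, 100))
        corr1 = sp.pairwise_correlation(data)
        corr2 = sp.pairwise_correlation(3.0 * data + 11.0)
        np.testing.assert_allclose(corr1, corr2, atol=1e-12)


class TestSignificantPairs:
    def test_zero_r_is_ns(self):
        corr = np.eye(3)
        out = sp.significant_pairs(corr, n_frames=100)
        assert (out["label"] == "ns").all()

    def test_shared_signal_positive(self):
        rng = np.random.default_rng(8)
        latent = rng.normal(size=2000)
        data = latent[None, :] + 0.1 * rng.normal(size=(4, 2000))
        d = DffMatrix(data, 2.0, mode="moving_window")
        corr = sp.pairwise_correlation(d)
        out = sp.significant_pairs(corr, n_frames=2000, dff_mat=d)
        assert (out["label"] == "positive").all()

    def test_white_noise_false_positive_rate(self):
        rng = np.random.default_rng(9)
        data = rng.normal(size=(40, 1000))
        d = DffMatrix(data, 2.0, mode="moving_window")
        corr = sp.pairwise_correlation(d)
        out = sp.significant_pairs(corr, n_frames=1000, dff_mat=d, alpha=0.05)
        frac = (out["label"] != "ns").mean()
        assert 0.02 <= frac <= 0.09

    def test_permutation_method(self):
        rng = np.random.default_rng(10)
        latent = rng.normal(size=500)
        data = np.vstack([latent + 0.2 * rng.normal(size=500) for _ in range(3)]
                         + [rng.normal(size=500)])
        d = DffMatrix(data, 2.0, mode="moving_window")
        corr = sp.pairwise_correlation(d)
        out = sp.significant_pairs(corr, n_frames=500, method="perm", dff_mat=d,
                                   n_perm=200, seed=1)
        shared = out[(out["i"] < 3) & (out["j"] < 3)]
        assert (shared["label"] == "positive").all()


class TestPairDistances:
    def test_construction(self):
        geo = geometry_from([0.0, 10.0, 0.0, 60.0])
        labels = pd.DataFrame({"i": [0, 2], "j": [1, 3], "r": [0.9, -0.8],
                               "label": ["positive", "negative"]})
        out = sp.pair_distances(labels, geo)
        assert out["mean_dist_positive_um"] == pytest.approx(10.0)
        assert out["mean_dist_negative_um"] == pytest.approx(60.0)

    def test_identical_distributions_null(self):
        rng = np.random.default_rng(11)
        fish = []
        for _ in range(8):
            d = rng.uniform(10, 50)
            fish.append({"mean_dist_positive_um": d, "mean_dist_negative_um": d})
        out = sp.pair_distance_contrast(fish, sided="less")
        assert out["test"].undefined  # all differences zero

    def test_anticorrelated_distant_ensembles(self):
        cfg = SimConfig(n_neurons=60, n_ensembles=2, cross_coupling=-1.0,
                        noise_sd=1.0, duration_s=500.0, box_um=(200.0, 60.0, 80.0),
                        seed=12)
        fish = []
        for s in range(6):
            import dataclasses
            c = dataclasses.replace(cfg, seed=100 + s)
            geo = syn.generate_population(c)
            traces, _ = syn.simulate_spontaneous(geo, c)
            corr = sp.pairwise_correlation(traces.data)
            pairs = sp.significant_pairs(corr, traces.n_frames)
            fish.append(sp.pair_distances(pairs, geo))
        out = sp.pair_distance_contrast(fish, sided="less")
        assert (out["per_fish_positive_um"] < out["per_fish_negative_um"]).mean() > 0.8
        assert out["test"].p_value < 0.05


class TestCorrelationVsDistance:
    def test_equidistant_single_bin(self):
        geo = geometry_from([0.0, 10.0], [0.0, 0.0])
        corr = np.array([[1.0, 0.5], [0.5, 1.0]])
        prof = sp.correlation_vs_distance(corr, geo, bin_width_um=20.0)
        occupied = np.flatnonzero(prof.counts)
        assert len(occupied) == 1
        assert prof.mean_r[occupied[0]] == pytest.approx(0.5)

    def test_shared_signal_flat_profile(self):
        rng = np.random.default_rng(13)
        latent = rng.normal(size=1000)
        data = latent[None, :] + 0.01 * rng.normal(size=(10, 1000))
        geo = geometry_from(np.linspace(0, 90, 10))
        prof = sp.correlation_vs_distance(sp.pairwise_correlation(data), geo, 10.0)
        finite = np.isfinite(prof.mean_r)
        assert np.all(prof.mean_r[finite] > 0.99)

    def test_binned_means_match_loop_oracle(self):
        rng = np.random.default_rng(14)
        n = 25
        geo = geometry_from(rng.uniform(0, 100, n), rng.uniform(0, 60, n),
                            rng.uniform(0, 40, n))
        corr = sp.pairwise_correlation(rng.normal(size=(n, 50)))
        prof = sp.correlation_vs_distance(corr, geo, bin_width_um=15.0)
        # oracle: explicit per-pair loop
        pos = geo.positions
        sums = np.zeros_like(prof.mean_r)
        counts = np.zeros_like(prof.counts)
        for i in range(n):
            for j in range(i + 1, n):
                d = np.sqrt(((pos[i] - pos[j]) ** 2).sum())
                b = min(int(d // 15.0), len(sums) - 1)
                sums[b] += corr[i, j]
                counts[b] += 1
        np.testing.assert_array_equal(prof.counts, counts)
        for b in range(len(sums)):
            if counts[b]:
                assert prof.mean_r[b] == pytest.approx(sums[b] / counts[b], rel=1e-12)

    def test_exponential_decay_scale_recovered(self):
        # population whose pairwise correlation decays as exp(-d / L)
        rng = np.random.default_rng(15)
        n, L = 60, 30.0
        x = np.sort(rng.uniform(0, 150, n))
        geo = geometry_from(x)
        cov = np.exp(-np.abs(x[:, None] - x[None, :]) / L)
        data = rng.multivariate_normal(np.zeros(n), cov, size=3000).T
        prof = sp.correlation_vs_distance(sp.pairwise_correlation(data), geo, 10.0)
        m = np.isfinite(prof.mean_r) & (prof.counts > 5)
        popt, _ = curve_fit(lambda d, l: np.exp(-d / l), prof.bin_centers_um[m],
                            prof.mean_r[m], p0=[20.0])
        assert abs(popt[0] - L) / L < 0.25


class TestCompareProfiles:
    def _profiles(self, offsets, decay=0.0, n_units=6, seed=0):
        rng = np.random.default_rng(seed)
        edges = np.arange(0.0, 60.0, 10.0)
        out = {}
        for treat, off in offsets.items():
            plist = []
            for _ in range(n_units):
                centers = 0.5 * (edges[:-1] + edges[1:])
                r = off + decay * np.exp(-centers / 20.0) + 0.02 * rng.normal(size=len(centers))
                plist.append(sp.CorrelationDistanceProfile(edges, r, np.full(len(r), 10)))
            out[treat] = plist
        return out

    def test_identical_flat_profiles_no_treatment_effect(self):
        profs = self._profiles({"a": 0.3, "b": 0.3}, seed=16)
        res = sp.compare_profiles(profs)
        assert res["treatment"]["p"] > 0.05

    def test_offset_treatment_detected(self):
        profs = self._profiles({"ctrl": 0.2, "drug": 0.45}, n_units=8, seed=17)
        res = sp.compare_profiles(profs)
        assert res["treatment"]["p"] < 0.001

    def test_distance_effect_without_treatment_effect(self):
        # under the null the treatment p-value is uniform, so check its
        # rejection rate over replicates instead of a single draw
        p_treat, p_dist = [], []
        for rep in range(30):
            profs = self._profiles({"a": 0.1, "b": 0.1}, decay=0.5, n_units=8,
                                   seed=1000 + rep)
            res = sp.compare_profiles(profs)
            p_treat.append(res["treatment"]["p"])
            p_dist.append(res["distance"]["p"])
        assert all(p < 1e-6 for p in p_dist)
        assert np.mean(np.asarray(p_treat) < 0.05) <= 0.2


class TestResponseVectorSimilarity:
    def test_identical(self):
        out = sp.response_vector_similarity([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["cosine"] == pytest.approx(1.0)

    def test_orthogonal(self):
        out = sp.response_vector_similarity([1.0, 0.0, 0.0], [0.0, 1.0, 0.0])
        assert out["cosine"] == pytest.approx(0.0)

    def test_closed_form_cosine(self):
        out = sp.response_vector_similarity([1.0, 0.0, 0.0], [1.0, 1.0, 0.0])
        assert out["cosine"] == pytest.approx(1 / np.sqrt(2))

    def test_zero_vector_flagged(self):
        with pytest.warns(UserWarning, match="zero response vector"):
            out = sp.response_vector_similarity([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
        assert np.isnan(out["cosine"])


class TestSelectDorsomedial:
    def test_hand_enumeration(self):
        # y = 0..4, z = 0: scores (0.5, 0.25, 0, 0.25, 0.5); 40% of 5 -> 2 kept:
        # the y=2 neuron and the lower-id member of the {1, 3} tie
        geo = geometry_from(np.zeros(5), y=[0.0, 1.0, 2.0, 3.0, 4.0])
        kept = sp.select_dorsomedial(geo, fraction=0.4)
        assert kept.tolist() == [1, 2]

    def test_fraction_one_keeps_all(self):
        geo = geometry_from(np.zeros(7), y=np.arange(7.0))
        assert len(sp.select_dorsomedial(geo, fraction=1.0)) == 7

    def test_hundred_neurons_forty_kept(self):
        rng = np.random.default_rng(19)
        geo = geometry_from(np.zeros(100), y=rng.permutation(100).astype(float),
                            z=rng.permutation(100).astype(float))
        assert len(sp.select_dorsomedial(geo, fraction=0.40)) == 40

    def test_translation_and_scaling_invariance(self):
        rng = np.random.default_rng(20)
        y, z = rng.uniform(0, 60, 30), rng.uniform(0, 80, 30)
        base = sp.select_dorsomedial(geometry_from(np.zeros(30), y=y, z=z))
        moved = sp.select_dorsomedial(
            geometry_from(np.zeros(30), y=2.5 * y + 100.0, z=0.3 * z + 7.0))
        np.testing.assert_array_equal(base, moved)

    def test_bad_fraction(self):
        geo = geometry_from([0.0], y=[0.0])
        with pytest.raises(ConfigError):
            sp.select_dorsomedial(geo, fraction=0.0)


class TestSplitDorsalVentral:
    def test_boundary_rule(self):
        geo = geometry_from(np.zeros(3), z=[10.0, 40.0, 50.0])
        out = sp.split_dorsal_ventral(geo, threshold_um=40.0)
        assert out["division"].tolist() == ["dorsal", "ventral", "ventral"]

    def test_all_surface(self):
        geo = geometry_from(np.zeros(4), z=np.zeros(4))
        assert (sp.split_dorsal_ventral(geo)["division"] == "dorsal").all()

    def test_uniform_depths_half_dorsal(self):
        rng = np.random.default_rng(21)
        z = rng.uniform(0, 80, 2000)
        out = sp.split_dorsal_ventral(geometry_from(np.zeros(2000), z=z), 40.0)
        assert (out["division"] == "dorsal").mean() == pytest.approx(0.5, abs=0.05)
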