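"""Ensemble analytics: TSE/BSE extraction, clustering, flow, correlations."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from dimerpath.analysis import (EnsembleCluster, TransitionPath,
                                binding_initiative, cluster_bse, cluster_tse,
                                contact_frequency, contact_series_from_frames,
                                extract_bse, extract_tse, flow_matrix,
                                isocommittor_profiles, kmedoids,
                                pb_distance_correlation, switching_fraction)
from dimerpath.helices import make_archetypes
from dimerpath.system import Configuration, N_RESIDUES
from dimerpath.descriptors import sidechain_distances


def toy_tp(pb, frames=None, **kw):
    pb = np.asarray(pb, dtype=float)
    if frames is None:
        frames = np.column_stack([np.linspace(-1, 1, len(pb)),
                                  np.zeros(len(pb))])
    return TransitionPath(frames=frames, pb=pb, **kw)


def interpolated_helix_tp(n_frames=50, d0=3.0, d1=0.5):
    """Two straight chains approaching linearly: every equivalent-residue
    distance is an exact linear function of the frame index (and of pb)."""
    z = np.arange(N_RESIDUES) * 0.15
    bb1 = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    frames = []
    for t in np.linspace(0, 1, n_frames):
        sep = d0 + t * (d1 - d0)
        bb2 = bb1 + [sep, 0.0, 0.0]
        frames.append(Configuration(bb1, bb2, bb1.copy(), bb2.copy()))
    pb = np.linspace(0.0, 1.0, n_frames)
    return TransitionPath(frames=frames, pb=pb, channel="upper")


class TestExtraction:
    def test_linear_ramp_selects_the_middle_band(self):
        tp = toy_tp(np.linspace(0, 1, 100))
        picks = extract_tse([tp], band=(0.45, 0.55))
        assert len(picks) == 10
        idx = [j for _, j in picks]
        assert min(idx) == 45 and max(idx) == 54

    def test_full_band_selects_all_frames(self):
        tp = toy_tp(np.linspace(0, 1, 30))
        assert len(extract_tse([tp], band=(0.0, 1.0))) == 30

    def test_fallback_nearest_to_half(self):
        tp = toy_tp([0.0, 0.1, 0.9, 1.0])
        picks = extract_tse([tp])
        assert picks == [(0, 1)]  # 0.1 is nearest to 0.5

    def test_bse_one_frame_per_toy_path(self):
        tps = [toy_tp(np.linspace(0, 1, n)) for n in (10, 20)]
        picks = extract_bse(tps)
        assert picks == [(0, 9), (1, 19)]

    def test_bse_missing_dimerized_frame_is_error(self):
        tp = interpolated_helix_tp(n_frames=5, d0=6.0, d1=3.0)  # never binds
        with pytest.raises(ValueError):
            extract_bse([tp])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            extract_tse([])


class TestClustering:
    def test_single_cluster_population_one(self, rng):
        X = rng.normal(0, 1, (10, 4))
        labels, clusters = cluster_bse(X, k=1, seed=0)
        assert clusters[0].population == 1.0
        assert np.all(labels == 0)

    def test_duplicated_dataset_same_assignment(self, rng):
        centers = np.array([[0.0, 0], [5.0, 0], [0.0, 5]])
        X = np.vstack([c + rng.normal(0, 0.3, (8, 2)) for c in centers])
        l1, _ = cluster_bse(X, k=3, seed=0)
        l2, _ = cluster_bse(np.vstack([X, X]), k=3, seed=0)
        assert adjusted_rand_score(np.concatenate([l1, l1]), l2) == 1.0

    def test_k_exceeding_n_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_bse(rng.normal(0, 1, (3, 2)), k=5)
        with pytest.raises(ValueError):
            cluster_tse(rng.normal(0, 1, (3, 2)), k=5)

    def test_every_point_its_own_medoid_at_k_equals_n(self, rng):
        X = rng.normal(0, 1, (6, 3))
        labels, medoids = kmedoids(X, k=6, seed=0)
        assert sorted(medoids) == list(range(6))

    def test_medoid_is_always_a_member(self, rng):
        X = np.vstack([rng.normal(0, 0.2, (15, 4)),
                       rng.normal(3, 0.2, (12, 4))])
        labels, clusters = cluster_tse(X, k=2, seed=0)
        for c in clusters:
            assert c.medoid_index in c.member_indices
            assert any(np.array_equal(c.representative, X[i])
                       for i in c.member_indices)

    def test_kmedoids_recovers_planted_channels(self):
        X, y = [], []
        for i, kind in enumerate(("X", "Lambda")):
            for cfg in make_archetypes(kind, 12, seed=20 + i, noise_sd=0.0):
                X.append(sidechain_distances(cfg))
                y.append(i)
        labels, _ = cluster_tse(np.asarray(X), k=2, seed=0)
        assert adjusted_rand_score(y, labels) == 1.0


class TestFlowAndSwitching:
    def test_single_route_single_entry(self):
        M = flow_matrix([0, 0, 0], [0, 0, 0], k_tse=2, k_bse=3)
        assert M[0, 0] == 3 and M.sum() == 3

    def test_planted_2_1_1_split(self):
        bse = [0, 0, 1, 2] * 10
        M = flow_matrix([0] * 40, bse, k_tse=1, k_bse=3)
        assert np.allclose(M[0] / M.sum(), [0.5, 0.25, 0.25])

    def test_total_conserved_and_labels_required(self, toy_pipeline):
        run, _, _ = toy_pipeline
        tps = run.transition_paths
        t = np.array([0 if tp["channel"] == "upper" else 1 for tp in tps])
        b = np.array([tp["terminal_state"] - 2 for tp in tps])
        M = flow_matrix(t, b, k_tse=2, k_bse=3)
        assert M.sum() == len(tps)
        with pytest.raises(ValueError):
            flow_matrix([0, -1], [0, 1])

    @pytest.mark.parametrize("labels,expected", [
        ([1, 1, 1, 1], 0.0),
        ([1, 2, 1, 2], 1.0),
        ([1, 1, 2, 2, 3], 0.5),
    ])
    def test_switch_fraction_anchors(self, labels, expected):
        res = switching_fraction([labels])
        assert res["fractions"][0] == pytest.approx(expected)

    def test_short_chains_excluded_with_note(self):
        with pytest.warns(UserWarning, match="excluded"):
            res = switching_fraction([[1], [1, 2]])
        assert res["n_excluded"] == 1
        assert len(res["fractions"]) == 1


class TestCorrelations:
    def test_linear_comonotone_distance_gives_minus_one(self):
        tp = interpolated_helix_tp()
        corr = pb_distance_correlation([tp])
        assert np.allclose(corr, -1.0, atol=1e-12)

    def test_shuffled_distance_uncorrelated(self, rng):
        z = np.arange(N_RESIDUES) * 0.15
        bb1 = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        seps = rng.permutation(np.linspace(0.5, 3.0, 1000))
        frames = [Configuration(bb1, bb1 + [s, 0, 0], bb1.copy(),
                                bb1 + [s, 0, 0]) for s in seps]
        tp = TransitionPath(frames=frames, pb=np.linspace(0, 1, 1000))
        corr = pb_distance_correlation([tp])
        assert np.all(np.abs(corr) < 0.1)

    def test_constant_distance_undefined(self):
        tp = interpolated_helix_tp(d0=2.0, d1=2.0)
        corr = pb_distance_correlation([tp])
        assert np.all(np.isnan(corr))

    def test_per_path_averaging_option(self):
        tps = [interpolated_helix_tp(), interpolated_helix_tp(d0=2.5, d1=0.4)]
        corr = pb_distance_correlation(tps, pooled=False)
        assert np.allclose(corr, -1.0, atol=1e-12)


class TestIsocommittorProfiles:
    def test_profiles_shrink_with_level(self):
        tp = interpolated_helix_tp()
        prof = isocommittor_profiles([tp], levels=(0.3, 0.5, 0.8))
        p = prof["upper"]
        assert np.all(p[0.3] > p[0.5]) and np.all(p[0.5] > p[0.8])

    def test_invalid_levels_rejected(self):
        with pytest.raises(ValueError):
            isocommittor_profiles([interpolated_helix_tp()], levels=(0.5, 1.2))

    def test_empty_level_omitted_with_note(self):
        tp = interpolated_helix_tp()
        tp = TransitionPath(frames=tp.frames, pb=np.full(len(tp), 0.9),
                            channel="upper")
        with pytest.warns(UserWarning, match="omitted"):
            prof = isocommittor_profiles([tp], levels=(0.3,))
        assert prof["upper"] == {}


class TestContactFrequency:
    def test_anchor_values(self):
        z = np.arange(N_RESIDUES) * 5.0   # residues far apart within a helix
        bb1 = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        for sep, expected in ((0.0, 1.0), (0.45, 0.5)):
            frames = [Configuration(bb1, bb1 + [sep, 0, 0], bb1.copy(),
                                    bb1 + [sep, 0, 0])]
            f = contact_frequency(frames)
            assert np.allclose(np.diag(f), expected)
        far = [Configuration(bb1, bb1 + [2.5, 0, 0], bb1.copy(),
                             bb1 + [2.5, 0, 0])]
        assert np.all(contact_frequency(far) < 1e-8)


class TestBindingInitiative:
    def test_formation_time_anchors(self):
        T = 100
        s = np.zeros((T, 2), dtype=bool)
        s[25:, 0] = True
        s[75:, 1] = True
        scores = binding_initiative(s)
        assert scores[0] == pytest.approx(1.0)
        assert scores[1] == pytest.approx(0.0)

    def test_three_contacts_evenly_spread(self):
        T = 100
        s = np.zeros((T, 3), dtype=bool)
        s[25:, 0] = True
        s[50:, 1] = True
        s[75:, 2] = True
        assert np.allclose(binding_initiative(s), [1.0, 0.5, 0.0])

    def test_persistent_from_start_scores_one(self):
        s = np.ones((50, 1), dtype=bool)
        assert binding_initiative(s)[0] == 1.0

    def test_never_persistent_reported_absent(self):
        T = 100
        s = np.zeros((T, 2), dtype=bool)
        s[10:, 0] = True
        s[::2, 1] = True          # present only half the time: not persistent
        scores = binding_initiative(s)
        assert scores[0] == 1.0
        assert np.isnan(scores[1])

    def test_persistence_requires_90_percent_of_remainder(self):
        T = 100
        s = np.zeros((T, 1), dtype=bool)
        s[20:, 0] = True
        s[60:65, 0] = False       # 5% gap in the remainder: still persistent
        scores = binding_initiative(s)
        assert np.isfinite(scores[0])

    def test_series_from_frames(self):
        tp = interpolated_helix_tp(n_frames=10, d0=2.0, d1=0.1)
        series = contact_series_from_frames(tp.frames)
        assert series.shape == (10, N_RESIDUES)
        assert not series[0].any() and series[-1].all()
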