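"""Featurization: switching function, distances, state definitions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dimerpath.descriptors import (GeometryError, N_DESCRIPTORS, classify,
                                   contact_sum_sigma, backbone_distances,
                                   descriptor_names, descriptor_ordering_hash,
                                   featurize, global_descriptors,
                                   min_interhelix_distance, n_contacts,
                                   residue_pair_min_distances,
                                   sidechain_distances, switch)
from dimerpath.helices import HelixPairGeometry, make_archetypes, make_helix_pair
from dimerpath.system import Configuration, N_RESIDUES


def superposed_config():
    geom = HelixPairGeometry(inter_axis_distance=4.0, noise_sd=0.0)
    cfg = make_helix_pair(geom)
    return Configuration(cfg.bb1, cfg.bb1.copy(), cfg.sc1, cfg.sc1.copy())


def line_config(separation=6.0, spacing=0.5):
    """Two straight 'helices' with residues spaced along z, sc tips = anchors."""
    z = np.arange(N_RESIDUES) * spacing
    bb1 = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    bb2 = bb1 + [separation, 0.0, 0.0]
    return Configuration(bb1, bb2, bb1.copy(), bb2.copy())


class TestSwitch:
    def test_printed_anchor_values(self):
        assert switch(0.0, 1.7) == 1.0
        assert switch(1.7, 1.7) == pytest.approx(0.5, abs=1e-12)
        assert switch(3.4, 1.7) == pytest.approx(1.0 / (1.0 + 2.0 ** 12), rel=1e-12)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            switch(1.0, 0.0)
        with pytest.raises(ValueError):
            switch(-0.1, 1.0)

    @settings(derandomize=True, max_examples=200)
    @given(d=st.floats(0.0, 10.0), r0=st.floats(0.05, 5.0))
    def test_agrees_with_literal_form_and_stays_in_unit_interval(self, d, r0):
        s = switch(d, r0)
        assert 0.0 < s <= 1.0
        x = d / r0
        if abs(x - 1.0) > 1e-3:  # literal form has a removable 0/0 at d = r0
            literal = (1.0 - x ** 12) / (1.0 - x ** 24)
            assert s == pytest.approx(literal, abs=1e-12)

    def test_strictly_decreasing(self):
        d = np.linspace(0.0, 5.0, 200)
        s = switch(d, 1.7)
        assert np.all(np.diff(s) <= 0)
        # strictly decreasing wherever (d/r0)^12 does not underflow
        d2 = np.linspace(0.6, 5.0, 200)
        assert np.all(np.diff(switch(d2, 1.7)) < 0)


class TestDistances:
    def test_superposed_helices_give_zeros(self):
        cfg = superposed_config()
        assert np.allclose(backbone_distances(cfg), 0.0)
        assert np.allclose(sidechain_distances(cfg), 0.0)

    def test_rigid_translation_gives_constant_distances(self):
        cfg = superposed_config()
        cfg2 = Configuration(cfg.bb1, cfg.bb2 + [2.0, 0, 0], cfg.sc1,
                             cfg.sc2 + [2.0, 0, 0])
        assert np.allclose(backbone_distances(cfg2), 2.0)

    def test_matches_bruteforce_pairwise_oracle(self):
        geom = HelixPairGeometry(inter_axis_distance=1.0, noise_sd=0.02)
        cfg = make_helix_pair(geom, seed=5)
        expected = [float(np.sqrt(((cfg.bb1[i] - cfg.bb2[i]) ** 2).sum()))
                    for i in range(N_RESIDUES)]
        assert np.allclose(backbone_distances(cfg), expected)

    def test_glycine_uses_backbone_anchor(self):
        geom = HelixPairGeometry(inter_axis_distance=1.0, noise_sd=0.0)
        cfg = make_helix_pair(geom, seed=0)
        i = int(np.nonzero(cfg.residue_ids == 223)[0][0])
        gly = np.zeros(N_RESIDUES, dtype=bool)
        gly[i] = True
        cfg_gly = Configuration(cfg.bb1, cfg.bb2, cfg.sc1, cfg.sc2,
                                glycine_mask=gly)
        d = sidechain_distances(cfg_gly)
        assert d[i] == pytest.approx(backbone_distances(cfg)[i])
        j = i + 1
        assert d[j] == pytest.approx(sidechain_distances(cfg)[j])


class TestGlobalDescriptors:
    def test_tilt_anchors(self):
        geom = HelixPairGeometry(inter_axis_distance=4.0, noise_sd=0.0)
        cfg = make_helix_pair(geom)           # axes along +z
        _, t1, t2 = global_descriptors(cfg)
        # the principal axis of a finite helix with a non-integer number of
        # turns deviates from the geometric axis by a fraction of a degree
        assert t1 == pytest.approx(0.0, abs=0.01)
        # rotate helix axes onto x by swapping coordinates
        rot = cfg.bb1[:, [2, 1, 0]]
        cfg_x = Configuration(rot, cfg.bb2[:, [2, 1, 0]], rot, cfg.bb2[:, [2, 1, 0]])
        _, tx, _ = global_descriptors(cfg_x)
        assert tx == pytest.approx(np.pi / 2, abs=0.01)

    def test_superposed_com_distance_zero(self):
        com, _, _ = global_descriptors(superposed_config())
        assert com == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_helix_rejected(self):
        pts = np.zeros((N_RESIDUES, 3))
        cfg = Configuration(pts, pts + [1, 0, 0], pts, pts + [1, 0, 0])
        with pytest.raises(GeometryError):
            global_descriptors(cfg)


class TestFeaturize:
    @pytest.mark.parametrize("kind", ["parallel", "X", "Lambda", "separated"])
    def test_vector_width_and_range(self, kind):
        vec = featurize(make_archetypes(kind, 1, seed=0)[0])
        assert vec.shape == (N_DESCRIPTORS,)
        assert np.all(vec >= 0.0) and np.all(vec <= 1.0)

    def test_separated_archetype_switched_distances_small(self):
        vec = featurize(make_archetypes("separated", 1, seed=0, noise_sd=0.0)[0])
        assert np.all(vec[:75] < 0.05)   # all switched distances incl. com

    def test_superposed_helices_saturate(self):
        vec = featurize(superposed_config())
        assert np.allclose(vec[:75], 1.0)

    def test_rigid_motion_invariance(self, rng):
        cfg = make_archetypes("X", 1, seed=2, noise_sd=0.02)[0]
        ref = featurize(cfg)
        shifted = cfg.translated(rng.normal(0, 3.0, 3))
        rotated = cfg.rotated_z(rng.uniform(0, 2 * np.pi))
        assert np.allclose(featurize(shifted), ref, atol=1e-9)
        assert np.allclose(featurize(rotated), ref, atol=1e-9)

    def test_ordering_frozen(self):
        names = descriptor_names()
        assert len(names) == N_DESCRIPTORS
        assert names[0] == "bb_206" and names[36] == "bb_242"
        assert names[37] == "sc_206" and names[-3:] == ["com", "tilt1", "tilt2"]
        assert descriptor_ordering_hash() == descriptor_ordering_hash()


class TestStates:
    def test_contact_sum_anchors(self):
        assert contact_sum_sigma(superposed_config()) == pytest.approx(16.0)
        sep = make_archetypes("separated", 1, seed=0, noise_sd=0.0)[0]
        assert contact_sum_sigma(sep) < 0.01

    def test_contact_sum_bounded_by_16(self):
        for kind in ("parallel", "X", "Lambda"):
            for cfg in make_archetypes(kind, 5, seed=3):
                assert 0.0 <= contact_sum_sigma(cfg) <= 16.0

    def test_n_contacts_counts_constructed_pairs(self):
        cfg = line_config()
        assert n_contacts(cfg) == 0
        # move three sidechain tips into contact across the interface
        sc1 = cfg.sc1.copy()
        for i in (5, 15, 25):
            sc1[i] = cfg.sc2[i] - [0.1, 0.0, 0.0]
        cfg3 = Configuration(cfg.bb1, cfg.bb2, sc1, cfg.sc2)
        assert n_contacts(cfg3) == 3

    def test_superposed_exceeds_contact_threshold(self):
        cfg = superposed_config()
        assert n_contacts(cfg) > 25
        assert classify(cfg) == "dimerized"

    def test_separated_state(self):
        cfg = line_config(separation=1.5)
        assert min_interhelix_distance(cfg) == pytest.approx(1.5)
        assert n_contacts(cfg) == 0
        assert classify(cfg) == "separated"

    def test_sigma_criterion_alone_dimerizes(self):
        # 16 central sidechain pairs in contact, backbones far apart: NC stays
        # low but the contact function crosses its threshold
        cfg = line_config(separation=6.0)
        sc1 = cfg.sc1.copy()
        mask = (cfg.residue_ids >= 211) & (cfg.residue_ids <= 226)
        sc1[mask] = cfg.sc2[mask]
        cfg2 = Configuration(cfg.bb1, cfg.bb2, sc1, cfg.sc2)
        assert contact_sum_sigma(cfg2) == pytest.approx(16.0)
        assert n_contacts(cfg2) <= 25
        assert classify(cfg2) == "dimerized"

    def test_intermediate_between_criteria(self):
        cfg = make_archetypes("X", 1, seed=0, noise_sd=0.0)[0]
        assert classify(cfg) == "intermediate"

    def test_state_criteria_never_coincide_on_generated_configs(self, rng):
        # separated requires min distance > 1.4 nm; both dimerized criteria
        # require sub-nm contacts, so the two can never hold together
        for kind in ("parallel", "X", "Lambda", "separated"):
            for cfg in make_archetypes(kind, 5, seed=int(rng.integers(1e6))):
                classify(cfg)  # must not raise StateConsistencyError

    def test_residue_pair_matrix_shape_and_symmetry_of_equivalents(self):
        cfg = superposed_config()
        m = residue_pair_min_distances(cfg)
        assert m.shape == (37, 37)
        assert np.allclose(np.diag(m), 0.0)
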