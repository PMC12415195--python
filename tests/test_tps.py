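"""Two-way-shooting TPS engine: selection, shots, MC chains, accounting."""

import numpy as np
import pytest

from dimerpath.landscape import ToyLandscapeSpec, harvest_transition_paths
from dimerpath.network import CommittorNet
from dimerpath.tps import (MCChainState, ShootingResult, ToyDynamics,
                           committor_validation, expected_tp_series,
                           make_initial_tp, mc_step, run_tps,
                           select_shooting_point, selection_probability,
                           two_way_shot)


class _FieldModel:
    """Committor stand-in with a prescribed logit field over descriptors."""

    def __init__(self, fn):
        self.fn = fn

    def predict_logit(self, X):
        return self.fn(np.atleast_2d(X))

    def predict(self, X):
        return 1.0 / (1.0 + np.exp(-self.predict_logit(X)))


@pytest.fixture(scope="module")
def dynamics(default_spec):
    return ToyDynamics(default_spec)


@pytest.fixture(scope="module")
def initial_tp(default_spec, dynamics):
    tp = harvest_transition_paths(default_spec, 1, seed=31)[0]
    return make_initial_tp(tp, dynamics)


class TestSelection:
    def test_flat_committor_gives_uniform_selection(self, initial_tp, dynamics):
        model = CommittorNet(input_dim=2, seed=0)   # untrained: q = 0 everywhere
        n = len(initial_tp["selectable"])
        for fi in initial_tp["selectable"][:5]:
            assert selection_probability(initial_tp, fi, model, dynamics) \
                == pytest.approx(1.0 / n)

    def test_transition_state_frame_dominates(self, initial_tp, dynamics):
        # one frame with q = 0, all others |q| >= 3
        sel = initial_tp["selectable"]
        target = initial_tp["frames"][sel[len(sel) // 2]]

        def fn(X):
            pts = X * dynamics._span + dynamics._lo
            d = np.linalg.norm(pts - target, axis=1)
            return np.where(d < 1e-9, 0.0, 3.0)

        model = _FieldModel(fn)
        p = selection_probability(initial_tp, sel[len(sel) // 2], model, dynamics)
        assert p >= 0.9

    def test_fixed_seed_selects_same_frame(self, initial_tp, dynamics):
        model = CommittorNet(input_dim=2, seed=0)
        i1, w1, p1 = select_shooting_point(initial_tp, model, dynamics,
                                           np.random.default_rng(5))
        i2, w2, p2 = select_shooting_point(initial_tp, model, dynamics,
                                           np.random.default_rng(5))
        assert (i1, w1, p1) == (i2, w2, p2)


class TestTwoWayShot:
    def test_fixed_seed_reproducible(self, dynamics):
        pt = np.array([0.0, 0.5])
        a, _ = two_way_shot(pt, dynamics, seed=17)
        b, _ = two_way_shot(pt, dynamics, seed=17)
        assert (a.outcome_1, a.outcome_2, a.is_tp) == (b.outcome_1, b.outcome_2, b.is_tp)

    def test_shot_from_state_rejected(self, dynamics):
        with pytest.raises(ValueError):
            two_way_shot(np.array([-1.2, 0.0]), dynamics, seed=1)

    def test_reactant_adjacent_point_rarely_makes_tp(self, dynamics):
        # oracle pB < 0.01 here; a TP needs one trial to reach B
        pt = np.array([-0.85, 0.0])
        n_tp = 0
        for s in range(40):
            res, _ = two_way_shot(pt, dynamics, seed=1000 + s)
            n_tp += res.is_tp
        assert n_tp <= 2

    def test_tp_assembled_from_a_to_b(self, dynamics):
        pt = np.array([0.0, 0.5])
        for s in range(60):
            res, tp = two_way_shot(pt, dynamics, seed=2000 + s)
            if tp is not None:
                assert dynamics.classify(tp["frames"][0]) == 1
                assert dynamics.classify(tp["frames"][-1]) == tp["terminal_state"]
                assert tp["terminal_state"] >= 2
                # the shooting point is on the path
                d = np.linalg.norm(tp["frames"] - pt, axis=1)
                assert d.min() < 1e-12
                break
        else:
            pytest.fail("no transition path generated in 60 shots at the saddle")

    def test_outcome_counts_match_flag(self, dynamics):
        res, tp = two_way_shot(np.array([0.0, 0.5]), dynamics, seed=3)
        assert res.is_tp == (res.n_a == 1 and res.n_b == 1)
        assert (tp is not None) == res.is_tp


class TestMCStep:
    def test_rejected_step_keeps_current_path(self, dynamics, initial_tp):
        model = CommittorNet(input_dim=2, seed=0)
        rng = np.random.default_rng(0)
        chain = MCChainState(chain_id=0, current_tp=dict(initial_tp))
        chain.record_acceptance(chain.current_tp, mc_step=-1)
        before = chain.current_tp
        # iterate until a step produces no TP: state must be unchanged
        for step in range(1, 50):
            res = mc_step(chain, model, dynamics, rng, step)
            if not res.is_tp and chain.current_tp is before:
                break
        assert chain.step_counter >= 1

    def test_run_deterministic_under_seed(self, dynamics, initial_tp):
        kw = dict(n_steps=4, n_chains=3, train_model=False)
        a = run_tps(dynamics, [initial_tp], seed=42, **kw)
        b = run_tps(dynamics, [initial_tp], seed=42, **kw)
        assert np.array_equal(a.n_generated_series, b.n_generated_series)
        assert np.array_equal(a.n_expected_series, b.n_expected_series)
        assert [r.outcome_1 for r in a.results] == [r.outcome_1 for r in b.results]

    def test_zero_steps_returns_initial_state_only(self, dynamics, initial_tp):
        run = run_tps(dynamics, [initial_tp], n_steps=0, seed=1, n_chains=2)
        assert len(run.results) == 0
        assert all(ch.accepted == 1 for ch in run.chains)

    def test_no_initial_tp_is_configuration_error(self, dynamics):
        with pytest.raises(ValueError):
            run_tps(dynamics, [], n_steps=1, seed=0)

    def test_accounting_invariants(self, toy_pipeline):
        run, _, _ = toy_pipeline
        assert run.n_generated == sum(r.is_tp for r in run.results)
        assert run.n_generated_series[-1] == run.n_generated
        assert np.all(np.diff(run.n_expected_series) >= 0)
        assert len(run.n_expected_series) == len(run.results)
        for ch in run.chains:
            assert ch.switches <= ch.accepted - 1


class TestExpectedSeries:
    def test_expected_increment_is_2p1mp(self):
        results = [ShootingResult(point=np.zeros(2), descriptor=np.zeros(2),
                                  p_pred=p, selection_weight=0.1, outcome_1=1,
                                  outcome_2=2, is_tp=True, n_a=1, n_b=1)
                   for p in (0.0, 0.5, 0.5)]
        series = expected_tp_series(results)
        assert np.allclose(series, [0.0, 0.5, 1.0])


class TestValidationShots:
    def test_committed_config_samples_one(self, dynamics):
        res = committor_validation(dynamics, [(1.2, 0.0)], 20, seed=1)
        assert res["sampled"][0] == 1.0

    def test_ci_width_shrinks_with_sqrt_n(self, dynamics):
        pt = [(0.0, 0.5)]
        r20 = committor_validation(dynamics, pt, 20, seed=2)
        r80 = committor_validation(dynamics, pt, 80, seed=3)
        w20 = r20["ci_high"][0] - r20["ci_low"][0]
        w80 = r80["ci_high"][0] - r80["ci_low"][0]
        assert 0.35 <= w80 / w20 <= 0.7    # ~1/2 expected

    def test_model_predictions_attached(self, dynamics):
        model = CommittorNet(input_dim=2, seed=0)
        res = committor_validation(dynamics, [(0.0, 0.5)], 20, seed=4,
                                   model=model)
        assert res["predicted"][0] == pytest.approx(0.5)

    def test_calibration_after_training(self, toy_pipeline, dynamics):
        """Predicted vs sampled pB falls on the diagonal within CI for >= 90%
        of validation configurations (trained-model calibration)."""
        run, model, dyn = toy_pipeline
        val = run.validation
        pred = model.predict(dyn.featurize(val["points"]))
        inside = np.mean((pred >= val["ci_low"] - 0.02)
                         & (pred <= val["ci_high"] + 0.02))
        assert inside >= 0.9
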