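"""Two-way-shooting transition path sampling with committor-guided selection.

In each Monte Carlo step a shooting point (SP) is drawn from the current
transition path with weight w(x) proportional to exp(-q(x)^2), where q is the
committor-model logit -- concentrating shots near the current estimate of the
transition state ensemble.  Two trial trajectories are launched from the SP
with independent noise streams; a new transition path is generated whenever
the two trials end in different states, and is accepted with the detailed
balance ratio

    acc = min{1, p_sel(x_sp | new path) / p_sel(x_sp | old path)}

which corrects for the biased SP selection.  All shooting results, accepted
or not, are recorded and feed the on-the-fly training of the committor model.

The engine is dynamics-agnostic: anything implementing the small
``DynamicsBackend`` surface (shoot / classify / featurize) can be plugged in.
The in-package backend is the 2D toy landscape; an atomistic backend would
implement the same three methods on top of an MD engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import landscape as ls
from .network import CommittorNet, TrainingSchedule, train, effective_lr
from .stats import binomial_ci

__all__ = ["ToyDynamics", "ShootingResult", "MCChainState", "TPSRun",
           "select_shooting_point", "two_way_shot", "mc_step", "run_tps",
           "expected_tp_series", "committor_validation", "make_initial_tp"]

_Q_CLIP = 18.0  # |q| beyond this has selection weight exp(-324) ~ 0


class ToyDynamics:
    """Dynamics backend for the 2D toy landscape.

    ``max_trial_steps`` caps each trial trajectory (a trial hitting the cap
    has outcome "none": kept for the record, excluded from TP assembly and
    from the binomial counts).  The default cap of 400k steps is two to three
    orders of magnitude above the typical commitment time on the default
    landscape, so unresolved trials are rare.
    """

    def __init__(self, spec: ls.ToyLandscapeSpec, max_trial_steps: int = 400_000,
                 stride: int = 10):
        self.spec = spec
        self.max_trial_steps = int(max_trial_steps)
        self.stride = int(stride)
        xmin, xmax, ymin, ymax = spec.bounds
        self._lo = np.array([xmin, ymin])
        self._span = np.array([xmax - xmin, ymax - ymin])
        self.input_dim = 2

    def shoot(self, point, seed: int) -> ls.TrajectorySegment:
        return ls.propagate(self.spec, point, self.max_trial_steps, seed,
                            stop_on_state=True, stride=self.stride)

    def classify(self, point) -> int:
        return ls.classify_point(self.spec, point)

    def classify_batch(self, frames: np.ndarray) -> np.ndarray:
        p = self.spec.params()
        r2 = p[29] ** 2
        centers = np.array([[p[0], p[1]], [p[4], p[5]], [p[8], p[9]], [p[12], p[13]]])
        codes = np.array([1, 2, 3, 4])
        d2 = ((frames[:, None, :] - centers[None, :, :]) ** 2).sum(axis=-1)
        inside = d2 < r2
        out = np.zeros(len(frames), dtype=int)
        any_in = inside.any(axis=1)
        out[any_in] = codes[inside.argmax(axis=1)[any_in]]
        return out

    def featurize(self, points) -> np.ndarray:
        """Map toy coordinates to [0,1]^2 descriptors (normalized x, y)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self._lo) / self._span


@dataclass
class ShootingResult:
    """Record of one two-way shooting move."""

    point: np.ndarray
    descriptor: np.ndarray
    p_pred: float                 # model pB at selection time
    selection_weight: float       # normalized SP selection probability
    outcome_1: int                # state codes (0 = unresolved)
    outcome_2: int
    is_tp: bool
    n_a: int
    n_b: int
    mc_step: int = -1
    chain_id: int = -1

    @property
    def p_tp_pred(self) -> float:
        return 2.0 * self.p_pred * (1.0 - self.p_pred)


@dataclass
class MCChainState:
    chain_id: int
    current_tp: dict              # frames, terminal_state, channel, selectable
    step_counter: int = 0
    accepted: int = 0
    switches: int = 0
    history: list = field(default_factory=list)   # accepted-TP records

    def record_acceptance(self, tp: dict, mc_step: int):
        if self.history and self.history[-1]["terminal_state"] != tp["terminal_state"]:
            self.switches += 1
        self.accepted += 1
        self.history.append({"mc_step": mc_step,
                             "terminal_state": tp["terminal_state"],
                             "channel": tp["channel"]})
        self.current_tp = tp


@dataclass
class TPSRun:
    chains: list
    results: list
    n_generated_series: np.ndarray
    n_expected_series: np.ndarray
    model: CommittorNet
    seed: int
    transition_paths: list        # accepted TPs in order of acceptance
    meta_results: list | None = None   # incl. preliminary-phase shots (pipeline)
    validation: dict | None = None     # validation-shot record (pipeline)

    @property
    def n_generated(self) -> int:
        return sum(r.is_tp for r in self.results)


def _wrap_tp(frames: np.ndarray, terminal_state: int, dynamics) -> dict:
    states = dynamics.classify_batch(frames)
    selectable = np.nonzero(states == 0)[0]
    return {"frames": np.asarray(frames, dtype=float),
            "terminal_state": int(terminal_state),
            "channel": ls.channel_label(frames),
            "selectable": selectable}


def make_initial_tp(tp_dict: dict, dynamics) -> dict:
    """Adapt a harvested transition path (from direct simulation) for TPS."""
    return _wrap_tp(tp_dict["frames"], tp_dict["terminal_state"], dynamics)


def select_shooting_point(tp: dict, model: CommittorNet, dynamics,
                          rng: np.random.Generator):
    """Draw an SP from a path with weight w = exp(-q^2) over intermediate frames.

    Returns (frame index, normalized selection weight, predicted pB).
    """
    idx = tp["selectable"]
    if len(idx) == 0:
        raise ValueError("transition path has no intermediate frames")
    feats = dynamics.featurize(tp["frames"][idx])
    q = np.clip(model.predict_logit(feats), -_Q_CLIP, _Q_CLIP)
    w = np.exp(-q * q)
    tot = w.sum()
    if tot <= 0 or not np.isfinite(tot):
        warnings.warn("all selection weights vanished; falling back to uniform")
        w = np.ones_like(w)
        tot = w.sum()
    w = w / tot
    j = rng.choice(len(idx), p=w)
    p_pred = float(1.0 / (1.0 + np.exp(np.clip(-q[j], -50, 50))))
    return int(idx[j]), float(w[j]), p_pred


def selection_probability(tp: dict, frame_index: int, model: CommittorNet,
                          dynamics) -> float:
    """Normalized selection weight of one frame on a path (for acceptance)."""
    idx = tp["selectable"]
    pos = np.nonzero(idx == frame_index)[0]
    if len(pos) == 0:
        return 0.0
    feats = dynamics.featurize(tp["frames"][idx])
    q = np.clip(model.predict_logit(feats), -_Q_CLIP, _Q_CLIP)
    w = np.exp(-q * q)
    tot = w.sum()
    if tot <= 0:
        return 1.0 / len(idx)
    return float(w[pos[0]] / tot)


def two_way_shot(point, dynamics, seed: int, model: CommittorNet | None = None,
                 p_pred: float = np.nan, selection_weight: float = np.nan
                 ) -> tuple[ShootingResult, dict | None]:
    """Launch two trial trajectories from ``point`` with independent noise.

    Returns the shooting record and, if the trials ended in different states
    (one in A, one in B), the assembled transition path (A-trial reversed +
    B-trial) as a dict; otherwise None.
    """
    point = np.asarray(point, dtype=float)
    if dynamics.classify(point) != 0:
        raise ValueError("shooting point must be an intermediate configuration")
    rng = np.random.default_rng(seed)
    s1, s2 = (int(s) for s in rng.integers(0, 2**31, size=2))
    t1 = dynamics.shoot(point, s1)
    t2 = dynamics.shoot(point, s2)
    o1, o2 = t1.terminal_state, t2.terminal_state
    n_a = int(o1 == 1) + int(o2 == 1)
    n_b = int(o1 >= 2) + int(o2 >= 2)
    is_tp = n_a == 1 and n_b == 1
    if model is not None and np.isnan(p_pred):
        p_pred = float(model.predict(dynamics.featurize(point))[0])
    result = ShootingResult(point=point,
                            descriptor=dynamics.featurize(point)[0],
                            p_pred=float(p_pred),
                            selection_weight=float(selection_weight),
                            outcome_1=o1, outcome_2=o2, is_tp=is_tp,
                            n_a=n_a, n_b=n_b)
    tp = None
    if is_tp:
        ta, tb = (t1, t2) if o1 == 1 else (t2, t1)
        frames = np.vstack([ta.frames[::-1], tb.frames[1:]])
        tp = _wrap_tp(frames, tb.terminal_state, dynamics)
    return result, tp


def mc_step(chain: MCChainState, model: CommittorNet, dynamics,
            rng: np.random.Generator, mc_step_index: int) -> ShootingResult:
    """Advance one chain by one TPS Monte Carlo step."""
    tp_old = chain.current_tp
    idx, w_old, p_pred = select_shooting_point(tp_old, model, dynamics, rng)
    sp = tp_old["frames"][idx]
    result, tp_new = two_way_shot(sp, dynamics, int(rng.integers(0, 2**31)),
                                  p_pred=p_pred, selection_weight=w_old)
    result.mc_step = mc_step_index
    result.chain_id = chain.chain_id
    if tp_new is not None:
        # the SP sits at the junction of the reversed A-trial and the B-trial
        j = int(np.argmin(np.linalg.norm(tp_new["frames"] - sp, axis=1)))
        w_new = selection_probability(tp_new, j, model, dynamics)
        ratio = w_new / w_old if w_old > 0 else 1.0
        if rng.random() < min(1.0, ratio):
            chain.record_acceptance(tp_new, mc_step_index)
    chain.step_counter += 1
    return result


def _window_stats(results: list, window: int) -> tuple[float, float]:
    tail = results[-window:]
    n_gen = float(sum(r.is_tp for r in tail))
    n_pred = float(sum(r.p_tp_pred for r in tail))
    return n_gen, n_pred


def run_tps(dynamics, initial_tps: list, n_steps: int, seed: int,
            model: CommittorNet | None = None, n_chains: int = 15,
            schedule: TrainingSchedule | None = None,
            train_model: bool = True) -> TPSRun:
    """Run TPS in ``n_chains`` parallel MC chains for ``n_steps`` sweeps.

    Each sweep advances every chain by one MC step; the global MC step count
    therefore grows by ``n_chains`` per sweep.  The committor model is shared
    across chains and trained on the pooled shooting results per the
    schedule.  Fully deterministic given ``seed``.
    """
    if not initial_tps:
        raise ValueError("at least one initial transition path is required")
    if schedule is None:
        schedule = TrainingSchedule()
    root = np.random.SeedSequence(seed)
    chain_seeds, train_seed_seq = root.spawn(2)
    chain_rngs = [np.random.default_rng(s) for s in chain_seeds.spawn(n_chains)]
    train_rng = np.random.default_rng(train_seed_seq)
    if model is None:
        model = CommittorNet(input_dim=dynamics.input_dim,
                             seed=int(train_rng.integers(0, 2**31)))
    chains = [MCChainState(chain_id=i,
                           current_tp=dict(initial_tps[i % len(initial_tps)]))
              for i in range(n_chains)]
    for ch in chains:
        ch.record_acceptance(ch.current_tp, mc_step=-1)

    results: list[ShootingResult] = []
    accepted_tps: list[dict] = []
    gen_series = []
    exp_series = []
    mc_index = 0
    for _ in range(n_steps):
        for ci, chain in enumerate(chains):
            mc_index += 1
            before = chain.accepted
            res = mc_step(chain, model, dynamics, chain_rngs[ci], mc_index)
            results.append(res)
            if chain.accepted > before:
                accepted_tps.append(chain.current_tp)
            gen_series.append(res.is_tp)
            exp_series.append(res.p_tp_pred)
            if train_model and mc_index % schedule.train_every == 0:
                n_gen, n_pred = _window_stats(results, schedule.window)
                lr = (schedule.base_lr if n_pred == 0
                      else effective_lr(n_gen, n_pred, schedule.base_lr))
                if lr >= schedule.lr_floor:
                    X = np.array([r.descriptor for r in results])
                    n_a = np.array([r.n_a for r in results])
                    n_b = np.array([r.n_b for r in results])
                    keep = (n_a + n_b) > 0
                    if keep.any():
                        train(model, X[keep], n_a[keep], n_b[keep], lr=lr,
                              epochs=schedule.epochs,
                              batch_size=schedule.batch_size,
                              seed=int(train_rng.integers(0, 2**31)))
    return TPSRun(chains=chains, results=results,
                  n_generated_series=np.cumsum(np.asarray(gen_series, dtype=float)),
                  n_expected_series=np.cumsum(np.asarray(exp_series, dtype=float)),
                  model=model, seed=seed, transition_paths=accepted_tps)


def expected_tp_series(results: list, model: CommittorNet | None = None,
                       dynamics=None) -> np.ndarray:
    """Cumulative expected TP count, sum of 2 p (1-p) per shooting point.

    With ``model`` given, predictions are recomputed with that (e.g. final)
    model; otherwise the predictions recorded at selection time are used,
    which is the on-the-fly diagnostic.
    """
    if model is None:
        p = np.array([r.p_pred for r in results])
    else:
        X = np.array([r.descriptor for r in results])
        p = model.predict(X)
    return np.cumsum(2.0 * p * (1.0 - p))


def committor_validation(dynamics, configs, shots_per_config: int, seed: int,
                         model: CommittorNet | None = None,
                         max_steps: int | None = None) -> dict:
    """One-way validation committor shots from a list of configurations.

    Returns sampled pB with 95% binomial CIs, paired with model predictions
    when a model is given (for calibration plots).
    """
    if shots_per_config < 1:
        raise ValueError("need at least one shot per configuration")
    pts = np.atleast_2d(np.asarray(configs, dtype=float))
    # configurations already inside a state commit trivially (pB exactly 0 or 1)
    res = ls.brute_force_committor(dynamics.spec, pts, shots_per_config, seed,
                                   max_steps=max_steps or dynamics.max_trial_steps)
    out = {"points": pts, "sampled": res["estimate"],
           "ci_low": res["ci_low"], "ci_high": res["ci_high"],
           "n_unresolved": res["n_unresolved"]}
    if model is not None:
        out["predicted"] = model.predict(dynamics.featurize(pts))
    return out
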