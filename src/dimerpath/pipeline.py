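"""End-to-end committor-learning pipeline on the toy landscape.

The pipeline mirrors a production path-sampling study:

1. harvest a handful of initial transition paths from direct simulation;
2. a preliminary round of two-way shots with *uniform* shooting-point
   selection along the initial paths (broad coverage before a model exists);
3. committor-guided TPS in parallel MC chains with on-the-fly training;
4. retrain-and-select: several fresh analysis models are trained on the
   pooled shooting results and the one agreeing best with independent
   validation committor shots (stratified across the predicted-pB range) is
   selected.  The selected analysis model, not the on-the-fly one, feeds the
   downstream ensemble analysis.
"""

from __future__ import annotations

import numpy as np

from . import landscape as ls
from .network import CommittorNet, TrainingSchedule, train
from .tps import (ToyDynamics, make_initial_tp, run_tps, two_way_shot,
                  committor_validation, TPSRun)

__all__ = ["learn_toy_committor", "transition_region_grid", "results_to_arrays",
           "preliminary_shots", "select_analysis_model", "committor_grid_rmse",
           "chain_occupancy"]


def results_to_arrays(results: list):
    """Stack shooting results into (X, n_a, n_b), dropping fully unresolved ones."""
    X = np.array([r.descriptor for r in results])
    n_a = np.array([r.n_a for r in results])
    n_b = np.array([r.n_b for r in results])
    keep = (n_a + n_b) > 0
    return X[keep], n_a[keep], n_b[keep]


def preliminary_shots(dynamics: ToyDynamics, initial_tps: list, n_shots: int,
                      seed: int) -> list:
    """Uniform-selection two-way shots along the initial paths.

    Before any committor model exists there is nothing to bias the
    shooting-point choice with; these shots give the training set broad
    coverage of the whole path, including the near-state regions that
    model-guided selection later avoids.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_shots):
        tp = initial_tps[i % len(initial_tps)]
        sel = tp["selectable"]
        idx = sel[rng.integers(0, len(sel))]
        res, _ = two_way_shot(tp["frames"][idx], dynamics,
                              int(rng.integers(0, 2**31)))
        res.mc_step = -1
        out.append(res)
    return out


def select_analysis_model(results: list, dynamics: ToyDynamics, seed: int,
                          reference_model: CommittorNet | None = None,
                          k_models: int = 5, epochs: int = 250,
                          batch_size: int = 256,
                          n_validation_points: int = 20,
                          validation_shots: int = 40):
    """Retrain-and-select over ``k_models`` candidate committor models.

    Each candidate is trained from a fresh initialization on all pooled
    shooting results; selection minimizes the RMSE between predicted and
    sampled pB on independent validation committor shots, launched from
    shooting points stratified across the predicted-pB range (so calibration
    is probed over the whole transition, not only near pB = 0.5).

    Returns (best model, validation dict).
    """
    X, n_a, n_b = results_to_arrays(results)
    root = np.random.SeedSequence(seed)
    s_pick, s_shots, s_train = (int(s.generate_state(1)[0] % 2**31)
                                for s in root.spawn(3))
    usable = [r for r in results if r.n_a + r.n_b > 0]
    ref = reference_model
    p_ref = (ref.predict(X) if ref is not None
             else np.full(len(X), 0.5))
    rng = np.random.default_rng(s_pick)
    n_bins = max(1, n_validation_points // 2)
    picks = []
    for lo in np.linspace(0.0, 1.0, n_bins, endpoint=False):
        band = np.nonzero((p_ref >= lo) & (p_ref < lo + 1.0 / n_bins))[0]
        if len(band):
            take = min(max(1, n_validation_points // n_bins), len(band))
            picks.extend(rng.choice(band, size=take, replace=False))
    pts_val = np.array([usable[i].point for i in picks])
    valres = committor_validation(dynamics, pts_val, validation_shots, s_shots)

    best, best_score = None, np.inf
    scores = []
    for i in range(k_models):
        m = CommittorNet(input_dim=dynamics.input_dim, seed=s_train + 101 * i)
        train(m, X, n_a, n_b, lr=1e-3, epochs=epochs, batch_size=batch_size,
              seed=s_train + 211 * i)
        pred = m.predict(dynamics.featurize(pts_val))
        score = float(np.sqrt(np.mean((pred - valres["sampled"]) ** 2)))
        scores.append(score)
        if score < best_score:
            best, best_score = m, score
    valres["model_scores"] = scores
    valres["selected_score"] = best_score
    return best, valres


def learn_toy_committor(spec: ls.ToyLandscapeSpec | None = None, seed: int = 0,
                        n_chains: int = 15, n_steps: int = 300,
                        n_initial_tps: int = 5, n_preliminary: int = 300,
                        k_models: int = 5, post_epochs: int = 250,
                        schedule: TrainingSchedule | None = None
                        ) -> tuple[TPSRun, CommittorNet, ToyDynamics]:
    """Full pipeline: initial TPs -> preliminary shots -> guided TPS ->
    retrain-and-select analysis model.

    Returns (tps_run, analysis_model, dynamics); deterministic given ``seed``.
    The preliminary shooting results are pooled with the TPS results for
    training (``run.results`` holds only the TPS-phase records; the combined
    list is stored as ``run.meta_results``).
    """
    spec = spec or ls.ToyLandscapeSpec()
    dynamics = ToyDynamics(spec)
    root = np.random.SeedSequence(seed)
    s_harvest, s_pre, s_tps, s_post = (int(s.generate_state(1)[0] % (2**31))
                                       for s in root.spawn(4))
    harvested = ls.harvest_transition_paths(spec, n_initial_tps, s_harvest)
    if not harvested:
        raise RuntimeError("no initial transition paths found by direct simulation")
    initial = [make_initial_tp(t, dynamics) for t in harvested]
    pre = preliminary_shots(dynamics, initial, n_preliminary, s_pre)
    run = run_tps(dynamics, initial, n_steps, s_tps, n_chains=n_chains,
                  schedule=schedule)
    combined = pre + run.results
    model, valres = select_analysis_model(combined, dynamics, s_post,
                                          reference_model=run.model,
                                          k_models=k_models, epochs=post_epochs)
    run.meta_results = combined
    run.validation = valres
    return run, model, dynamics


def transition_region_grid(spec: ls.ToyLandscapeSpec, n: int = 15,
                           margin: float = 0.25, extra_kt: float = 1.0
                           ) -> np.ndarray:
    """Grid points covering the transition region between the A and B states.

    The grid spans the rectangle between the state boundaries; points inside a
    state region or thermally inaccessible ones (potential above the higher
    channel saddle plus ``extra_kt``) are dropped -- the retained points are
    the support of the shooting-point distribution, which is where a
    committor model is meaningful.
    """
    (ax, _), _, _ = spec.well_a
    bx = spec.wells_b[0][0][0]
    ys = [w[0][1] for w in spec.wells_b] + [spec.channel_upper[0],
                                            spec.channel_lower[0]]
    x_lo = ax + spec.state_radius + margin
    x_hi = bx - spec.state_radius - margin
    y_lo = min(ys) - 0.5
    y_hi = max(ys) + 0.5
    xs = np.linspace(x_lo, x_hi, n)
    yv = np.linspace(y_lo, y_hi, n)
    v_saddle = max(ls.potential_energy(spec, (0.0, spec.channel_upper[0])),
                   ls.potential_energy(spec, (0.0, spec.channel_lower[0])))
    pts = []
    for x in xs:
        for y in yv:
            p = (x, y)
            if ls.classify_point(spec, p) != 0:
                continue
            if ls.potential_energy(spec, p) <= v_saddle + extra_kt:
                pts.append(p)
    return np.asarray(pts)


def committor_grid_rmse(model: CommittorNet, dynamics: ToyDynamics,
                        oracle: dict) -> float:
    """RMSE between model predictions and a brute-force committor result."""
    pred = model.predict(dynamics.featurize(oracle["points"]))
    ok = np.isfinite(oracle["estimate"])
    return float(np.sqrt(np.mean((pred[ok] - oracle["estimate"][ok]) ** 2)))


def chain_occupancy(run: TPSRun) -> dict:
    """Per-MC-step occupancy of the chains' current transition paths.

    The TPS estimator weights each chain's current path at every MC step
    (rejected moves repeat the old path), so ensemble populations are counted
    over the per-step occupancy, not only over newly accepted paths.  Returns
    channel and terminal-basin occupancy counts.
    """
    from collections import Counter
    channels: Counter = Counter()
    basins: Counter = Counter()
    n_chains = len(run.chains)
    for ci, chain in enumerate(run.chains):
        hist = chain.history              # sorted by global mc_step
        j = 0
        for sweep in range(chain.step_counter):
            t = sweep * n_chains + ci + 1  # global mc index of this chain step
            while j + 1 < len(hist) and hist[j + 1]["mc_step"] <= t:
                j += 1
            channels[hist[j]["channel"]] += 1
            basins[hist[j]["terminal_state"]] += 1
    return {"channels": dict(channels), "basins": dict(basins)}
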