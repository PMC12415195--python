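"""Two-dimensional multi-channel model landscape with Brownian dynamics.

This module provides the synthetic dynamical system used to exercise the
path-sampling machinery on a problem with computable ground truth.  The
landscape has one reactant basin A on the left, three product basins B1, B2,
B3 on the right, and a central barrier ridge pierced by two channels (an
upper and a lower saddle), so that transition paths split into two distinct
reaction channels and three distinct product states -- a low-dimensional
analog of a helix-pair association with competing association pathways and
multiple bound geometries.

Dynamics are overdamped Langevin (Euler--Maruyama):

    x_{n+1} = x_n - (dt / gamma) * grad V(x_n) + sqrt(2 kT dt / gamma) * xi_n

with xi_n standard normal.  The committor of any point can be estimated by
brute force, which serves as the oracle for everything trained on top.

State encoding used throughout: 0 = no state, 1 = A, 2/3/4 = B1/B2/B3.

Flat parameter layout consumed by the numba kernels::

    0..3    A well: cx, cy, depth, width
    4..15   B wells (3 x 4, same layout)
    16      barrier ridge height
    17      barrier ridge x-width
    18..20  upper channel: y_center, gap_depth, gap_width
    21..23  lower channel: y_center, gap_depth, gap_width
    24      quadratic confinement coefficient
    25..28  domain bounds xmin, xmax, ymin, ymax
    29      state radius
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from numba import njit

from .stats import binomial_ci

__all__ = [
    "ToyLandscapeSpec",
    "TrajectorySegment",
    "DomainError",
    "IntegrationError",
    "potential_energy",
    "potential_gradient",
    "classify_point",
    "propagate",
    "brute_force_committor",
    "channel_label",
    "harvest_transition_paths",
    "STATE_NONE",
    "STATE_A",
    "STATE_B1",
    "STATE_NAMES",
]

STATE_NONE = 0
STATE_A = 1
STATE_B1 = 2  # B2 = 3, B3 = 4

STATE_NAMES = {0: None, 1: "A", 2: "B1", 3: "B2", 4: "B3"}


class DomainError(ValueError):
    """Point outside the landscape domain."""


class IntegrationError(RuntimeError):
    """Non-finite coordinate encountered during propagation."""


@dataclass(frozen=True)
class ToyLandscapeSpec:
    """Parameters of the default four-well, two-channel landscape.

    Wells are inverted Gaussians on a weak quadratic confining background;
    the barrier is a Gaussian ridge along x = 0 whose height is lowered at
    two channel locations.  The upper channel gap is deeper by default, so the
    two reaction channels carry asymmetric statistical weight -- controllable
    ground truth for channel-population tests.  Energies are in units of kT
    at ``temperature=1``.
    """

    well_a: tuple = ((-1.2, 0.0), 4.0, 0.35)          # (center, depth, width)
    wells_b: tuple = (
        ((1.2, 0.9), 4.0, 0.30),
        ((1.2, 0.0), 4.0, 0.30),
        ((1.2, -0.9), 4.0, 0.30),
    )
    barrier_height: float = 6.0
    barrier_width: float = 0.25
    # (y_center, gap_depth, gap_width); deeper gap = lower saddle barrier.
    # The two channels overlap enough that path sampling can switch between
    # them (the sampled system's transition channels are similarly connected);
    # fully disconnected channels would freeze each MC chain in one channel.
    channel_upper: tuple = (0.5, 4.8, 0.40)
    channel_lower: tuple = (-0.5, 4.2, 0.40)
    confinement: float = 0.5
    temperature: float = 1.0
    friction: float = 1.0
    timestep: float = 5.0e-4
    bounds: tuple = (-3.0, 3.0, -3.0, 3.0)
    state_radius: float = 0.30

    def __post_init__(self):
        for (_, depth, width) in (self.well_a, *self.wells_b):
            if depth <= 0 or width <= 0:
                raise ValueError("well depths and widths must be positive")
        if self.temperature < 0 or self.friction <= 0 or self.timestep <= 0:
            raise ValueError("invalid dynamics parameters")
        centers = [np.asarray(self.well_a[0])] + [np.asarray(w[0]) for w in self.wells_b]
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                if np.linalg.norm(centers[i] - centers[j]) <= 2 * self.state_radius:
                    raise ValueError("state regions must be pairwise disjoint")

    def params(self) -> np.ndarray:
        """Flat float64 parameter vector for the numba kernels."""
        (ax, ay), da, wa = self.well_a
        flat = [ax, ay, da, wa]
        for (cx, cy), d, w in self.wells_b:
            flat += [cx, cy, d, w]
        flat += [self.barrier_height, self.barrier_width]
        flat += list(self.channel_upper) + list(self.channel_lower)
        flat += [self.confinement]
        flat += list(self.bounds)
        flat += [self.state_radius]
        return np.asarray(flat, dtype=np.float64)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ToyLandscapeSpec":
        def tup(x):
            return tuple(tup(v) for v in x) if isinstance(x, (list, tuple)) else x
        return cls(**{k: tup(v) for k, v in d.items()})


@dataclass
class TrajectorySegment:
    """An ordered sequence of 2D frames produced by :func:`propagate`."""

    frames: np.ndarray          # (n, 2)
    timestep: float
    stride: int
    seed: int
    terminal_state: int         # STATE_* code of the last frame (0 if none)
    n_steps: int                # raw integrator steps taken

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 2 or self.frames.shape[0] < 1:
            raise ValueError("a trajectory needs at least one frame")

    @property
    def terminal_label(self):
        return STATE_NAMES[int(self.terminal_state)]


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _potential_and_gradient(p, x, y):
    conf = p[24]
    v = conf * (x * x + y * y)
    gx = 2.0 * conf * x
    gy = 2.0 * conf * y
    # four inverted Gaussian wells: A then B1..B3
    for k in range(4):
        o = 4 * k
        cx = p[o]; cy = p[o + 1]; d = p[o + 2]; w = p[o + 3]
        dx = x - cx; dy = y - cy
        e = d * np.exp(-(dx * dx + dy * dy) / (2.0 * w * w))
        v -= e
        gx += e * dx / (w * w)
        gy += e * dy / (w * w)
    # ridge height profile h(y) with two channel gaps
    hh = p[16]
    dhy = 0.0
    for c in range(2):
        o = 18 + 3 * c
        yc = p[o]; gd = p[o + 1]; gw = p[o + 2]
        dy = y - yc
        e = gd * np.exp(-dy * dy / (2.0 * gw * gw))
        hh -= e
        dhy += e * dy / (gw * gw)
    bw = p[17]
    ex = np.exp(-x * x / (2.0 * bw * bw))
    v += hh * ex
    gx += hh * ex * (-x / (bw * bw))
    gy += dhy * ex
    return v, gx, gy


@njit(cache=True)
def _state(p, x, y):
    r = p[29]
    dx = x - p[0]; dy = y - p[1]
    if dx * dx + dy * dy < r * r:
        return 1
    for k in range(3):
        o = 4 + 4 * k
        dx = x - p[o]; dy = y - p[o + 1]
        if dx * dx + dy * dy < r * r:
            return 2 + k
    return 0


@njit(cache=True)
def _reflect(v, lo, hi):
    # reflecting boundary; the confinement makes double reflections impossible
    if v < lo:
        return 2.0 * lo - v
    if v > hi:
        return 2.0 * hi - v
    return v


@njit(cache=True)
def _propagate_kernel(p, x0, y0, max_steps, dt, kT, gamma, seed, stop_on_state, stride):
    np.random.seed(seed)
    cap = max_steps // stride + 2
    out = np.empty((cap, 2), dtype=np.float64)
    out[0, 0] = x0
    out[0, 1] = y0
    n_rec = 1
    x = x0
    y = y0
    pref = dt / gamma
    noise = np.sqrt(2.0 * kT * dt / gamma)
    term = _state(p, x, y)
    if stop_on_state and term != 0:
        return out[:1], 0, term, -1
    for step in range(1, max_steps + 1):
        _, gx, gy = _potential_and_gradient(p, x, y)
        x = x - pref * gx + noise * np.random.normal()
        y = y - pref * gy + noise * np.random.normal()
        x = _reflect(x, p[25], p[26])
        y = _reflect(y, p[27], p[28])
        if not (np.isfinite(x) and np.isfinite(y)):
            return out[:n_rec], step, 0, step
        s = _state(p, x, y)
        if step % stride == 0 or (stop_on_state and s != 0):
            out[n_rec, 0] = x
            out[n_rec, 1] = y
            n_rec += 1
        if stop_on_state and s != 0:
            return out[:n_rec], step, s, -1
        term = s
    return out[:n_rec], max_steps, term, -1


@njit(cache=True)
def _shoot_batch(p, x0, y0, n_shots, max_steps, dt, kT, gamma, seed):
    """Endpoint-only shots from one point: (nA, nB per basin, n_unresolved)."""
    n_a = 0
    n_b = np.zeros(3, dtype=np.int64)
    n_un = 0
    pref = dt / gamma
    noise = np.sqrt(2.0 * kT * dt / gamma)
    for shot in range(n_shots):
        np.random.seed(seed + shot)
        x = x0
        y = y0
        s = _state(p, x, y)
        resolved = s != 0
        if not resolved:
            for step in range(max_steps):
                _, gx, gy = _potential_and_gradient(p, x, y)
                x = x - pref * gx + noise * np.random.normal()
                y = y - pref * gy + noise * np.random.normal()
                x = _reflect(x, p[25], p[26])
                y = _reflect(y, p[27], p[28])
                s = _state(p, x, y)
                if s != 0:
                    resolved = True
                    break
        if not resolved:
            n_un += 1
        elif s == 1:
            n_a += 1
        else:
            n_b[s - 2] += 1
    return n_a, n_b, n_un


@njit(cache=True)
def _long_run(p, x0, y0, n_steps, dt, kT, gamma, seed, stride):
    np.random.seed(seed)
    cap = n_steps // stride + 2
    out = np.empty((cap, 2), dtype=np.float64)
    states = np.empty(cap, dtype=np.int64)
    out[0, 0] = x0
    out[0, 1] = y0
    states[0] = _state(p, x0, y0)
    n_rec = 1
    x = x0
    y = y0
    pref = dt / gamma
    noise = np.sqrt(2.0 * kT * dt / gamma)
    for step in range(1, n_steps + 1):
        _, gx, gy = _potential_and_gradient(p, x, y)
        x = x - pref * gx + noise * np.random.normal()
        y = y - pref * gy + noise * np.random.normal()
        x = _reflect(x, p[25], p[26])
        y = _reflect(y, p[27], p[28])
        if step % stride == 0:
            out[n_rec, 0] = x
            out[n_rec, 1] = y
            states[n_rec] = _state(p, x, y)
            n_rec += 1
    return out[:n_rec], states[:n_rec]


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _check_domain(spec: ToyLandscapeSpec, point) -> np.ndarray:
    pt = np.asarray(point, dtype=float)
    if pt.shape != (2,):
        raise ValueError("point must be a 2-vector")
    xmin, xmax, ymin, ymax = spec.bounds
    if not (xmin <= pt[0] <= xmax and ymin <= pt[1] <= ymax):
        raise DomainError(f"point {pt} outside domain bounds {spec.bounds}")
    return pt


def potential_energy(spec: ToyLandscapeSpec, point) -> float:
    """Potential V(x, y) in units of kT (at temperature 1)."""
    pt = _check_domain(spec, point)
    v, _, _ = _potential_and_gradient(spec.params(), pt[0], pt[1])
    return float(v)


def potential_gradient(spec: ToyLandscapeSpec, point) -> np.ndarray:
    """Analytic gradient of the potential at ``point``."""
    pt = _check_domain(spec, point)
    _, gx, gy = _potential_and_gradient(spec.params(), pt[0], pt[1])
    return np.array([gx, gy])


def classify_point(spec: ToyLandscapeSpec, point) -> int:
    """State code of a point: 0 none, 1 A, 2/3/4 B1/B2/B3."""
    pt = np.asarray(point, dtype=float)
    return int(_state(spec.params(), pt[0], pt[1]))


def propagate(spec: ToyLandscapeSpec, start, max_steps: int, seed: int,
              stop_on_state: bool = False, stride: int = 10) -> TrajectorySegment:
    """Integrate overdamped Langevin dynamics from ``start``.

    Reproducible given (spec, start, seed).  If ``stop_on_state``, propagation
    halts at the first frame classified A or B (the stopping frame is always
    recorded, whatever the stride).
    """
    pt = _check_domain(spec, start)
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    frames, n_steps, term, blow = _propagate_kernel(
        spec.params(), pt[0], pt[1], int(max_steps), spec.timestep,
        spec.temperature, spec.friction, int(seed) % (2**32),
        bool(stop_on_state), int(stride))
    if blow >= 0:
        raise IntegrationError(f"non-finite coordinate at integrator step {blow}")
    return TrajectorySegment(frames=frames, timestep=spec.timestep, stride=stride,
                             seed=int(seed), terminal_state=int(term),
                             n_steps=int(n_steps))


def brute_force_committor(spec: ToyLandscapeSpec, points, shots_per_point: int,
                          seed: int, max_steps: int = 400_000):
    """Monte-Carlo committor oracle.

    For each point, launches ``shots_per_point`` independent trajectories and
    reports the fraction committing to any B basin before A, with a 95%
    binomial CI.  Shots exhausting ``max_steps`` are counted separately; if
    more than 10% of the shots at a point are unresolved a warning is emitted.

    Returns a dict of arrays: ``points``, ``estimate``, ``ci_low``,
    ``ci_high``, ``n_a``, ``n_b``, ``n_unresolved``, ``basin_counts``.
    """
    if shots_per_point < 1:
        raise ValueError("shots_per_point must be >= 1")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    p = spec.params()
    n = pts.shape[0]
    est = np.empty(n)
    lo = np.empty(n)
    hi = np.empty(n)
    n_a = np.empty(n, dtype=int)
    n_un = np.empty(n, dtype=int)
    basins = np.empty((n, 3), dtype=int)
    rng = np.random.default_rng(seed)
    for i in range(n):
        _check_domain(spec, pts[i])
        sub = int(rng.integers(0, 2**31 - shots_per_point))
        a, b, un = _shoot_batch(p, pts[i, 0], pts[i, 1], int(shots_per_point),
                                int(max_steps), spec.timestep, spec.temperature,
                                spec.friction, sub)
        nb = int(b.sum())
        resolved = a + nb
        est[i] = nb / resolved if resolved else np.nan
        if resolved:
            lo[i], hi[i] = binomial_ci(nb, resolved)
        else:
            lo[i] = hi[i] = np.nan
        n_a[i] = a
        n_un[i] = un
        basins[i] = b
        if un > 0.1 * shots_per_point:
            warnings.warn(f"{un}/{shots_per_point} unresolved shots at point {pts[i]}")
    return {
        "points": pts, "estimate": est, "ci_low": lo, "ci_high": hi,
        "n_a": n_a, "n_b": basins.sum(axis=1), "n_unresolved": n_un,
        "basin_counts": basins,
    }


def channel_label(frames: np.ndarray) -> str | None:
    """Reaction-channel label: sign of y at the last x=0 crossing.

    Returns ``"upper"`` / ``"lower"``, or None if the path never crosses x=0.
    """
    x = frames[:, 0]
    y = frames[:, 1]
    sign = np.sign(x)
    idx = np.nonzero(sign[1:] * sign[:-1] < 0)[0]
    if len(idx) == 0:
        return None
    i = idx[-1]
    t = -x[i] / (x[i + 1] - x[i])
    yc = y[i] + t * (y[i + 1] - y[i])
    return "upper" if yc > 0 else "lower"


def harvest_transition_paths(spec: ToyLandscapeSpec, n_paths: int, seed: int,
                             chunk_steps: int = 4_000_000, stride: int = 10,
                             max_chunks: int = 60):
    """Collect A->B transition paths from long direct simulation.

    Runs a continuous equilibrium trajectory started in A and slices out every
    segment from the last A-exit to the first subsequent B-entry.  Returns a
    list of dicts with keys ``frames`` (strided), ``terminal_state`` and
    ``channel``.  This is the unbiased reference ensemble the path-sampling
    engine is validated against.
    """
    p = spec.params()
    rng = np.random.default_rng(seed)
    tps: list[dict] = []
    start = np.asarray(spec.well_a[0], dtype=float)
    for _ in range(max_chunks):
        sub = int(rng.integers(0, 2**31))
        frames, states = _long_run(p, start[0], start[1], int(chunk_steps),
                                   spec.timestep, spec.temperature,
                                   spec.friction, sub, int(stride))
        last_a = None
        for i in range(len(frames)):
            s = states[i]
            if s == 1:
                last_a = i
            elif s >= 2 and last_a is not None:
                seg = frames[last_a:i + 1]
                tps.append({
                    "frames": seg.copy(),
                    "terminal_state": int(s),
                    "channel": channel_label(seg),
                })
                last_a = None
                if len(tps) >= n_paths:
                    return tps
        start = frames[-1]
    return tps
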