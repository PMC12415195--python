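"""Pseudo-helix pair generator.

Generates idealized two-helix configurations standing in for atomistic
transmembrane helices: backbone anchors on an ideal alpha-helical curve
(rise 0.15 nm/residue, radius 0.23 nm, twist 100 deg/residue) and sidechain
tips displaced radially outward.  Four archetype families mirror the
characteristic dimer geometries -- parallel, X-shaped (crossing angle about
45 deg, closest approach at mid-helix), Lambda-shaped (helices splayed apart
toward the N-termini, tip on the C-terminal side) and fully separated pairs.

These generators never claim atomistic fidelity; they exist so that
featurization, state classification, clustering and committor machinery can
be tested against planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .system import Configuration, N_RESIDUES

__all__ = ["HelixPairGeometry", "make_helix_pair", "make_archetypes",
           "ARCHETYPES"]

ARCHETYPES = ("parallel", "X", "Lambda", "separated")


@dataclass(frozen=True)
class HelixPairGeometry:
    """Geometric parameters of an ideal two-helix pair.

    ``pivot`` is the fractional position along the helix axis (0 = N-terminus,
    1 = C-terminus) at which the two axes come closest; the crossing angle
    opens the axes symmetrically around that point.
    """

    rise: float = 0.15                  # nm per residue
    backbone_radius: float = 0.23       # nm
    twist_deg: float = 100.0            # degrees per residue
    inter_axis_distance: float = 1.0    # nm, at the pivot
    crossing_angle_deg: float = 0.0
    axial_offset: float = 0.0           # nm, shift of helix 2 along its axis
    phase1_deg: float = 0.0
    phase2_deg: float = 0.0
    sidechain_offset: float = 0.25      # nm, radial tip displacement
    pivot: float = 0.5
    noise_sd: float = 0.0               # nm, isotropic Gaussian noise

    def __post_init__(self):
        if min(self.rise, self.backbone_radius, self.inter_axis_distance,
               self.sidechain_offset) <= 0:
            raise ValueError("all length parameters must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not 0.0 <= self.pivot <= 1.0:
            raise ValueError("pivot must lie in [0, 1]")


def _rot_x(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _build_helix(center: np.ndarray, axis_rot: np.ndarray, geom: HelixPairGeometry,
                 phase_deg: float, s_offset: float = 0.0):
    """Backbone anchors and sidechain tips of one helix.

    ``center`` is the axis point at the pivot; ``axis_rot`` rotates the local
    frame (axis = rotated +z).  Residue i sits at arc parameter
    s_i = (i/36 - pivot) * length along the axis.
    """
    n = N_RESIDUES
    length = (n - 1) * geom.rise
    s = (np.arange(n) / (n - 1) - geom.pivot) * length + s_offset
    theta = np.deg2rad(phase_deg + np.arange(n) * geom.twist_deg)
    # local frame: axis along z, radial directions in x-y
    local_bb = np.stack([
        geom.backbone_radius * np.cos(theta),
        geom.backbone_radius * np.sin(theta),
        s,
    ], axis=1)
    r_sc = geom.backbone_radius + geom.sidechain_offset
    local_sc = np.stack([
        r_sc * np.cos(theta),
        r_sc * np.sin(theta),
        s,
    ], axis=1)
    bb = local_bb @ axis_rot.T + center
    sc = local_sc @ axis_rot.T + center
    return bb, sc


def make_helix_pair(geom: HelixPairGeometry, seed: int = 0) -> Configuration:
    """Build one two-helix configuration from ``geom``; reproducible per seed.

    Helix 1 sits at x = -d/2, helix 2 at x = +d/2 (d = inter-axis distance at
    the pivot); the crossing angle is split symmetrically between the two
    axes by counter-rotation about the x axis.
    """
    chi = np.deg2rad(geom.crossing_angle_deg)
    d = geom.inter_axis_distance
    rot1 = _rot_x(+chi / 2.0)
    rot2 = _rot_x(-chi / 2.0)
    c1 = np.array([-d / 2.0, 0.0, 0.0])
    c2 = np.array([+d / 2.0, 0.0, 0.0])
    bb1, sc1 = _build_helix(c1, rot1, geom, geom.phase1_deg)
    bb2, sc2 = _build_helix(c2, rot2, geom, geom.phase2_deg, geom.axial_offset)
    if geom.noise_sd > 0:
        rng = np.random.default_rng(seed)
        bb1 = bb1 + rng.normal(0.0, geom.noise_sd, bb1.shape)
        bb2 = bb2 + rng.normal(0.0, geom.noise_sd, bb2.shape)
        sc1 = sc1 + rng.normal(0.0, geom.noise_sd, sc1.shape)
        sc2 = sc2 + rng.normal(0.0, geom.noise_sd, sc2.shape)
    return Configuration(bb1, bb2, sc1, sc2,
                         meta={"geometry": geom, "seed": int(seed)})


# Archetype base geometries.  Dimerized archetypes use facing phases
# (phase2 = phase1 + 180) so sidechains point into the interface; the Lambda
# archetype uses matched phases, which makes the per-residue distance profile
# track the axis separation (monotone from N- to C-terminus).
_ARCHETYPE_GEOMETRY = {
    "parallel": HelixPairGeometry(inter_axis_distance=1.05, crossing_angle_deg=0.0,
                                  phase1_deg=0.0, phase2_deg=180.0, pivot=0.5),
    "X": HelixPairGeometry(inter_axis_distance=0.85, crossing_angle_deg=45.0,
                           phase1_deg=0.0, phase2_deg=180.0, pivot=0.5),
    "Lambda": HelixPairGeometry(inter_axis_distance=0.90, crossing_angle_deg=30.0,
                                phase1_deg=0.0, phase2_deg=0.0, pivot=1.0),
    "separated": HelixPairGeometry(inter_axis_distance=6.0, crossing_angle_deg=0.0,
                                   phase1_deg=0.0, phase2_deg=0.0, pivot=0.5),
}


def archetype_geometry(kind: str) -> HelixPairGeometry:
    try:
        return _ARCHETYPE_GEOMETRY[kind]
    except KeyError:
        raise ValueError(f"unknown archetype {kind!r}; choose from {ARCHETYPES}") from None


def make_archetypes(kind: str, n: int, seed: int = 0,
                    noise_sd: float = 0.05) -> list[Configuration]:
    """Draw ``n`` configurations from one archetype's geometry distribution.

    Noise is isotropic positional Gaussian noise of ``noise_sd`` nm.  The
    planted archetype label is stored in each configuration's ``meta`` as
    ground truth for clustering tests.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    base = archetype_geometry(kind)
    geom = replace(base, noise_sd=noise_sd)
    rng = np.random.default_rng(seed)
    configs = []
    for _ in range(n):
        cfg = make_helix_pair(geom, seed=int(rng.integers(0, 2**31)))
        cfg.meta["archetype"] = kind
        configs.append(cfg)
    return configs
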