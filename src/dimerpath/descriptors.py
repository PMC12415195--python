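"""Featurization and metastable-state definitions for the two-helix system.

The descriptor set contains 77 entries: 37 switched equivalent-residue
backbone distances, 37 switched equivalent-residue sidechain distances, one
switched helix-helix center-of-mass distance, and the two helix tilt angles
normalized by pi.  Distances d are mapped to [0, 1] by the switching
function

    sigma(d) = (1 - (d/r0)^12) / (1 - (d/r0)^24) = 1 / (1 + (d/r0)^12)

with r0 = 1.7 nm for descriptors.  The algebraically simplified form on the
right is used throughout to avoid the removable 0/0 singularity at d = r0.

States:

* separated  -- the minimum distance between any two points of different
  helices exceeds 1.4 nm;
* dimerized  -- the interhelical contact count NC exceeds 25, or the contact
  function Sigma = sum_{211 <= r = r' <= 226} sigma(d_SC(r, r'); r0 = 1 nm)
  exceeds 8.5;
* intermediate -- otherwise.

A "contact" for NC is an interhelical residue pair whose minimum
point-to-point distance is below 0.45 nm, the same contact scale used for
contact-frequency maps.
"""

from __future__ import annotations

import hashlib

import numpy as np

from .system import Configuration, N_RESIDUES, RESIDUE_IDS

__all__ = [
    "switch",
    "backbone_distances",
    "sidechain_distances",
    "global_descriptors",
    "featurize",
    "contact_sum_sigma",
    "n_contacts",
    "classify",
    "min_interhelix_distance",
    "residue_pair_min_distances",
    "descriptor_names",
    "descriptor_ordering_hash",
    "GeometryError",
    "StateConsistencyError",
    "R0_DESCRIPTOR",
    "R0_SIGMA",
    "R0_CONTACT",
    "SEPARATED_CUTOFF",
    "NC_THRESHOLD",
    "SIGMA_THRESHOLD",
    "N_DESCRIPTORS",
]

R0_DESCRIPTOR = 1.7     # nm, feature-scaling switch
R0_SIGMA = 1.0          # nm, restrained switch in the contact function Sigma
R0_CONTACT = 0.45       # nm, contact cutoff / contact-frequency switch
SEPARATED_CUTOFF = 1.4  # nm
NC_THRESHOLD = 25
SIGMA_THRESHOLD = 8.5
SIGMA_RESIDUES = (211, 226)  # inclusive equivalent-residue range in Sigma
N_DESCRIPTORS = 2 * N_RESIDUES + 3


class GeometryError(ValueError):
    """Degenerate geometry (e.g. all points of a helix coincide)."""


class StateConsistencyError(RuntimeError):
    """A configuration satisfied mutually exclusive state criteria."""


def switch(d, r0: float):
    """Switching function sigma(d) = 1 / (1 + (d/r0)^12), for d >= 0, r0 > 0.

    Accepts scalars or arrays; strictly decreasing with sigma(0) = 1 and
    sigma(r0) = 1/2.
    """
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    out = 1.0 / (1.0 + (d / r0) ** 12)
    return float(out) if out.ndim == 0 else out


def backbone_distances(config: Configuration) -> np.ndarray:
    """Distances (nm) between backbone anchors of equivalent residues."""
    return np.linalg.norm(config.bb1 - config.bb2, axis=1)


def sidechain_distances(config: Configuration) -> np.ndarray:
    """Equivalent-residue sidechain-tip distances (nm).

    For residues flagged glycine the backbone anchor substitutes for the
    missing sidechain tip.
    """
    p1 = np.where(config.glycine_mask[:, None], config.bb1, config.sc1)
    p2 = np.where(config.glycine_mask[:, None], config.bb2, config.sc2)
    return np.linalg.norm(p1 - p2, axis=1)


def _principal_axis(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    if np.allclose(centered, 0.0):
        raise GeometryError("degenerate helix: all points coincide")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    # orient N -> C: positive projection onto the first-to-last vector
    if axis @ (points[-1] - points[0]) < 0:
        axis = -axis
    return axis


def global_descriptors(config: Configuration) -> tuple[float, float, float]:
    """(center-of-mass distance nm, tilt1 rad, tilt2 rad).

    Centers of mass are taken over the backbone anchors of each helix; the
    tilt is the angle in [0, pi] between the N-to-C oriented principal axis
    of the anchors and the +z axis.
    """
    com1 = config.bb1.mean(axis=0)
    com2 = config.bb2.mean(axis=0)
    com_distance = float(np.linalg.norm(com1 - com2))
    tilts = []
    for bb in (config.bb1, config.bb2):
        axis = _principal_axis(bb)
        tilts.append(float(np.arccos(np.clip(axis[2], -1.0, 1.0))))
    return com_distance, tilts[0], tilts[1]


def descriptor_names() -> list[str]:
    """Frozen descriptor ordering: bb 206..242, sc 206..242, com, tilt1, tilt2."""
    names = [f"bb_{r}" for r in RESIDUE_IDS]
    names += [f"sc_{r}" for r in RESIDUE_IDS]
    names += ["com", "tilt1", "tilt2"]
    return names


def descriptor_ordering_hash() -> str:
    return hashlib.sha1(",".join(descriptor_names()).encode()).hexdigest()


def featurize(config: Configuration) -> np.ndarray:
    """The 77-entry descriptor vector, each entry in [0, 1].

    Distances are switched with r0 = 1.7 nm, tilt angles divided by pi;
    ordering per :func:`descriptor_names`.
    """
    bb = switch(backbone_distances(config), R0_DESCRIPTOR)
    sc = switch(sidechain_distances(config), R0_DESCRIPTOR)
    com, t1, t2 = global_descriptors(config)
    vec = np.concatenate([bb, sc,
                          [switch(com, R0_DESCRIPTOR), t1 / np.pi, t2 / np.pi]])
    assert vec.shape == (N_DESCRIPTORS,)
    return vec


def contact_sum_sigma(config: Configuration) -> float:
    """Contact function Sigma over equivalent residues 211..226 (16 terms).

    Sigma = sum sigma(d_SC(r, r'); r0 = 1 nm); bounded above by 16.
    """
    lo, hi = SIGMA_RESIDUES
    mask = (config.residue_ids >= lo) & (config.residue_ids <= hi)
    d = sidechain_distances(config)[mask]
    return float(np.sum(switch(d, R0_SIGMA)))


def residue_pair_min_distances(config: Configuration) -> np.ndarray:
    """(37, 37) interhelical residue-pair minimum point-to-point distances."""
    p1 = config.residue_points(1)        # (37, 2, 3)
    p2 = config.residue_points(2)
    diff = p1[:, None, :, None, :] - p2[None, :, None, :, :]
    d = np.linalg.norm(diff, axis=-1)    # (37, 37, 2, 2)
    return d.min(axis=(2, 3))


def n_contacts(config: Configuration) -> int:
    """Count of interhelical residue pairs closer than the 0.45 nm cutoff."""
    return int(np.count_nonzero(residue_pair_min_distances(config) < R0_CONTACT))


def min_interhelix_distance(config: Configuration) -> float:
    """Minimum distance between any point of helix 1 and any point of helix 2."""
    p1 = config.points(1)
    p2 = config.points(2)
    d = np.linalg.norm(p1[:, None, :] - p2[None, :, :], axis=-1)
    return float(d.min())


def classify(config: Configuration) -> str:
    """State of a configuration: 'separated', 'dimerized' or 'intermediate'."""
    separated = min_interhelix_distance(config) > SEPARATED_CUTOFF
    dimerized = (n_contacts(config) > NC_THRESHOLD
                 or contact_sum_sigma(config) > SIGMA_THRESHOLD)
    if separated and dimerized:
        raise StateConsistencyError(
            "configuration satisfies both the separated and dimerized criteria")
    if separated:
        return "separated"
    if dimerized:
        return "dimerized"
    return "intermediate"
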