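"""Two-helix configuration container.

A :class:`Configuration` holds, for each of the two helices, the per-residue
backbone anchor (C-alpha position for real structures) and the sidechain tip
(outermost sidechain carbon; the backbone anchor itself for glycines), in nm.
The container covers the transmembrane residue range 206-242 (37 residues).
An optional per-helix extra point set supports "heavy-atom" minimum-distance
queries beyond the anchor/tip approximation.

Boxes are non-periodic: configurations are assumed whole and distances are
plain Euclidean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Configuration", "RESIDUE_IDS", "N_RESIDUES", "configuration_from_pdb"]

N_RESIDUES = 37
RESIDUE_IDS = np.arange(206, 243)


@dataclass
class Configuration:
    bb1: np.ndarray                 # (37, 3) backbone anchors, helix 1, nm
    bb2: np.ndarray                 # (37, 3) backbone anchors, helix 2, nm
    sc1: np.ndarray                 # (37, 3) sidechain tips, helix 1, nm
    sc2: np.ndarray                 # (37, 3) sidechain tips, helix 2, nm
    residue_ids: np.ndarray = field(default_factory=lambda: RESIDUE_IDS.copy())
    glycine_mask: np.ndarray = field(
        default_factory=lambda: np.zeros(N_RESIDUES, dtype=bool))
    extra1: np.ndarray | None = None    # optional further points, helix 1
    extra2: np.ndarray | None = None
    box: tuple | None = None            # informational only (non-periodic)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("bb1", "bb2", "sc1", "sc2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_RESIDUES, 3):
                raise ValueError(f"{name} must have shape ({N_RESIDUES}, 3)")
            if not np.isfinite(arr).all():
                raise ValueError(f"{name} contains non-finite coordinates")
            setattr(self, name, arr)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        if len(self.residue_ids) != N_RESIDUES or np.any(np.diff(self.residue_ids) <= 0):
            raise ValueError("residue ids must be 37 strictly increasing integers")
        self.glycine_mask = np.asarray(self.glycine_mask, dtype=bool)
        if self.glycine_mask.shape != (N_RESIDUES,):
            raise ValueError("glycine mask must have length 37")

    def points(self, helix: int) -> np.ndarray:
        """All points of one helix (backbone anchors + sidechain tips + extras)."""
        bb, sc, ex = ((self.bb1, self.sc1, self.extra1) if helix == 1
                      else (self.bb2, self.sc2, self.extra2))
        parts = [bb, sc]
        if ex is not None:
            parts.append(np.asarray(ex, dtype=float))
        return np.vstack(parts)

    def residue_points(self, helix: int) -> np.ndarray:
        """(37, 2, 3) per-residue point sets (anchor, tip) of one helix."""
        bb, sc = (self.bb1, self.sc1) if helix == 1 else (self.bb2, self.sc2)
        return np.stack([bb, sc], axis=1)

    def translated(self, shift) -> "Configuration":
        s = np.asarray(shift, dtype=float)
        return Configuration(self.bb1 + s, self.bb2 + s, self.sc1 + s,
                             self.sc2 + s, self.residue_ids.copy(),
                             self.glycine_mask.copy(),
                             None if self.extra1 is None else self.extra1 + s,
                             None if self.extra2 is None else self.extra2 + s,
                             self.box, dict(self.meta))

    def rotated_z(self, angle: float) -> "Configuration":
        c, s = np.cos(angle), np.sin(angle)
        R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

        def rot(a):
            return None if a is None else a @ R.T

        return Configuration(rot(self.bb1), rot(self.bb2), rot(self.sc1),
                             rot(self.sc2), self.residue_ids.copy(),
                             self.glycine_mask.copy(), rot(self.extra1),
                             rot(self.extra2), self.box, dict(self.meta))


# outermost sidechain carbon per the standard naming; first present wins
_TIP_PRIORITY = ("CZ", "CH2", "CZ2", "CE", "CD", "CG2", "CG1", "CG", "CB")


def configuration_from_pdb(path, helix_segments=None) -> Configuration:
    """Read a two-helix configuration from a PDB file (secondary input path).

    The two helices are taken as the first two chains/segments (or the pair
    named in ``helix_segments``).  The backbone anchor is the C-alpha atom;
    the sidechain tip is the most distal sidechain carbon present (CZ > CG >
    CB, by the priority list), or C-alpha for glycines.  Coordinates are
    converted from Angstrom to nm.
    """
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    segids = helix_segments or [s.segid for s in u.segments][:2]
    if len(segids) < 2:
        raise ValueError("need two chains/segments in the PDB file")

    def extract(segid):
        seg = u.select_atoms(f"segid {segid}")
        residues = seg.residues
        if len(residues) != N_RESIDUES:
            raise ValueError(
                f"segment {segid} has {len(residues)} residues, expected {N_RESIDUES}")
        bb = np.empty((N_RESIDUES, 3))
        sc = np.empty((N_RESIDUES, 3))
        gly = np.zeros(N_RESIDUES, dtype=bool)
        for i, res in enumerate(residues):
            names = {a.name: a for a in res.atoms}
            if "CA" not in names:
                raise ValueError(f"residue {res.resid} lacks a CA atom")
            bb[i] = names["CA"].position / 10.0
            gly[i] = res.resname.upper() == "GLY"
            tip = None
            if not gly[i]:
                for cand in _TIP_PRIORITY:
                    if cand in names:
                        tip = names[cand].position / 10.0
                        break
            sc[i] = bb[i] if tip is None else tip
        return bb, sc, gly

    bb1, sc1, g1 = extract(segids[0])
    bb2, sc2, g2 = extract(segids[1])
    return Configuration(bb1, bb2, sc1, sc2, glycine_mask=g1 | g2,
                         meta={"source": str(path)})
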