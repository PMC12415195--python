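"""Post-sampling analytics on transition-path ensembles.

Covers extraction of the transition state ensemble (TSE, frames with
pB near 0.5) and bound state ensemble (BSE, first dimerized frame of each
transition path), their clustering (k-means for the BSE, k-medoids for the
TSE so each cluster is represented by an actual member), the TSE-to-BSE flow
matrix, per-chain switching statistics, committor-distance correlations,
isocommittor distance profiles, contact-frequency maps and the per-contact
"binding initiative" score ranking how early a contact becomes persistently
formed along a transition path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .descriptors import (classify, residue_pair_min_distances,
                          sidechain_distances, switch, R0_CONTACT)

__all__ = ["TransitionPath", "EnsembleCluster", "extract_tse", "extract_bse",
           "cluster_bse", "cluster_tse", "kmedoids", "flow_matrix",
           "switching_fraction", "pb_distance_correlation",
           "isocommittor_profiles", "contact_frequency", "binding_initiative"]


@dataclass
class TransitionPath:
    """An ordered A-to-B path with per-frame committor values.

    ``frames`` may be a (n, 2) coordinate array (toy system) or a list of
    two-helix Configurations; ``pb`` holds the per-frame committor.
    """

    frames: object
    pb: np.ndarray
    descriptors: np.ndarray | None = None
    terminal_label: object = None      # BSE label (basin code or cluster id)
    channel: object = None             # TSE channel label
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pb = np.asarray(self.pb, dtype=float)
        if len(self.pb) != len(self.frames):
            raise ValueError("pb must have one value per frame")

    def __len__(self):
        return len(self.frames)


@dataclass
class EnsembleCluster:
    cluster_id: int
    member_indices: np.ndarray
    population: float
    representative: np.ndarray
    medoid_index: int | None = None    # set for k-medoids clusters


# ---------------------------------------------------------------------------
# ensemble extraction
# ---------------------------------------------------------------------------

def extract_tse(tps: list, band: tuple = (0.45, 0.55)) -> list[tuple[int, int]]:
    """Frames with pB inside ``band``, as (path index, frame index) pairs.

    Every path contributes at least one frame: if none falls inside the band,
    the frame with pB nearest to 0.5 is taken as fallback.
    """
    if not tps:
        raise ValueError("no transition paths given")
    lo, hi = band
    picks = []
    for i, tp in enumerate(tps):
        inside = np.nonzero((tp.pb >= lo) & (tp.pb <= hi))[0]
        if len(inside) == 0:
            inside = [int(np.argmin(np.abs(tp.pb - 0.5)))]
        picks.extend((i, int(j)) for j in inside)
    return picks


def extract_bse(tps: list, dimerized=None) -> list[tuple[int, int]]:
    """First dimerized frame of each path, as (path index, frame index) pairs.

    ``dimerized`` is a per-frame predicate; by default, two-helix frames use
    the dimerized-state criterion and toy paths (which terminate on state
    entry) contribute their final frame.
    """
    if not tps:
        raise ValueError("no transition paths given")
    picks = []
    for i, tp in enumerate(tps):
        if dimerized is None and isinstance(tp.frames, np.ndarray):
            picks.append((i, len(tp) - 1))
            continue
        pred = dimerized or (lambda cfg: classify(cfg) == "dimerized")
        for j, frame in enumerate(tp.frames):
            if pred(frame):
                picks.append((i, j))
                break
        else:
            raise ValueError(f"transition path {i} has no dimerized frame")
    return picks


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_bse(vectors, k: int = 3, seed: int = 0
                ) -> tuple[np.ndarray, list[EnsembleCluster]]:
    """k-means clustering of bound-state feature vectors (e.g. sidechain
    distances); returns (labels, clusters) with centroid representatives."""
    X = np.asarray(vectors, dtype=float)
    if k < 1 or k > len(X):
        raise ValueError("need 1 <= k <= number of vectors")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
    labels = km.labels_
    clusters = []
    for c in range(k):
        members = np.nonzero(labels == c)[0]
        clusters.append(EnsembleCluster(
            cluster_id=c, member_indices=members,
            population=len(members) / len(X),
            representative=km.cluster_centers_[c]))
    return labels, clusters


def kmedoids(X: np.ndarray, k: int, seed: int = 0, n_init: int = 10,
             max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Alternating (Voronoi) k-medoids on Euclidean distances.

    Returns (labels, medoid indices); deterministic given ``seed``, best of
    ``n_init`` random restarts by total within-cluster distance.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if k < 1 or k > n:
        raise ValueError("need 1 <= k <= number of vectors")
    D = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
    rng = np.random.default_rng(seed)
    best_cost = np.inf
    best = None
    for _ in range(n_init):
        medoids = rng.choice(n, size=k, replace=False)
        for _ in range(max_iter):
            labels = np.argmin(D[:, medoids], axis=1)
            new_medoids = medoids.copy()
            for c in range(k):
                members = np.nonzero(labels == c)[0]
                if len(members) == 0:
                    continue
                within = D[np.ix_(members, members)].sum(axis=1)
                new_medoids[c] = members[np.argmin(within)]
            if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
                break
            medoids = new_medoids
        labels = np.argmin(D[:, medoids], axis=1)
        cost = D[np.arange(n), medoids[labels]].sum()
        if cost < best_cost - 1e-12:
            best_cost = cost
            best = (labels.copy(), medoids.copy())
    return best


def cluster_tse(vectors, k: int = 2, seed: int = 0
                ) -> tuple[np.ndarray, list[EnsembleCluster]]:
    """k-medoids clustering of TSE feature vectors; the representative of
    each cluster is an actual member (the medoid)."""
    X = np.asarray(vectors, dtype=float)
    labels, medoids = kmedoids(X, k, seed=seed)
    clusters = []
    for c in range(k):
        members = np.nonzero(labels == c)[0]
        clusters.append(EnsembleCluster(
            cluster_id=c, member_indices=members,
            population=len(members) / len(X),
            representative=X[medoids[c]], medoid_index=int(medoids[c])))
    return labels, clusters


# ---------------------------------------------------------------------------
# flow and switching
# ---------------------------------------------------------------------------

def flow_matrix(tse_labels, bse_labels, k_tse: int | None = None,
                k_bse: int | None = None) -> np.ndarray:
    """Counts matrix: entry (i, j) = number of TPs passing TSE cluster i and
    ending in BSE cluster j.  Every TP must carry both labels."""
    t = np.asarray(tse_labels)
    b = np.asarray(bse_labels)
    if len(t) != len(b):
        raise ValueError("label vectors must have equal length")
    if np.any(t < 0) or np.any(b < 0):
        raise ValueError("every transition path must be labeled in both dimensions")
    kt = k_tse or int(t.max()) + 1
    kb = k_bse or int(b.max()) + 1
    M = np.zeros((kt, kb), dtype=int)
    np.add.at(M, (t, b), 1)
    return M


def switching_fraction(label_sequences: list) -> dict:
    """Per-chain switching statistics of accepted-TP terminal labels.

    The switch fraction of a chain is (number of label changes between
    consecutive accepted TPs) / (accepted TPs - 1); 1 means every subsequent
    TP terminated in a different bound state.  Chains with fewer than two
    accepted TPs are excluded (reported in the result).
    """
    fractions = []
    excluded = 0
    for seq in label_sequences:
        seq = list(seq)
        if len(seq) < 2:
            excluded += 1
            continue
        changes = sum(a != b for a, b in zip(seq[:-1], seq[1:]))
        fractions.append(changes / (len(seq) - 1))
    if excluded:
        warnings.warn(f"{excluded} chain(s) with < 2 accepted TPs excluded")
    fractions = np.asarray(fractions)
    hist, edges = np.histogram(fractions, bins=10, range=(0.0, 1.0))
    return {"fractions": fractions, "histogram": hist, "bin_edges": edges,
            "n_excluded": excluded}


# ---------------------------------------------------------------------------
# committor-distance structure
# ---------------------------------------------------------------------------

def pb_distance_correlation(tps: list, pooled: bool = True) -> np.ndarray:
    """Pearson correlation of each equivalent-residue sidechain distance with
    pB over transition-path frames.

    Negative values mean the distance shrinks as pB grows (the contact forms
    as the transition progresses).  Zero-variance distances yield NaN
    (undefined), not 0.  With ``pooled=False`` the correlation is computed
    per path and averaged.
    """
    def corr(d, p):
        out = np.full(d.shape[1], np.nan)
        sp = p.std()
        for j in range(d.shape[1]):
            sd = d[:, j].std()
            if sd > 0 and sp > 0:
                out[j] = np.corrcoef(d[:, j], p)[0, 1]
        return out

    mats = []
    pbs = []
    for tp in tps:
        d = np.array([sidechain_distances(c) for c in tp.frames])
        mats.append(d)
        pbs.append(tp.pb)
    if pooled:
        return corr(np.vstack(mats), np.concatenate(pbs))
    per = np.array([corr(d, p) for d, p in zip(mats, pbs)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(per, axis=0)


def isocommittor_profiles(tps: list, levels=(0.3, 0.4, 0.5, 0.6, 0.7, 0.8),
                          halfwidth: float = 0.05) -> dict:
    """Mean sidechain-distance profiles of the isocommittor ensembles.

    For each channel label and level, frames with |pB - level| <= halfwidth
    are pooled and their equivalent-residue sidechain distances averaged.
    Empty (channel, level) combinations are omitted with a note.  Returns
    {channel: {level: (37,) mean profile}}.
    """
    levels = np.asarray(levels, dtype=float)
    if np.any(levels < 0) or np.any(levels > 1):
        raise ValueError("isocommittor levels must lie in [0, 1]")
    out: dict = {}
    channels = sorted({tp.channel for tp in tps}, key=str)
    for ch in channels:
        out[ch] = {}
        members = [tp for tp in tps if tp.channel == ch]
        for lv in levels:
            pool = []
            for tp in members:
                sel = np.nonzero(np.abs(tp.pb - lv) <= halfwidth)[0]
                pool.extend(sidechain_distances(tp.frames[j]) for j in sel)
            if not pool:
                warnings.warn(f"no frames at level {lv} in channel {ch}; omitted")
                continue
            out[ch][float(lv)] = np.mean(pool, axis=0)
    return out


def contact_frequency(frames: list, r0: float = R0_CONTACT) -> np.ndarray:
    """(37, 37) mean soft contact map over frames.

    Each entry is the frame-average of sigma(d; r0) applied to the minimum
    interresidue point distance, with the contact-scale cutoff r0 = 0.45 nm.
    """
    if not frames:
        raise ValueError("no frames given")
    acc = np.zeros((len(frames[0].residue_ids), len(frames[0].residue_ids)))
    for cfg in frames:
        acc += switch(residue_pair_min_distances(cfg), r0)
    return acc / len(frames)


def binding_initiative(contact_series: np.ndarray,
                       persistence: float = 0.9) -> np.ndarray:
    """Binding-initiative scores from a boolean per-frame contact series.

    ``contact_series`` has shape (n_frames, n_contacts).  For each contact the
    earliest formation frame t is found after which the contact is present in
    more than ``persistence`` of the remaining frames; the raw score is the
    remaining-runtime fraction (T - t)/T, then min-max normalized across
    contacts so the earliest persistent contact scores 1 and the latest 0.
    Contacts that never become persistent are reported as NaN and excluded
    from the normalization.  If all persistent contacts form at the same time
    (including the single-contact case) they all score 1.
    """
    S = np.asarray(contact_series, dtype=bool)
    if S.ndim != 2 or len(S) < 1:
        raise ValueError("contact series must be a (n_frames, n_contacts) array")
    T, m = S.shape
    raw = np.full(m, np.nan)
    for j in range(m):
        col = S[:, j]
        # suffix fraction of frames (from t inclusive) in which the contact holds
        suffix = np.cumsum(col[::-1])[::-1]
        remaining = T - np.arange(T)
        frac = suffix / remaining
        ok = col & (frac > persistence)
        t = np.argmax(ok) if ok.any() else None
        if t is not None:
            raw[j] = (T - t) / T
    have = np.isfinite(raw)
    if not have.any():
        return raw
    lo, hi = np.nanmin(raw), np.nanmax(raw)
    out = raw.copy()
    if hi - lo < 1e-15:
        out[have] = 1.0
    else:
        out[have] = (raw[have] - lo) / (hi - lo)
    return out


def contact_series_from_frames(frames: list, pairs=None,
                               cutoff: float = R0_CONTACT) -> np.ndarray:
    """Boolean contact series for a list of configurations.

    ``pairs`` is an iterable of (i, j) residue-index pairs (0-based); default
    is the 37 equivalent-residue pairs.
    """
    n_res = len(frames[0].residue_ids)
    if pairs is None:
        pairs = [(i, i) for i in range(n_res)]
    pairs = list(pairs)
    out = np.zeros((len(frames), len(pairs)), dtype=bool)
    for t, cfg in enumerate(frames):
        d = residue_pair_min_distances(cfg)
        out[t] = [d[i, j] < cutoff for i, j in pairs]
    return out
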