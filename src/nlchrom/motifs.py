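"""Tetra-nucleosome folding motifs.

Sliding windows of four consecutive nucleosomes are reduced to a 6-entry
binary contact vector (the unique pairs among i..i+3; two nucleosomes are
in contact when their centres lie within 2.5 nucleosome diameters). The
vectors, pooled over windows and frames, are clustered by k-means and the
clusters ranked by prevalence; the mean 4x4 contact map of each cluster
summarises the motif (open, paired, or fully closed arrangements).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .chain import NUCLEOSOME_DIAMETER_NM

__all__ = ["TetraMotifSet", "tetra_contact_maps", "cluster_motifs", "PAIR_INDEX"]

# the 6 unique pairs among 4 consecutive nucleosomes, in fixed order
PAIR_INDEX = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass
class TetraMotifSet:
    vectors: np.ndarray                 # (n_obs, 6) binary
    window_ids: np.ndarray              # (n_obs,) first-nucleosome index
    frame_ids: np.ndarray               # (n_obs,)
    labels: np.ndarray | None = None    # cluster label per observation
    prevalence: np.ndarray | None = None  # per cluster, ranked order
    cluster_means: np.ndarray | None = None  # (k, 4, 4) mean contact maps
    order: np.ndarray | None = None     # cluster ids by descending prevalence

    @property
    def n_observations(self) -> int:
        return int(self.vectors.shape[0])


def _vector_to_map(vec: np.ndarray) -> np.ndarray:
    m = np.eye(4)
    for v, (a, b) in zip(vec, PAIR_INDEX):
        m[a, b] = m[b, a] = v
    return m


def tetra_contact_maps(
    nuc_frames_nm: np.ndarray, threshold_factor: float = 2.5
) -> TetraMotifSet:
    """Binary pair vectors for every 4-nucleosome window in every frame.

    ``nuc_frames_nm``: (F, n_nucleosomes, 3) nucleosome centres in nm.
    Contact iff centre distance <= threshold_factor x nucleosome diameter.
    """
    frames = np.asarray(nuc_frames_nm, dtype=float)
    f, n, _ = frames.shape
    if n < 4:
        raise ValueError("need at least 4 nucleosomes")
    cutoff = threshold_factor * NUCLEOSOME_DIAMETER_NM
    vecs, wins, fids = [], [], []
    for fr in range(f):
        pos = frames[fr]
        for w in range(n - 3):
            quad = pos[w : w + 4]
            v = np.array(
                [
                    np.linalg.norm(quad[a] - quad[b]) <= cutoff
                    for a, b in PAIR_INDEX
                ],
                dtype=float,
            )
            vecs.append(v)
            wins.append(w)
            fids.append(fr)
    return TetraMotifSet(
        vectors=np.array(vecs), window_ids=np.array(wins), frame_ids=np.array(fids)
    )


def cluster_motifs(motifs: TetraMotifSet, k: int = 10, seed: int = 0, n_init: int = 20) -> TetraMotifSet:
    """k-means over the binary pair vectors; clusters ranked by prevalence.

    If fewer distinct vectors than k exist, k is reduced with a warning.
    Deterministic given the seed (best of ``n_init`` restarts by inertia).
    """
    import warnings

    x = motifs.vectors
    n_distinct = np.unique(x, axis=0).shape[0]
    if n_distinct < k:
        warnings.warn(
            f"only {n_distinct} distinct vectors; reducing k from {k}",
            stacklevel=2,
        )
        k = n_distinct
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)
    labels = km.labels_
    counts = np.bincount(labels, minlength=k)
    prevalence = counts / counts.sum()
    order = np.argsort(-prevalence, kind="stable")
    # means of binary vectors live in [0,1]; clip k-means round-off
    centers = np.clip(km.cluster_centers_, 0.0, 1.0)
    means = np.stack([_vector_to_map(centers[c]) for c in order])
    return TetraMotifSet(
        vectors=motifs.vectors,
        window_ids=motifs.window_ids,
        frame_ids=motifs.frame_ids,
        labels=labels,
        prevalence=prevalence[order],
        cluster_means=means,
        order=order,
    )
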