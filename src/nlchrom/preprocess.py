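"""Stage-1 front end: significant-contact extraction and stochastic
decomposition of a balanced contact map into per-replicate restraint sets.

Per genomic-separation diagonal ``d = |i - j| >= 2`` a threshold
``theta_d = mu_d + sigma_d`` (mean plus standard deviation of that
diagonal's entries) selects the persistent contacts. The retained pairs
are then decomposed into M replicate restraint sets by independent
Bernoulli draws with inclusion probability ``q_ij = p_ij / max p``
(clamped to [q_min, 1]), so that the replicate-averaged inclusion
reproduces the retained frequencies up to the max-normalisation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import ContactMap

log = logging.getLogger(__name__)

__all__ = [
    "SignificantContactSet",
    "ContactEnsemble",
    "significant_contacts",
    "decompose",
    "balance_map",
    "sinkhorn_balance",
]


@dataclass
class SignificantContactSet:
    """Retained (i, j, p_ij) contacts with their per-diagonal thresholds."""

    pairs: np.ndarray          # (n, 2) int, i < j
    probabilities: np.ndarray  # (n,) float
    thresholds: dict[int, float]
    n_bins: int
    source: str = ""

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if np.any(self.pairs[:, 0] >= self.pairs[:, 1]):
            raise ValueError("pairs must satisfy i < j")
        if np.any(np.abs(self.pairs[:, 1] - self.pairs[:, 0]) < 2):
            raise ValueError("adjacent/self pairs are covered by the backbone")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ContactEnsemble:
    """M replicate restraint sets drawn from a SignificantContactSet."""

    replicates: list[np.ndarray]   # each (m_r, 2) int pairs
    inclusion_q: np.ndarray        # (n_pairs,) probability used per pair
    pairs: np.ndarray              # (n_pairs, 2) the candidate pairs
    seed: int
    n_bins: int

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    def empirical_inclusion(self) -> np.ndarray:
        """Fraction of replicates containing each candidate pair."""
        key = {tuple(p): k for k, p in enumerate(map(tuple, self.pairs))}
        counts = np.zeros(len(self.pairs))
        for rep in self.replicates:
            for p in map(tuple, rep):
                if p in key:
                    counts[key[p]] += 1
        return counts / max(self.n_replicates, 1)


def significant_contacts(cmap: ContactMap, min_separation: int = 2) -> SignificantContactSet:
    """Retain contacts exceeding their diagonal's mean + SD threshold.

    Diagonals with fewer than 3 entries are skipped; |i-j| < 2 pairs are
    excluded because the chain backbone already bonds adjacent beads.
    """
    m = cmap.matrix
    n = cmap.n_bins
    if n < 4:
        raise ValueError("contact map too small (N >= 4 required)")
    if not np.any(m > 0):
        raise ValueError("all-zero contact map")
    pairs: list[tuple[int, int]] = []
    probs: list[float] = []
    thresholds: dict[int, float] = {}
    for d in range(max(2, min_separation), n):
        diag = np.diagonal(m, offset=d)
        if diag.size < 3:
            continue
        theta = diag.mean() + diag.std()
        thresholds[d] = float(theta)
        sel = np.nonzero(diag > theta)[0]
        for i in sel:
            pairs.append((int(i), int(i + d)))
            probs.append(float(diag[i]))
    return SignificantContactSet(
        pairs=np.array(pairs, dtype=int).reshape(-1, 2),
        probabilities=np.array(probs),
        thresholds=thresholds,
        n_bins=n,
        source=str(cmap.region),
    )


def _is_connected(n_bins: int, pairs: np.ndarray, include_backbone: bool = True) -> bool:
    """Connectivity of the restraint graph (plus backbone) via union-find."""
    parent = np.arange(n_bins)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        parent[find(a)] = find(b)

    if include_backbone:
        for i in range(n_bins - 1):
            union(i, i + 1)
    for i, j in pairs:
        union(int(i), int(j))
    root = find(0)
    return all(find(i) == root for i in range(n_bins))


def decompose(
    sig: SignificantContactSet,
    M: int,
    seed: int,
    q_min: float = 0.02,
    repair_connectivity: bool = True,
) -> ContactEnsemble:
    """Draw M independent Bernoulli replicate restraint sets.

    q_ij = p_ij / max p, clamped to [q_min, 1]. Replicates whose restraint
    graph (with the backbone) is disconnected receive the highest-q
    bridging pairs until connected (logged); with the backbone included
    this is a safety net that also guarantees non-empty replicates.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if len(sig) == 0:
        raise ValueError("empty significant-contact set")
    q = np.clip(sig.probabilities / sig.probabilities.max(), q_min, 1.0)
    rng = np.random.default_rng(seed)
    order = np.argsort(-q, kind="stable")
    replicates: list[np.ndarray] = []
    for _ in range(M):
        mask = rng.random(len(q)) < q
        chosen = sig.pairs[mask]
        if repair_connectivity and (
            chosen.shape[0] == 0 or not _is_connected(sig.n_bins, chosen)
        ):
            added = []
            for k in order:
                if mask[k]:
                    continue
                added.append(sig.pairs[k])
                cand = np.vstack([chosen, np.array(added)]) if len(added) else chosen
                if cand.shape[0] > 0 and _is_connected(sig.n_bins, cand):
                    break
            if added:
                log.info("replicate repaired with %d bridging pair(s)", len(added))
                chosen = np.vstack([chosen, np.array(added)]) if chosen.size else np.array(added)
        replicates.append(np.asarray(chosen, dtype=int).reshape(-1, 2))
    return ContactEnsemble(
        replicates=replicates, inclusion_q=q, pairs=sig.pairs, seed=seed, n_bins=sig.n_bins
    )


def sinkhorn_balance(
    matrix: np.ndarray, tol: float = 1e-10, max_iter: int = 10_000
) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric Sinkhorn scaling to unit row sums.

    Returns (balanced matrix, mask of retained bins). All-zero rows are
    masked out (their rows/columns stay zero). Raises on non-convergence.
    """
    m = np.asarray(matrix, dtype=float).copy()
    if np.any(m < 0):
        raise ValueError("matrix must be non-negative")
    mask = m.sum(axis=1) > 0
    if not np.any(mask):
        raise ValueError("all rows are zero")
    sub = m[np.ix_(mask, mask)]
    if np.any(sub.sum(axis=1) == 0):
        raise ValueError("zero row among retained bins")
    for _ in range(max_iter):
        r = sub.sum(axis=1)
        if np.max(np.abs(r - 1.0)) < tol:
            break
        d = 1.0 / np.sqrt(r)
        sub = sub * d[:, None] * d[None, :]
    else:
        raise RuntimeError("Sinkhorn balancing did not converge")
    # final one-sided polish keeps row sums exactly 1 while staying
    # symmetric to round-off (the symmetric fixed point has equal row sums)
    out = np.zeros_like(m)
    out[np.ix_(mask, mask)] = sub
    return out, mask


def balance_map(cmap: ContactMap, tol: float = 1e-8, max_iter: int = 10_000) -> ContactMap:
    """Balance a raw contact map to unit row sums (Sinkhorn iteration).

    All-zero bins are masked and reported via the returned map's masked
    rows (left zero). An already-balanced map is a fixed point.
    """
    balanced, mask = sinkhorn_balance(cmap.matrix, tol=tol * 1e-2, max_iter=max_iter)
    n_masked = int((~mask).sum())
    if n_masked:
        log.warning("balance_map: %d all-zero bin(s) masked", n_masked)
    return cmap.copy_with(balanced, balanced=True)
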